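"""Hybrid structure learning for discrete Bayesian networks.

Score-based greedy hill climbing (add / delete / reverse single-arc
moves) under prior-knowledge arc constraints, scored by the BIC for
multinomial data,

    score(G) = sum_i sum_{j,k} N_ijk log(N_ijk / N_ij)
               - (log N / 2) * sum_i q_i (r_i - 1),

which is decomposable by node family, so each move re-scores at most two
families.  Robustness against locally optimal single graphs comes from
nonparametric bootstrap model averaging: the learner is rerun on B row
resamples, arcs are aggregated into per-pair strengths (fraction of
replicates containing the arc in either direction) and directions
(fraction of those supporting an orientation), and the averaged network
keeps arcs at or above a strength threshold (0.85 by default), oriented
by a direction threshold (0.5).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .network import CategoricalVariable, Dag

__all__ = [
    "ArcConstraints",
    "ArcStrengthTable",
    "bic_score",
    "hill_climb",
    "bootstrap_arc_strengths",
    "averaged_network",
]

_EPS = 1e-10  # minimum score gain to accept a move


@dataclass(frozen=True)
class ArcConstraints:
    """Prior knowledge as required (whitelist) and forbidden (blacklist) arcs."""

    whitelist: frozenset[tuple[str, str]] = frozenset()
    blacklist: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "whitelist", frozenset(map(tuple, self.whitelist)))
        object.__setattr__(self, "blacklist", frozenset(map(tuple, self.blacklist)))
        clash = self.whitelist & self.blacklist
        if clash:
            raise ValueError(f"arcs both required and forbidden: {sorted(clash)}")
        nodes = {n for arc in self.whitelist for n in arc}
        Dag(nodes, self.whitelist)  # raises if the whitelist is cyclic

    @classmethod
    def none(cls) -> "ArcConstraints":
        return cls()


def variables_from_data(data: pd.DataFrame, columns: Sequence[str] | None = None) -> list[CategoricalVariable]:
    """Infer categorical variables from observed values (sorted level order)."""
    cols = list(columns) if columns is not None else list(data.columns)
    out = []
    for c in cols:
        levels = sorted(data[c].dropna().astype(str).unique())
        out.append(CategoricalVariable(c, tuple(levels)))
    return out


class _FamilyScorer:
    """Cached decomposable BIC family scores over an integer-encoded table."""

    def __init__(self, data: pd.DataFrame, variables: Sequence[CategoricalVariable]):
        self.variables = list(variables)
        self.names = [v.name for v in self.variables]
        self.cards = np.array([v.cardinality for v in self.variables])
        n = len(data)
        self.codes = np.empty((n, len(self.variables)), dtype=np.int64)
        for j, v in enumerate(self.variables):
            col = data[v.name]
            mapping = {lv: i for i, lv in enumerate(v.levels)}
            coded = col.astype(str).map(mapping)
            coded[col.isna()] = -1
            self.codes[:, j] = coded.fillna(-1).to_numpy(dtype=np.int64)
        self._cache: dict[tuple[int, frozenset[int]], float] = {}

    def resampled(self, rows: np.ndarray) -> "_FamilyScorer":
        new = object.__new__(_FamilyScorer)
        new.variables = self.variables
        new.names = self.names
        new.cards = self.cards
        new.codes = self.codes[rows]
        new._cache = {}
        return new

    def local_score(self, child: int, parents: frozenset[int]) -> float:
        key = (child, parents)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        fam = [child, *sorted(parents)]
        sub = self.codes[:, fam]
        sub = sub[(sub >= 0).all(axis=1)]
        n_rows = sub.shape[0]
        r = int(self.cards[child])
        q = int(np.prod(self.cards[sorted(parents)])) if parents else 1
        if n_rows == 0:
            score = -0.5 * np.log(max(n_rows, 1)) * q * (r - 1)
            self._cache[key] = score
            return score
        # flatten (parent combo, child level) into one index and count
        dims = [r] + [int(self.cards[p]) for p in sorted(parents)]
        flat = np.ravel_multi_index([sub[:, i] for i in range(sub.shape[1])], dims)
        njk = np.bincount(flat, minlength=int(np.prod(dims))).reshape(r, q)
        nj = np.broadcast_to(njk.sum(axis=0), njk.shape)
        mask = njk > 0  # 0*log(0) == 0, and nj > 0 wherever njk > 0
        ll = float(np.sum(njk[mask] * (np.log(njk[mask]) - np.log(nj[mask]))))
        score = ll - 0.5 * np.log(n_rows) * q * (r - 1)
        self._cache[key] = score
        return score

    def total_score(self, parent_sets: dict[int, frozenset[int]]) -> float:
        return sum(self.local_score(c, ps) for c, ps in parent_sets.items())


def bic_score(
    dag: Dag,
    data: pd.DataFrame,
    variables: Sequence[CategoricalVariable] | None = None,
) -> float:
    """BIC of a DAG on categorical data (higher is better)."""
    variables = list(variables) if variables else variables_from_data(data, dag.nodes)
    scorer = _FamilyScorer(data, variables)
    idx = {v.name: i for i, v in enumerate(variables)}
    parent_sets = {
        idx[n]: frozenset(idx[p] for p in dag.parents(n)) for n in dag.nodes
    }
    return scorer.total_score(parent_sets)


def _reachable(adj: dict[int, set[int]], src: int, dst: int) -> bool:
    stack, seen = [src], set()
    while stack:
        u = stack.pop()
        if u == dst:
            return True
        for w in adj[u]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return False


def hill_climb(
    data: pd.DataFrame,
    constraints: ArcConstraints | None = None,
    seed: int = 0,
    max_iter: int = 200,
    variables: Sequence[CategoricalVariable] | None = None,
    score_cache: "_FamilyScorer | None" = None,
) -> Dag:
    """Greedy hill climbing over single-arc moves.

    Starts from the whitelist-only graph; never violates the blacklist,
    removes a whitelist arc, or creates a cycle.  The algorithm is
    deterministic: equal-score moves are broken lexicographically by
    (move type, parent, child), so ``seed`` only matters to callers that
    resample the data themselves.
    """
    constraints = constraints or ArcConstraints.none()
    if score_cache is not None:
        scorer = score_cache
        variables = scorer.variables
    else:
        variables = list(variables) if variables else variables_from_data(data)
        scorer = _FamilyScorer(data, variables)
    names = [v.name for v in variables]
    idx = {n: i for i, n in enumerate(names)}
    for p, c in sorted(constraints.whitelist | constraints.blacklist):
        if p not in idx or c not in idx:
            raise ValueError(f"constraint arc {p}->{c} names an unknown variable")

    p_count = len(names)
    parents: dict[int, set[int]] = {i: set() for i in range(p_count)}
    children: dict[int, set[int]] = {i: set() for i in range(p_count)}
    for u_name, v_name in constraints.whitelist:
        parents[idx[v_name]].add(idx[u_name])
        children[idx[u_name]].add(idx[v_name])
    wl = {(idx[a], idx[b]) for a, b in constraints.whitelist}
    bl = {(idx[a], idx[b]) for a, b in constraints.blacklist}

    local = {i: scorer.local_score(i, frozenset(parents[i])) for i in range(p_count)}

    for _ in range(max_iter):
        best: tuple[float, str, int, int] | None = None

        def consider(delta: float, move: str, u: int, v: int) -> None:
            nonlocal best
            if delta <= _EPS:
                return
            cand = (-delta, move, names[u], names[v])
            if best is None or cand < (-best[0], best[1], names[best[2]], names[best[3]]):
                best = (delta, move, u, v)

        for u, v in itertools.permutations(range(p_count), 2):
            if u in parents[v]:
                # delete u -> v
                if (u, v) not in wl:
                    new_v = scorer.local_score(v, frozenset(parents[v] - {u}))
                    consider(new_v - local[v], "delete", u, v)
                # reverse u -> v
                if (u, v) not in wl and (v, u) not in bl:
                    children[u].discard(v)
                    cyclic = _reachable(children, u, v)
                    children[u].add(v)
                    if not cyclic:
                        new_v = scorer.local_score(v, frozenset(parents[v] - {u}))
                        new_u = scorer.local_score(u, frozenset(parents[u] | {v}))
                        consider(new_v - local[v] + new_u - local[u], "reverse", u, v)
            else:
                # add u -> v
                if (u, v) not in bl and not _reachable(children, v, u):
                    new_v = scorer.local_score(v, frozenset(parents[v] | {u}))
                    consider(new_v - local[v], "add", u, v)

        if best is None:
            break
        _, move, u, v = best
        if move == "add":
            parents[v].add(u)
            children[u].add(v)
        elif move == "delete":
            parents[v].discard(u)
            children[u].discard(v)
        else:  # reverse
            parents[v].discard(u)
            children[u].discard(v)
            parents[u].add(v)
            children[v].add(u)
            local[u] = scorer.local_score(u, frozenset(parents[u]))
        local[v] = scorer.local_score(v, frozenset(parents[v]))

    edges = [(names[u], names[v]) for v in parents for u in parents[v]]
    return Dag(names, edges)


@dataclass
class ArcStrengthTable:
    """Bootstrap support for each arc.

    ``strength(a, b)`` is the fraction of bootstrap networks containing
    the arc in either direction; ``direction(a, b)`` is, among those, the
    fraction orienting it a -> b (so direction(a,b) + direction(b,a) = 1
    whenever strength > 0).
    """

    nodes: tuple[str, ...]
    n_replicates: int
    directed_counts: dict[tuple[str, str], int] = field(default_factory=dict)

    def _pair_count(self, a: str, b: str) -> int:
        return self.directed_counts.get((a, b), 0) + self.directed_counts.get((b, a), 0)

    def strength(self, a: str, b: str) -> float:
        return self._pair_count(a, b) / self.n_replicates

    def direction(self, a: str, b: str) -> float:
        pair = self._pair_count(a, b)
        if pair == 0:
            return 0.0
        return self.directed_counts.get((a, b), 0) / pair

    def to_frame(self) -> pd.DataFrame:
        rows = []
        seen = set()
        for a, b in sorted(self.directed_counts):
            for u, v in ((a, b), (b, a)):
                if (u, v) in seen or self._pair_count(u, v) == 0:
                    continue
                seen.add((u, v))
                rows.append(
                    {
                        "from": u,
                        "to": v,
                        "strength": self.strength(u, v),
                        "direction": self.direction(u, v),
                    }
                )
        return pd.DataFrame(rows, columns=["from", "to", "strength", "direction"])


def bootstrap_arc_strengths(
    data: pd.DataFrame,
    constraints: ArcConstraints | None = None,
    n_replicates: int = 200,
    seed: int = 0,
    variables: Sequence[CategoricalVariable] | None = None,
    max_iter: int = 200,
) -> ArcStrengthTable:
    """Arc strengths from B nonparametric bootstrap resamples of the rows.

    Each replicate resamples n rows with replacement using a stream keyed
    by (seed, replicate index), so increasing B extends rather than
    reshuffles the replicate sequence, and reruns hill climbing.  Level
    sets are fixed from the full data so rare levels missing from a
    resample cannot change the variable definitions.
    """
    if n_replicates < 1:
        raise ValueError("need at least one bootstrap replicate")
    constraints = constraints or ArcConstraints.none()
    variables = list(variables) if variables else variables_from_data(data)
    base = _FamilyScorer(data, variables)
    n = len(data)
    counts: dict[tuple[str, str], int] = {}
    for b in range(n_replicates):
        rng = np.random.default_rng([seed, b])
        rows = rng.integers(0, n, size=n)
        dag = hill_climb(
            data,
            constraints,
            seed=seed,
            max_iter=max_iter,
            score_cache=base.resampled(rows),
        )
        for arc in dag.edges:
            counts[arc] = counts.get(arc, 0) + 1
    return ArcStrengthTable(tuple(v.name for v in variables), n_replicates, counts)


def averaged_network(
    strengths: ArcStrengthTable,
    strength_threshold: float = 0.85,
    direction_threshold: float = 0.5,
) -> Dag:
    """Threshold the arc-strength table into a single averaged DAG.

    Keeps undirected arcs with strength >= the strength threshold,
    oriented in the direction whose support exceeds the direction
    threshold (an exact tie is broken toward the lexicographically
    smaller parent).  If thresholding would create a cycle, arcs are
    dropped in increasing strength order until the graph is acyclic.
    """
    if not (0 < strength_threshold <= 1 and 0 < direction_threshold <= 1):
        raise ValueError("thresholds must lie in (0, 1]")
    pairs = sorted(
        {tuple(sorted((a, b))) for a, b in strengths.directed_counts}
    )
    kept: list[tuple[float, str, str]] = []
    for a, b in pairs:
        s = strengths.strength(a, b)
        if s < strength_threshold:
            continue
        d_ab = strengths.direction(a, b)
        if d_ab > direction_threshold:
            kept.append((s, a, b))
        elif (1 - d_ab) > direction_threshold:
            kept.append((s, b, a))
        else:  # tie at the threshold: smaller name becomes the parent
            kept.append((s, a, b))
    # strongest first; a cycle-inducing arc is the weakest of its cycle
    kept.sort(key=lambda t: (-t[0], t[1], t[2]))
    edges: list[tuple[str, str]] = []
    for _, u, v in kept:
        try:
            Dag(strengths.nodes, edges + [(u, v)])
        except ValueError:
            continue
        edges.append((u, v))
    return Dag(strengths.nodes, edges)
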