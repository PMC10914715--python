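"""Core representation of discrete Bayesian networks.

A network is a directed acyclic graph (DAG) over categorical variables
together with one conditional probability table (CPT) per node.  The joint
distribution factorises as

    P(x_1, ..., x_n) = prod_i P(x_i | parents(x_i))

with each factor read off the node's CPT.  Parent-level combinations are
enumerated in row-major order of the parents' declared level orders; that
ordering is part of the serialization contract (see :mod:`metsnet.io`).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "CategoricalVariable",
    "Dag",
    "Cpt",
    "DiscreteBayesNet",
    "validate_network",
    "joint_probability",
    "count_dags",
]

#: rows whose probabilities sum to 1 within this are accepted (and
#: silently renormalized); larger deviations are construction errors.
ROW_SUM_TOL = 1e-6


@dataclass(frozen=True)
class CategoricalVariable:
    """A named categorical variable with a fixed, ordered set of levels."""

    name: str
    levels: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple(str(v) for v in self.levels))
        if len(self.levels) < 2:
            raise ValueError(f"variable {self.name!r} needs >= 2 levels")
        if len(set(self.levels)) != len(self.levels):
            raise ValueError(f"variable {self.name!r} has duplicate levels")

    @property
    def cardinality(self) -> int:
        return len(self.levels)

    def index(self, level: str) -> int:
        try:
            return self.levels.index(level)
        except ValueError:
            raise KeyError(
                f"{level!r} is not a declared level of {self.name!r} "
                f"(levels: {list(self.levels)})"
            ) from None


class Dag:
    """A directed acyclic graph over named nodes.

    Cycles and self-loops are rejected at construction; acyclicity is
    certified by a successful topological sort.
    """

    def __init__(self, nodes: Iterable[str], edges: Iterable[tuple[str, str]] = ()):
        self.nodes: tuple[str, ...] = tuple(dict.fromkeys(nodes))
        self.edges: frozenset[tuple[str, str]] = frozenset(
            (str(p), str(c)) for p, c in edges
        )
        node_set = set(self.nodes)
        for p, c in sorted(self.edges):
            if p == c:
                raise ValueError(f"self-loop {p}->{c}")
            if p not in node_set or c not in node_set:
                raise ValueError(f"edge {p}->{c} has endpoint outside node set")
        g = self._graph()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"graph contains a directed cycle: {cycle}")

    def _graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def parents(self, node: str) -> tuple[str, ...]:
        """Parents of *node*, ordered by declared node order."""
        ps = {p for p, c in self.edges if c == node}
        return tuple(n for n in self.nodes if n in ps)

    def children(self, node: str) -> tuple[str, ...]:
        cs = {c for p, c in self.edges if p == node}
        return tuple(n for n in self.nodes if n in cs)

    def topological_order(self) -> list[str]:
        # lexicographic tie-break so orderings are reproducible
        return list(nx.lexicographical_topological_sort(self._graph()))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dag):
            return NotImplemented
        return set(self.nodes) == set(other.nodes) and self.edges == other.edges

    def __hash__(self) -> int:
        return hash((frozenset(self.nodes), self.edges))

    def __repr__(self) -> str:
        return f"Dag(nodes={list(self.nodes)}, edges={sorted(self.edges)})"


class Cpt:
    """Conditional probability table P(child | parents).

    ``table`` maps each parent-level combination (a tuple, ``()`` for root
    nodes) to a probability vector over the child's levels.  Rows whose sum
    deviates from 1 by more than ``ROW_SUM_TOL`` are rejected unless
    ``normalize=True``; smaller deviations are silently renormalized.
    """

    def __init__(
        self,
        child: str,
        parents: Sequence[str],
        table: Mapping[tuple[str, ...], Sequence[float]],
        *,
        normalize: bool = False,
    ):
        self.child = str(child)
        self.parents = tuple(str(p) for p in parents)
        self.table: dict[tuple[str, ...], np.ndarray] = {}
        for combo, probs in table.items():
            key = tuple(str(v) for v in (combo if isinstance(combo, tuple) else (combo,)))
            if len(key) != len(self.parents):
                raise ValueError(
                    f"CPT row for {self.child!r}: combination {key} does not "
                    f"match parents {self.parents}"
                )
            vec = np.asarray(probs, dtype=float)
            if vec.ndim != 1 or vec.size < 2:
                raise ValueError(f"CPT row {key} of {self.child!r}: need a vector of >=2 probabilities")
            if np.any(vec < 0) or np.any(vec > 1 + ROW_SUM_TOL):
                raise ValueError(f"CPT row {key} of {self.child!r}: entries outside [0,1]")
            s = vec.sum()
            if abs(s - 1.0) > ROW_SUM_TOL and not normalize:
                raise ValueError(
                    f"CPT row {key} of {self.child!r} sums to {s:.6f}, not 1"
                )
            if s <= 0:
                raise ValueError(f"CPT row {key} of {self.child!r} sums to zero")
            self.table[key] = vec / s

    def row(self, combo: tuple[str, ...]) -> np.ndarray:
        return self.table[tuple(combo)]

    def __repr__(self) -> str:
        return f"Cpt(child={self.child!r}, parents={list(self.parents)}, rows={len(self.table)})"


@dataclass
class DiscreteBayesNet:
    """A discrete Bayesian network: variables, DAG and one CPT per node."""

    variables: list[CategoricalVariable]
    dag: Dag
    cpts: dict[str, Cpt] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.variables = list(self.variables)
        self._by_name = {v.name: v for v in self.variables}
        if len(self._by_name) != len(self.variables):
            raise ValueError("duplicate variable names")

    def variable(self, name: str) -> CategoricalVariable:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown variable {name!r}") from None

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    def parent_combinations(self, node: str) -> Iterator[tuple[str, ...]]:
        """Row-major enumeration of the node's parent-level combinations."""
        parents = self.dag.parents(node)
        yield from itertools.product(*(self.variable(p).levels for p in parents))

    def cpt_array(self, node: str) -> np.ndarray:
        """CPT as an ndarray with one axis per parent plus the child axis."""
        cpt = self.cpts[node]
        shape = tuple(self.variable(p).cardinality for p in cpt.parents) + (
            self.variable(node).cardinality,
        )
        arr = np.empty(shape, dtype=float)
        for combo in self.parent_combinations(node):
            idx = tuple(self.variable(p).index(v) for p, v in zip(cpt.parents, combo))
            arr[idx] = cpt.row(combo)
        return arr


def validate_network(net: DiscreteBayesNet) -> list[str]:
    """Check a network's structural invariants.

    Returns a list of human-readable violation descriptions; the empty
    list means the network is valid.  Violations are reported, not raised,
    so callers can present all problems at once.
    """
    violations: list[str] = []
    names = set(net.names)
    if set(net.dag.nodes) != names:
        violations.append(
            f"DAG nodes {sorted(net.dag.nodes)} differ from variables {sorted(names)}"
        )
    try:
        net.dag.topological_order()
    except nx.NetworkXError as exc:  # pragma: no cover - Dag ctor rejects cycles
        violations.append(f"DAG is cyclic: {exc}")
    for name in net.names:
        var = net.variable(name)
        cpt = net.cpts.get(name)
        if cpt is None:
            violations.append(f"node {name!r}: missing CPT")
            continue
        dag_parents = net.dag.parents(name)
        if cpt.parents != dag_parents:
            violations.append(
                f"node {name!r}: CPT parents {list(cpt.parents)} != DAG parents {list(dag_parents)}"
            )
            continue
        expected = set(itertools.product(*(net.variable(p).levels for p in cpt.parents)))
        got = set(cpt.table)
        for combo in sorted(expected - got):
            violations.append(f"node {name!r}: CPT row for {combo} missing")
        for combo in sorted(got - expected):
            violations.append(f"node {name!r}: CPT row {combo} uses undeclared parent levels")
        for combo in sorted(got & expected):
            vec = cpt.row(combo)
            if vec.size != var.cardinality:
                violations.append(
                    f"node {name!r}: CPT row {combo} has {vec.size} entries for "
                    f"{var.cardinality} levels"
                )
            elif abs(float(vec.sum()) - 1.0) > 1e-9:
                violations.append(
                    f"node {name!r}: CPT row {combo} sums to {float(vec.sum()):.12f}"
                )
    return violations


def joint_probability(net: DiscreteBayesNet, assignment: Mapping[str, str]) -> float:
    """Probability of one full assignment under the network factorization."""
    missing = [n for n in net.names if n not in assignment]
    if missing:
        raise ValueError(f"assignment is missing variables: {missing}")
    p = 1.0
    for name in net.names:
        var = net.variable(name)
        level = assignment[name]
        var.index(level)  # raises KeyError on undeclared level
        cpt = net.cpts[name]
        combo = tuple(assignment[par] for par in cpt.parents)
        k = var.index(level)
        p *= float(cpt.row(combo)[k])
    return p


def count_dags(n: int) -> int:
    """Number of labeled DAGs on ``n`` nodes (Robinson's recurrence).

    a(n) = sum_{i=1..n} (-1)^(i+1) C(n, i) 2^(i(n-i)) a(n-i), a(0) = 1.
    Exact integer arithmetic; feasible for n <= 20 and beyond.
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    a = [1] + [0] * n
    for m in range(1, n + 1):
        a[m] = sum(
            (-1) ** (i + 1) * math.comb(m, i) * 2 ** (i * (m - i)) * a[m - i]
            for i in range(1, m + 1)
        )
    return a[n]
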