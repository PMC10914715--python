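"""Exact inference on discrete Bayesian networks.

``query`` computes P(target | evidence) by variable elimination with a
min-degree elimination order over the moralized graph; the order affects
speed only, never values.  ``enumerate_posterior`` is the deliberately
naive full-joint oracle used to property-test ``query``.

Two epidemiological reasoning modes are layered on top:

* causal reasoning — instantiate a risk factor as hard (100%) evidence
  and read the outcome's posterior against its prior;
* evidential reasoning — condition on an outcome level and read each
  factor's posterior, the Bayes inversion of the former.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .network import DiscreteBayesNet, joint_probability

__all__ = [
    "ZeroProbabilityEvidenceError",
    "ReasoningTable",
    "query",
    "enumerate_posterior",
    "causal_reasoning",
    "evidential_reasoning",
]

_ZERO = 1e-300


class ZeroProbabilityEvidenceError(ValueError):
    """The supplied evidence has probability zero under the network."""


def _check_evidence(net: DiscreteBayesNet, evidence: Mapping[str, str]) -> dict[str, str]:
    ev = {}
    for name, level in evidence.items():
        var = net.variable(name)  # KeyError on unknown variable
        var.index(level)  # KeyError on undeclared level
        ev[name] = level
    return ev


@dataclass
class _Factor:
    vars: tuple[str, ...]
    values: np.ndarray  # one axis per variable, in `vars` order

    def multiply(self, other: "_Factor") -> "_Factor":
        out_vars = self.vars + tuple(v for v in other.vars if v not in self.vars)
        a = self._expand(out_vars)
        b = other._expand(out_vars)
        return _Factor(out_vars, a * b)

    def _expand(self, out_vars: tuple[str, ...]) -> np.ndarray:
        # move own axes into out_vars order, insert length-1 axes elsewhere
        src = [self.vars.index(v) for v in out_vars if v in self.vars]
        arr = np.transpose(self.values, src) if self.values.ndim else self.values
        shape = [arr.shape[[v for v in out_vars if v in self.vars].index(v)] if v in self.vars else 1
                 for v in out_vars]
        return arr.reshape(shape)

    def marginalize(self, var: str) -> "_Factor":
        ax = self.vars.index(var)
        return _Factor(
            self.vars[:ax] + self.vars[ax + 1:], self.values.sum(axis=ax)
        )


def _cpt_factor(net: DiscreteBayesNet, node: str, evidence: Mapping[str, str]) -> _Factor:
    cpt = net.cpts[node]
    vars_ = cpt.parents + (node,)
    arr = net.cpt_array(node)
    keep_vars, idx = [], []
    for v in vars_:
        if v in evidence:
            idx.append(net.variable(v).index(evidence[v]))
        else:
            keep_vars.append(v)
            idx.append(slice(None))
    return _Factor(tuple(keep_vars), arr[tuple(idx)])


def _relevant_nodes(net: DiscreteBayesNet, target: str, evidence: Mapping[str, str]) -> set[str]:
    # ancestors of the target and the evidence suffice for exact posteriors
    needed = {target, *evidence}
    out: set[str] = set()
    stack = list(needed)
    while stack:
        n = stack.pop()
        if n in out:
            continue
        out.add(n)
        stack.extend(net.dag.parents(n))
    return out


def query(
    net: DiscreteBayesNet,
    target: str,
    evidence: Mapping[str, str] | None = None,
) -> np.ndarray:
    """Exact posterior P(target | evidence) by variable elimination."""
    evidence = _check_evidence(net, evidence or {})
    if target in evidence:
        raise ValueError(f"target {target!r} is already fixed by the evidence")
    net.variable(target)
    nodes = _relevant_nodes(net, target, evidence)
    factors = [_cpt_factor(net, n, evidence) for n in nodes]

    # min-degree order on the moralized interaction graph, ties lexicographic
    hidden = {v for f in factors for v in f.vars} - {target}
    neighbors: dict[str, set[str]] = {v: set() for v in hidden | {target}}
    scopes = [set(f.vars) for f in factors]
    for scope in scopes:
        for a in scope:
            neighbors[a] |= scope - {a}
    order = []
    remaining = set(hidden)
    while remaining:
        v = min(remaining, key=lambda x: (len(neighbors[x] & remaining), x))
        order.append(v)
        nb = neighbors[v] & remaining
        for a in nb:
            neighbors[a] |= nb - {a}
        remaining.discard(v)

    for v in order:
        involved = [f for f in factors if v in f.vars]
        rest = [f for f in factors if v not in f.vars]
        prod = involved[0]
        for f in involved[1:]:
            prod = prod.multiply(f)
        factors = rest + [prod.marginalize(v)]

    result = factors[0]
    for f in factors[1:]:
        result = result.multiply(f)
    if result.vars != (target,):
        result = _Factor((target,), result._expand((target,)).reshape(-1))
    total = float(result.values.sum())
    if total <= _ZERO:
        raise ZeroProbabilityEvidenceError(
            f"evidence {dict(evidence)} has probability zero under the network"
        )
    return result.values / total


def enumerate_posterior(
    net: DiscreteBayesNet,
    target: str,
    evidence: Mapping[str, str] | None = None,
) -> np.ndarray:
    """Brute-force posterior by summing the full joint (oracle; <= ~15 nodes)."""
    evidence = _check_evidence(net, evidence or {})
    if target in evidence:
        raise ValueError(f"target {target!r} is already fixed by the evidence")
    tvar = net.variable(target)
    free = [n for n in net.names if n != target and n not in evidence]
    post = np.zeros(tvar.cardinality)
    for k, t_level in enumerate(tvar.levels):
        for combo in itertools.product(*(net.variable(n).levels for n in free)):
            assignment = dict(zip(free, combo))
            assignment[target] = t_level
            assignment.update(evidence)
            post[k] += joint_probability(net, assignment)
    total = post.sum()
    if total <= _ZERO:
        raise ZeroProbabilityEvidenceError(
            f"evidence {dict(evidence)} has probability zero under the network"
        )
    return post / total


def _arrow(delta: float, tol: float = 5e-7) -> str:
    if delta > tol:
        return "↑"
    if delta < -tol:
        return "↓"
    return ""


@dataclass
class ReasoningTable:
    """Prior-vs-posterior probabilities under one reasoning mode.

    One row per (evidence, queried variable, level): prior and posterior
    probability, their difference, and an up/down arrow marker.  Raw
    probabilities are kept unrounded; rounding happens only in rendered
    reports.
    """

    mode: str  # "causal" | "evidential"
    table: pd.DataFrame

    def rounded(self, decimals: int = 2) -> pd.DataFrame:
        """Percent-scale view rounded half-up, table style."""
        out = self.table.copy()
        for col in ("prior", "posterior", "delta"):
            scaled = out[col] * 100
            out[col] = np.floor(scaled * 10**decimals + 0.5) / 10**decimals
        return out


def causal_reasoning(
    net: DiscreteBayesNet,
    outcome: str,
    factors: Sequence[str],
) -> ReasoningTable:
    """Instantiate each factor level as hard evidence; watch the outcome.

    For every factor and every one of its levels, the level is set as
    100% evidence and the outcome posterior is recorded next to the
    no-evidence prior.
    """
    if outcome in factors:
        raise ValueError("outcome cannot be one of the factors")
    prior = query(net, outcome)
    out_levels = net.variable(outcome).levels
    rows = []
    for factor in factors:
        for level in net.variable(factor).levels:
            post = query(net, outcome, {factor: level})
            for k, out_level in enumerate(out_levels):
                delta = float(post[k] - prior[k])
                rows.append(
                    {
                        "evidence": f"{factor}={level}",
                        "variable": outcome,
                        "level": out_level,
                        "prior": float(prior[k]),
                        "posterior": float(post[k]),
                        "delta": delta,
                        "trend": _arrow(delta),
                    }
                )
    return ReasoningTable("causal", pd.DataFrame(rows))


def evidential_reasoning(
    net: DiscreteBayesNet,
    outcome: str,
    outcome_level: str,
    factors: Sequence[str],
) -> ReasoningTable:
    """Condition on an outcome level; watch each factor's posterior."""
    if outcome in factors:
        raise ValueError("outcome cannot be one of the factors")
    net.variable(outcome).index(outcome_level)
    rows = []
    for factor in factors:
        prior = query(net, factor)
        post = query(net, factor, {outcome: outcome_level})
        for k, level in enumerate(net.variable(factor).levels):
            delta = float(post[k] - prior[k])
            rows.append(
                {
                    "evidence": f"{outcome}={outcome_level}",
                    "variable": factor,
                    "level": level,
                    "prior": float(prior[k]),
                    "posterior": float(post[k]),
                    "delta": delta,
                    "trend": _arrow(delta),
                }
            )
    return ReasoningTable("evidential", pd.DataFrame(rows))
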