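"""Bayesian CPT estimation from complete categorical data.

Given a fixed DAG, each node's conditional distribution is estimated by
the posterior mean under a Dirichlet prior:

    theta_ijk = (N_ijk + alpha_ijk) / (N_ij + sum_k alpha_ijk)

where ``N_ijk`` is the number of rows with child level ``k`` and parent
combination ``j``, and the hyperparameters spread a total imaginary
sample size (iss) uniformly over the CPT cells of node ``i``,
``alpha_ijk = iss / (r_i * q_i)`` (BDeu-style).  Rows with no data return
the uniform prior mean; with iss > 0 no estimated cell is ever exactly 0
or 1 on finite data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .network import CategoricalVariable, Cpt, Dag, DiscreteBayesNet

__all__ = ["CountTable", "DirichletPrior", "tabulate_counts", "fit_cpts"]


@dataclass
class CountTable:
    """Sufficient statistics N_ijk for one node family."""

    child: str
    parents: tuple[str, ...]
    counts: dict[tuple[str, ...], np.ndarray]

    def row_total(self, combo: tuple[str, ...]) -> int:
        """N_ij: total observations for one parent combination."""
        return int(self.counts[combo].sum())

    @property
    def total(self) -> int:
        return sum(int(v.sum()) for v in self.counts.values())


@dataclass(frozen=True)
class DirichletPrior:
    """Uniform Dirichlet prior with a total imaginary sample size."""

    imaginary_sample_size: float = 1.0

    def __post_init__(self) -> None:
        if self.imaginary_sample_size <= 0:
            raise ValueError("imaginary sample size must be > 0")

    def alpha(self, r: int, q: int) -> float:
        """Per-cell hyperparameter alpha_ijk for a node with r levels and q parent rows."""
        return self.imaginary_sample_size / (r * q)


def _check_levels(data: pd.DataFrame, variables: Sequence[CategoricalVariable]) -> None:
    for var in variables:
        if var.name not in data.columns:
            raise ValueError(f"data has no column for variable {var.name!r}")
        col = data[var.name]
        observed = col[col.notna()]
        bad = ~observed.astype(str).isin(var.levels)
        if bad.any():
            row = int(observed.index[np.asarray(bad)][0])
            raise ValueError(
                f"undeclared level {observed.astype(str)[bad].iloc[0]!r} in column "
                f"{var.name!r} (first at row {row}); declared: {list(var.levels)}"
            )


def tabulate_counts(
    data: pd.DataFrame,
    dag: Dag,
    variables: Sequence[CategoricalVariable],
) -> dict[str, CountTable]:
    """Count N_ijk per node family.

    Rows with a missing value anywhere in a node's family (the node plus
    its parents) are excluded for that family only (complete-case per
    family), so a missing covariate does not discard the whole record.
    """
    by_name = {v.name: v for v in variables}
    _check_levels(data, variables)
    out: dict[str, CountTable] = {}
    for node in dag.nodes:
        var = by_name[node]
        parents = dag.parents(node)
        family = [node, *parents]
        sub = data[family].dropna().astype(str)
        counts = {
            combo: np.zeros(var.cardinality, dtype=np.int64)
            for combo in itertools.product(*(by_name[p].levels for p in parents))
        }
        if len(sub):
            child_codes = sub[node].map(var.index).to_numpy()
            if parents:
                grouped = pd.DataFrame({"_k": child_codes})
                for p in parents:
                    grouped[p] = sub[p].to_numpy()
                for combo, grp in grouped.groupby(list(parents), sort=False):
                    key = combo if isinstance(combo, tuple) else (combo,)
                    counts[tuple(key)] += np.bincount(
                        grp["_k"].to_numpy(), minlength=var.cardinality
                    )
            else:
                counts[()] += np.bincount(child_codes, minlength=var.cardinality)
        out[node] = CountTable(node, parents, counts)
    return out


def fit_cpts(
    dag: Dag,
    data: pd.DataFrame,
    variables: Sequence[CategoricalVariable],
    prior: DirichletPrior | float = 1.0,
) -> DiscreteBayesNet:
    """Posterior-mean CPTs on a fixed DAG (Dirichlet-multinomial model)."""
    if not isinstance(prior, DirichletPrior):
        prior = DirichletPrior(float(prior))
    by_name = {v.name: v for v in variables}
    tables = tabulate_counts(data, dag, variables)
    cpts: dict[str, Cpt] = {}
    for node in dag.nodes:
        var = by_name[node]
        ct = tables[node]
        q = max(len(ct.counts), 1)
        a = prior.alpha(var.cardinality, q)
        rows = {
            combo: (vec + a) / (vec.sum() + a * var.cardinality)
            for combo, vec in ct.counts.items()
        }
        cpts[node] = Cpt(node, ct.parents, rows)
    ordered_vars = [by_name[n] for n in dag.nodes]
    return DiscreteBayesNet(variables=ordered_vars, dag=dag, cpts=cpts)
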