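"""Scikit-learn-style estimators over the learning pipeline.

``BayesianNetworkClassifier`` wraps the full learning stack — bootstrap
hill-climbing structure learning with model averaging, then Dirichlet
posterior-mean CPT estimation — behind the familiar
``fit`` / ``predict`` / ``predict_proba`` surface, so the network model
composes with sklearn model selection and pipelines.  ``MetsStager`` is
a stateless transformer that stages a two-wave biomarker cohort.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import mets
from .inference import query
from .params import DirichletPrior, fit_cpts
from .structure import (
    ArcConstraints,
    averaged_network,
    bootstrap_arc_strengths,
    hill_climb,
    variables_from_data,
)

__all__ = ["BayesianNetworkClassifier", "MetsStager"]


class BayesianNetworkClassifier(ClassifierMixin, BaseEstimator):
    """Discrete Bayesian network as a probabilistic classifier.

    Parameters
    ----------
    target : name of the outcome column (the class variable).
    constraints : prior-knowledge arc whitelist/blacklist, or None.
    n_bootstrap : bootstrap replicates for model averaging; 0 disables
        averaging and keeps the single hill-climbed graph.
    strength_threshold, direction_threshold : averaged-network cutoffs.
    iss : imaginary sample size of the Dirichlet parameter prior.
    random_state : master seed for the bootstrap resamples.

    Attributes (after ``fit``)
    --------------------------
    network_ : the fitted :class:`~metsnet.network.DiscreteBayesNet`.
    dag_ : the learned structure.
    arc_strengths_ : bootstrap arc-strength table (None if n_bootstrap=0).
    classes_ : outcome levels, in declared order.
    """

    def __init__(
        self,
        target: str = "progression",
        constraints: ArcConstraints | None = None,
        n_bootstrap: int = 0,
        strength_threshold: float = 0.85,
        direction_threshold: float = 0.5,
        iss: float = 1.0,
        random_state: int = 0,
    ):
        self.target = target
        self.constraints = constraints
        self.n_bootstrap = n_bootstrap
        self.strength_threshold = strength_threshold
        self.direction_threshold = direction_threshold
        self.iss = iss
        self.random_state = random_state

    def _assemble(self, X: pd.DataFrame, y: Sequence | None) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a pandas DataFrame of categorical columns")
        data = X.copy()
        if y is not None:
            data[self.target] = np.asarray(y, dtype=object)
        if self.target not in data.columns:
            raise ValueError(
                f"target column {self.target!r} not in X and y not provided"
            )
        return data

    def fit(self, X: pd.DataFrame, y: Sequence | None = None) -> "BayesianNetworkClassifier":
        data = self._assemble(X, y)
        variables = variables_from_data(data)
        constraints = self.constraints or ArcConstraints.none()
        if self.n_bootstrap:
            self.arc_strengths_ = bootstrap_arc_strengths(
                data,
                constraints,
                n_replicates=self.n_bootstrap,
                seed=self.random_state,
                variables=variables,
            )
            self.dag_ = averaged_network(
                self.arc_strengths_, self.strength_threshold, self.direction_threshold
            )
        else:
            self.arc_strengths_ = None
            self.dag_ = hill_climb(
                data, constraints, seed=self.random_state, variables=variables
            )
        self.network_ = fit_cpts(self.dag_, data, variables, DirichletPrior(self.iss))
        self.classes_ = np.asarray(self.network_.variable(self.target).levels)
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Row-wise posterior P(target | observed evidence columns)."""
        check_is_fitted(self, "network_")
        evid_cols = [
            c for c in X.columns if c in self.network_.names and c != self.target
        ]
        out = np.empty((len(X), len(self.classes_)))
        cache: dict[tuple, np.ndarray] = {}
        for i, (_, row) in enumerate(X.iterrows()):
            ev = {
                c: str(row[c]) for c in evid_cols
                if not (isinstance(row[c], float) and np.isnan(row[c]))
            }
            key = tuple(sorted(ev.items()))
            if key not in cache:
                cache[key] = query(self.network_, self.target, ev)
            out[i] = cache[key]
        return out

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]


class MetsStager(TransformerMixin, BaseEstimator):
    """Stateless JIS staging transform over a two-wave cohort frame.

    ``transform`` adds per-wave component counts, the four-state staging
    and the between-wave transition label (see :mod:`metsnet.mets`).
    """

    def fit(self, X: pd.DataFrame, y=None) -> "MetsStager":
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        drop = [c for c in ("transition",) if c in X.columns]
        return mets.stage_cohort(X.drop(columns=drop))
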