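"""scikit-learn style estimators over the inference engine.

:class:`BooleanNetworkEA` is the fit-shaped front end to the evolutionary
search: ``fit`` takes a :class:`~bpds.data.TimeSeriesSet` (breaking
inconsistencies first), exposes the inferred model family and consensus
wiring as fitted attributes, and ``predict`` applies one synchronous update
of the best model to an array of binary states.  The discretizers are plain
transformers (fit thresholds on pooled data, transform column-wise) and
compose with sklearn pipelines.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .data import TimeSeriesSet, break_inconsistencies, quantile_thresholds
from .ea import EAConfig, evolve
from .scoring import FitnessWeights, PriorMatrix

__all__ = ["BooleanNetworkEA", "QuantileDiscretizer", "IntervalDiscretizer"]


class BooleanNetworkEA(BaseEstimator):
    """Infer a Boolean polynomial dynamical system from binary time series.

    Parameters mirror :class:`~bpds.ea.EAConfig`; the fitness weights are
    exposed flat (``w_hm`` model fit, ``w_hp`` coordinate fit, ``w_c``
    parsimony, ``w_b`` / ``w_re`` priors) so they participate in sklearn
    parameter search.

    Attributes (after ``fit``)
    --------------------------
    result_ : InferenceResult
    family_ : ranked list of (PolynomialModel, FitnessReport)
    best_model_ : PolynomialModel
    consensus_adjacency_ : (n, n) edge-frequency matrix over the family
    search_space_ : SearchSpaceSpec (total length m and support bound Phi)
    n_features_in_ : number of network variables
    """

    def __init__(
        self,
        population_size: int = 200,
        generations: int = 500,
        mutation_rate: float = 0.2,
        crossover_rate: float = 0.8,
        clone_fraction: float = 0.05,
        tournament_size: int = 3,
        max_monomials_per_coordinate: int = 8,
        w_hm: float = 1.0,
        w_hp: float = 1.0,
        w_c: float = 0.5,
        w_b: float = 0.5,
        w_re: float = 0.5,
        xi: float = 0.05,
        output_family_size: int = 10,
        random_state: int = 0,
    ):
        self.population_size = population_size
        self.generations = generations
        self.mutation_rate = mutation_rate
        self.crossover_rate = crossover_rate
        self.clone_fraction = clone_fraction
        self.tournament_size = tournament_size
        self.max_monomials_per_coordinate = max_monomials_per_coordinate
        self.w_hm = w_hm
        self.w_hp = w_hp
        self.w_c = w_c
        self.w_b = w_b
        self.w_re = w_re
        self.xi = xi
        self.output_family_size = output_family_size
        self.random_state = random_state

    def _config(self) -> EAConfig:
        return EAConfig(
            population_size=self.population_size,
            generations=self.generations,
            mutation_rate=self.mutation_rate,
            crossover_rate=self.crossover_rate,
            clone_fraction=self.clone_fraction,
            tournament_size=self.tournament_size,
            max_monomials_per_coordinate=self.max_monomials_per_coordinate,
            weights=FitnessWeights(self.w_hm, self.w_hp, self.w_c, self.w_b, self.w_re),
            xi=self.xi,
            seed=self.random_state,
            output_family_size=self.output_family_size,
        )

    def fit(self, X: TimeSeriesSet, y=None, bio_prior: PriorMatrix | None = None,
            reveng_prior: PriorMatrix | None = None):
        if not isinstance(X, TimeSeriesSet):
            raise TypeError("X must be a TimeSeriesSet")
        result = evolve(
            break_inconsistencies(X),
            config=self._config(),
            bio_prior=bio_prior,
            reveng_prior=reveng_prior,
        )
        self.result_ = result
        self.family_ = result.family
        self.best_model_ = result.best_model
        self.consensus_adjacency_ = result.consensus_adjacency
        self.search_space_ = result.search_space
        self.n_features_in_ = X.n
        return self

    def predict(self, X) -> np.ndarray:
        """One synchronous update of the best inferred model applied to each
        row of a binary state matrix."""
        self._check_fitted()
        X = np.asarray(X)
        one = X.ndim == 1
        states = np.atleast_2d(X)
        out = np.array([self.best_model_.step(list(row)) for row in states], dtype=np.int8)
        return out[0] if one else out

    def score(self, X: TimeSeriesSet, y=None) -> float:
        """Free-run goodness of fit ``1 - H_f`` of the best model on ``X``."""
        from .scoring import model_hamming

        self._check_fitted()
        h, _ = model_hamming(self.best_model_, break_inconsistencies(X))
        return 1.0 - h

    def _check_fitted(self) -> None:
        if not hasattr(self, "best_model_"):
            raise RuntimeError("estimator is not fitted yet; call fit first")


class _Discretizer(TransformerMixin, BaseEstimator):
    def __init__(self, n_levels: int = 2):
        self.n_levels = n_levels

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("X must be a non-empty 2-D array")
        self.thresholds_ = self._thresholds(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "thresholds_"):
            raise RuntimeError("discretizer is not fitted yet")
        X = np.asarray(X, dtype=float)
        return (X[:, :, None] > self.thresholds_[None, :, :]).sum(axis=2)


class QuantileDiscretizer(_Discretizer):
    """Column-wise quantile binning (thresholds at the j/s quantiles of the
    training data; ties at a threshold go to the lower level)."""

    def _thresholds(self, X: np.ndarray) -> np.ndarray:
        return quantile_thresholds(X, self.n_levels)


class IntervalDiscretizer(_Discretizer):
    """Column-wise equal-width binning on the training range (the training
    maximum maps to the top level; internal bin boundaries map upward)."""

    def _thresholds(self, X: np.ndarray) -> np.ndarray:
        self.lo_ = X.min(axis=0)
        self.span_ = X.max(axis=0) - self.lo_
        s = self.n_levels
        return np.stack([self.lo_ + self.span_ * j / s for j in range(1, s)], axis=1)

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "thresholds_"):
            raise RuntimeError("discretizer is not fitted yet")
        X = np.asarray(X, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            raw = np.where(self.span_ > 0, (X - self.lo_) / self.span_ * self.n_levels, 0.0)
        return np.clip(np.floor(raw).astype(int), 0, self.n_levels - 1)
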