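"""Multi-objective fitness: data fit, complexity and prior agreement.

The fitness of a candidate model is a weighted sum of

* the model's free-run goodness of fit ``W_HM * (1 - H_f)``, where ``H_f``
  is the Hamming distance between each observed series and the trajectory
  obtained by iterating the model from the series' first point, normalised
  by ``n * sum(alpha_mu)``;
* the per-coordinate one-step fit ``W_HP * (1 - H_fi)``, where ``H_fi``
  counts mismatches between ``f_i`` applied to each observed state and the
  next observed value of column ``i``, normalised by ``sum(alpha_mu)``;
* a parsimony term ``W_C * (1 - complexity)``, with complexity the mean over
  coordinates of total degree divided by the support bound ``Phi``;
* prior-topology agreement ``W_B * BioScore + W_RE * RevEngScore``, where a
  prior matrix entry ``rho_ij`` is the believed probability of a causal
  influence ``j -> i`` and ``beta_ij`` rewards the model for following it.

Knock-out series are scored against the knock-out model ``f*`` (the
silenced coordinate replaced by the zero function) and combined with the
wildtype contribution by total-bit-count weighting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data import KNOCKOUT, TimeSeriesSet
from .polynomial import BooleanPolynomial, PolynomialModel
from .search_space import SearchSpaceSpec, support_bound

__all__ = [
    "FitnessWeights",
    "PriorMatrix",
    "FitnessReport",
    "model_hamming",
    "coordinate_hamming",
    "complexity_score",
    "prior_score",
    "total_fitness",
]


@dataclass(frozen=True)
class FitnessWeights:
    """Weights of the fitness components (all non-negative, at least one
    positive).  Defaults favour data fit over the soft criteria."""

    w_hm: float = 1.0
    w_hp: float = 1.0
    w_c: float = 0.5
    w_b: float = 0.5
    w_re: float = 0.5

    def __post_init__(self) -> None:
        vals = (self.w_hm, self.w_hp, self.w_c, self.w_b, self.w_re)
        if any(w < 0 for w in vals):
            raise ValueError("fitness weights must be non-negative")
        if not any(w > 0 for w in vals):
            raise ValueError("at least one fitness weight must be positive")

    @classmethod
    def parsimony_safe(
        cls, total_rows: int, phi: int, w_hm: float = 1.0, w_hp: float = 1.0,
        w_b: float = 0.5, w_re: float = 0.5,
    ) -> "FitnessWeights":
        """Weights whose parsimony pressure can never outbid the data.

        The complexity weight is set to half of ``w_hp * Phi / total_rows``,
        so that raising a coordinate's degree by one (cost ``w_c / Phi``)
        is always worth less than fixing a single observed bit (gain
        ``w_hp / total_rows``): parsimony then only discriminates between
        equally well-fitting candidates instead of trading fit away.
        """
        if total_rows < 1 or phi < 0:
            raise ValueError("total_rows must be >= 1 and phi >= 0")
        w_c = 0.5 * w_hp * phi / total_rows if phi > 0 else 0.0
        return cls(w_hm=w_hm, w_hp=w_hp, w_c=w_c, w_b=w_b, w_re=w_re)


@dataclass
class PriorMatrix:
    """Prior probabilities of causal influences: ``rho[i, j]`` is the
    probability of an edge ``x_{j+1} -> x_{i+1}``.  ``source`` records
    whether it encodes biological knowledge or another method's output."""

    rho: np.ndarray
    source: str = "bio"

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        if self.rho.ndim != 2 or self.rho.shape[0] != self.rho.shape[1]:
            raise ValueError("prior matrix must be square")
        if ((self.rho < 0) | (self.rho > 1)).any():
            raise ValueError("prior probabilities must lie in [0, 1]")

    @property
    def n(self) -> int:
        return self.rho.shape[0]

    @classmethod
    def uninformative(cls, n: int, source: str = "bio") -> "PriorMatrix":
        return cls(np.full((n, n), 0.5), source=source)

    @classmethod
    def read_tsv(cls, path, source: str = "bio") -> "PriorMatrix":
        import pandas as pd

        df = pd.read_csv(str(path), sep="\t", index_col=0)
        return cls(df.to_numpy(dtype=float), source=source)

    def write_tsv(self, path, variables: Sequence[str] | None = None) -> None:
        import pandas as pd

        names = list(variables) if variables else [f"x{i + 1}" for i in range(self.n)]
        pd.DataFrame(self.rho, index=names, columns=names).to_csv(str(path), sep="\t")


@dataclass
class FitnessReport:
    """All fitness components of one candidate model."""

    h_f: float
    d_mu: list[int]
    model_fit: float
    h_fi: list[float]
    polynomial_fit: list[float]
    complexity: list[float]
    complexity_mean: float
    bio_score: float | None
    reveng_score: float | None
    total: float
    data_consistent: bool | None = None

    def to_dict(self) -> dict:
        return {
            "h_f": self.h_f,
            "d_mu": list(self.d_mu),
            "model_fit": self.model_fit,
            "h_fi": list(self.h_fi),
            "polynomial_fit": list(self.polynomial_fit),
            "complexity": list(self.complexity),
            "complexity_mean": self.complexity_mean,
            "bio_score": self.bio_score,
            "reveng_score": self.reveng_score,
            "total": self.total,
            "data_consistent": self.data_consistent,
        }


# ---------------------------------------------------------------------------
# Packed view of the data (shared by the public scorers and the EA loop)
# ---------------------------------------------------------------------------


class PackedData:
    """Bit-packed fragments for fast repeated scoring."""

    __slots__ = ("fragments", "n", "total_rows", "total_bits")

    def __init__(self, tss: TimeSeriesSet):
        self.n = tss.n
        self.fragments: list[tuple[list[int], int | None]] = []
        for ts in tss.series:
            ko = ts.ko_target if ts.kind == KNOCKOUT else None
            self.fragments.append((ts.packed_rows(), ko))
        self.total_rows = sum(len(rows) for rows, _ in self.fragments)
        self.total_bits = self.total_rows * self.n


def _model_hamming_packed(f: PolynomialModel, pd: PackedData) -> tuple[float, list[int]]:
    d_mu: list[int] = []
    ko_cache: dict[int, PolynomialModel] = {}
    for rows, ko in pd.fragments:
        g = f
        if ko is not None:
            g = ko_cache.setdefault(ko, f.knockout(ko))
        s = rows[0]
        d = 0
        for obs in rows[1:]:
            s = g.step_packed(s)
            d += (s ^ obs).bit_count()
        d_mu.append(d)
    return sum(d_mu) / pd.total_bits, d_mu


def _coordinate_hamming_packed(fi: BooleanPolynomial, i: int, pd: PackedData) -> float:
    mism = 0
    bit = 1 << i
    for rows, ko in pd.fragments:
        if ko == i:
            # the silenced coordinate predicts 0
            for obs in rows[1:]:
                if obs & bit:
                    mism += 1
        else:
            prev = rows[0]
            for obs in rows[1:]:
                if fi.evaluate_packed(prev) != ((obs >> i) & 1):
                    mism += 1
                prev = obs
    return mism / pd.total_rows


# ---------------------------------------------------------------------------
# Public scorers
# ---------------------------------------------------------------------------


def model_hamming(f: PolynomialModel, tss: TimeSeriesSet) -> tuple[float, list[int]]:
    """Free-run Hamming score ``H_f`` and per-series distances ``D_mu``.

    Each fragment is regenerated by iterating ``f`` (or the knock-out model
    ``f*`` for perturbation fragments) from its first time point; ``D_mu``
    counts mismatched bits over all ``alpha_mu`` rows (the first row matches
    by construction).  ``H_f = sum(D_mu) / (n * sum(alpha_mu))``, pooling
    wildtype and knock-out contributions by total bit count.
    """
    if f.n != tss.n:
        raise ValueError("model and data disagree on n")
    return _model_hamming_packed(f, PackedData(tss))


def coordinate_hamming(fi: BooleanPolynomial, i: int, tss: TimeSeriesSet) -> float:
    """One-step prediction score ``H_fi`` of a single coordinate function.

    For every observed transition, column ``i`` of the successor is
    predicted as ``f_i`` evaluated on the observed full predecessor state;
    on fragments that knock out node ``i`` itself the prediction is 0.
    ``H_fi = mismatches / sum(alpha_mu)``.
    """
    if not 0 <= i < tss.n:
        raise IndexError(f"coordinate index {i} out of range")
    if fi.n != tss.n:
        raise ValueError("coordinate and data disagree on n")
    return _coordinate_hamming_packed(fi, i, PackedData(tss))


def complexity_score(f: PolynomialModel, phi: int) -> tuple[list[float], float]:
    """Per-coordinate complexity ``total_degree / Phi`` and its mean.

    A degree above ``Phi`` signals a candidate outside the admissible space
    and raises.  ``Phi = 0`` with all-constant coordinates scores 0.
    """
    per: list[float] = []
    for i, p in enumerate(f.coords):
        deg = p.total_degree
        if deg > phi:
            raise ValueError(
                f"coordinate f{i + 1} has degree {deg} > Phi={phi}: outside the search space"
            )
        per.append(deg / phi if phi > 0 else 0.0)
    return per, float(np.mean(per))


def prior_score(f: PolynomialModel, prior: PriorMatrix) -> tuple[list[float], float]:
    """Agreement between the model's wiring diagram and a prior matrix.

    ``beta_ij = rho_ij`` where the model uses edge ``j -> i`` and
    ``1 - rho_ij`` where it does not; the coordinate score is the row mean
    of ``beta`` and the model score the mean over coordinates.
    """
    if prior.n != f.n:
        raise ValueError("prior matrix and model disagree on n")
    V = f.adjacency()
    beta = np.where(V == 1, prior.rho, 1.0 - prior.rho)
    per = beta.mean(axis=1)
    return [float(v) for v in per], float(per.mean())


def prior_row_score(fi: BooleanPolynomial, rho_row: np.ndarray) -> float:
    """Row-wise prior agreement of a single coordinate function."""
    v = np.zeros(fi.n, dtype=bool)
    for j in fi.support:
        v[j] = True
    beta = np.where(v, rho_row, 1.0 - rho_row)
    return float(beta.mean())


def total_fitness(
    f: PolynomialModel,
    tss: TimeSeriesSet,
    weights: FitnessWeights | None = None,
    spec: SearchSpaceSpec | None = None,
    bio_prior: PriorMatrix | None = None,
    reveng_prior: PriorMatrix | None = None,
    xi: float | None = None,
) -> FitnessReport:
    """Assemble the full multi-objective fitness of a candidate model.

    ``total = W_HM (1 - H_f) + W_HP mean_i(1 - H_fi) + W_C (1 - complexity)
    + W_B BioScore + W_RE RevEngScore``; a missing prior contributes 0.
    When ``xi`` is given (default: the data set's assumed noise fraction),
    the model is flagged *data-consistent* if ``H_f <= xi``.
    """
    weights = weights or FitnessWeights()
    if spec is None:
        spec = SearchSpaceSpec(n=tss.n, m=max(tss.total_length, 1))
    pd_ = PackedData(tss)
    h_f, d_mu = _model_hamming_packed(f, pd_)
    h_fi = [_coordinate_hamming_packed(p, i, pd_) for i, p in enumerate(f.coords)]
    per_c, c_mean = complexity_score(f, spec.phi)
    bio = prior_score(f, bio_prior)[1] if bio_prior is not None else None
    reveng = prior_score(f, reveng_prior)[1] if reveng_prior is not None else None
    total = (
        weights.w_hm * (1.0 - h_f)
        + weights.w_hp * float(np.mean([1.0 - h for h in h_fi]))
        + weights.w_c * (1.0 - c_mean)
        + (weights.w_b * bio if bio is not None else 0.0)
        + (weights.w_re * reveng if reveng is not None else 0.0)
    )
    tol = tss.xi if xi is None else xi
    return FitnessReport(
        h_f=h_f,
        d_mu=d_mu,
        model_fit=weights.w_hm * (1.0 - h_f),
        h_fi=h_fi,
        polynomial_fit=[weights.w_hp * (1.0 - h) for h in h_fi],
        complexity=per_c,
        complexity_mean=c_mean,
        bio_score=bio,
        reveng_score=reveng,
        total=total,
        data_consistent=h_f <= tol + 1e-12,
    )
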