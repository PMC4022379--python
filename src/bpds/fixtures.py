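"""Planted-model fixtures: random Boolean polynomial systems and the time
series they generate, so the full inference pipeline can be exercised
without any external data set.

The generator emulates the validation protocol of the method: a known
Boolean model is simulated from random initial states to produce wildtype
trajectories, knock-out trajectories are produced by the knock-out model of
randomly chosen targets, and a chosen fraction of bits may be flipped to
emulate measurement noise.  Defaults aim at roughly ten time points per
network variable, split over several short series, which is the data
regime the method is designed for.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import KNOCKOUT, WILDTYPE, TimeSeries, TimeSeriesSet, inject_noise
from .evaluation import GoldNetwork
from .polynomial import BooleanPolynomial, PolynomialModel
from .search_space import support_bound, total_length

__all__ = ["FixtureSpec", "random_model", "generate_series", "planted_fixture", "canned_fixtures"]


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for a planted-model experiment.

    Defaults: a 5-node network with at most two regulators per gene, five
    wildtype and two knock-out series of eight time points each (56 points,
    m = 49 transitions, so the support bound admits the planted monomials),
    noiseless.
    """

    n: int = 5
    max_in_degree: int = 2
    monomials_per_coordinate: tuple[int, int] = (1, 2)
    num_wildtype_series: int = 5
    num_ko_series: int = 2
    series_length: tuple[int, int] = (8, 8)
    xi: float = 0.0
    seed: int = 0
    allow_out_of_space: bool = False

    def __post_init__(self) -> None:
        if self.max_in_degree > self.n:
            raise ValueError("max_in_degree cannot exceed n")
        if self.series_length[0] < 2:
            raise ValueError("series must have length >= 2")
        if self.monomials_per_coordinate[0] < 1:
            raise ValueError("each coordinate needs at least one monomial")
        if not 0 <= self.xi < 1:
            raise ValueError("xi must lie in [0, 1)")


def random_model(spec: FixtureSpec, rng: np.random.Generator | None = None) -> PolynomialModel:
    """A random planted model: each coordinate uses at most
    ``max_in_degree`` regulators, combined into 1..k square-free monomials
    (possibly plus the constant 1, giving NOT-like rules)."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    lo, hi = spec.monomials_per_coordinate
    coords = []
    for _ in range(spec.n):
        d = int(rng.integers(1, spec.max_in_degree + 1))
        regulators = rng.choice(spec.n, size=d, replace=False)
        masks: set[int] = set()
        k = int(rng.integers(lo, hi + 1))
        attempts = 0
        while len(masks) < k and attempts < 20:
            attempts += 1
            size = int(rng.integers(1, d + 1))
            sub = rng.choice(regulators, size=size, replace=False)
            mask = 0
            for j in sub:
                mask |= 1 << int(j)
            masks.add(mask)
        if rng.random() < 0.3:
            masks.add(0)  # constant term: negation-like rule
        coords.append(BooleanPolynomial(masks, spec.n))
    return PolynomialModel(coords)


def generate_series(
    f: PolynomialModel, spec: FixtureSpec, rng: np.random.Generator | None = None
) -> tuple[TimeSeriesSet, list[tuple[int, int, int]]]:
    """Simulate wildtype and knock-out series from a planted model.

    Initial states are drawn uniformly; knock-out targets are distinct
    random nodes, each simulated under the knock-out model.  When
    ``spec.xi > 0`` exactly ``round(xi * points * n)`` bits are flipped.
    Refuses specs whose planted in-degree exceeds the support bound of the
    generated data (the planted model would sit outside the admissible
    search space) unless ``allow_out_of_space`` is set.

    Returns the (possibly noisy) series and the flipped positions.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    lo, hi = spec.series_length
    series: list[TimeSeries] = []
    for w in range(spec.num_wildtype_series):
        alpha = int(rng.integers(lo, hi + 1))
        s0 = rng.integers(0, 2, size=spec.n)
        traj = f.simulate(list(s0), alpha)
        series.append(TimeSeries(np.array(traj), kind=WILDTYPE, label=f"wt{w + 1}"))
    if spec.num_ko_series > spec.n:
        raise ValueError("cannot knock out more distinct targets than nodes")
    targets = rng.choice(spec.n, size=spec.num_ko_series, replace=False)
    for k, r in enumerate(int(t) for t in targets):
        alpha = int(rng.integers(lo, hi + 1))
        s0 = rng.integers(0, 2, size=spec.n)
        traj = f.knockout(r).simulate(list(s0), alpha)
        series.append(
            TimeSeries(np.array(traj), kind=KNOCKOUT, ko_target=r, label=f"ko{k + 1}")
        )
    tss = TimeSeriesSet(series, xi=spec.xi)
    phi = support_bound(tss.total_length)
    planted_degree = max(p.total_degree for p in f.coords)
    if planted_degree > phi and not spec.allow_out_of_space:
        raise ValueError(
            f"planted model degree {planted_degree} exceeds the data's support "
            f"bound Phi={phi}; recovery would be ill-posed "
            "(pass allow_out_of_space=True to override)"
        )
    flips: list[tuple[int, int, int]] = []
    if spec.xi > 0:
        tss, flips = inject_noise(tss, spec.xi, seed=rng.integers(2**31))
    return tss, flips


def planted_fixture(
    spec: FixtureSpec,
) -> tuple[PolynomialModel, GoldNetwork, TimeSeriesSet, list[tuple[int, int, int]]]:
    """Convenience bundle: planted model, its gold wiring diagram, and the
    generated (possibly noisy) series."""
    rng = np.random.default_rng(spec.seed)
    f = random_model(spec, rng)
    tss, flips = generate_series(f, spec, rng)
    gold = GoldNetwork.from_adjacency(f.adjacency())
    return f, gold, tss, flips


# ---------------------------------------------------------------------------
# Canned fixtures
# ---------------------------------------------------------------------------


def _toggle_oscillator() -> PolynomialModel:
    # 3-node toggle/oscillator: x1 and x2 repress each other, x3 follows x1
    return PolynomialModel.from_text(
        "f1 = x2 + 1\nf2 = x1 + 1\nf3 = x1\n"
    )


_IRMA_SHAPED_GENES = ["CBF1", "GAL4", "SWI5", "GAL80", "ASH1"]

# Synthetic 5-gene network shaped like the yeast IRMA benchmark (5 genes,
# 8 edges, a positive feedback loop SWI5 -> CBF1 -> GAL4 -> SWI5 and
# repressions by GAL80 and ASH1).  It is NOT the published network or data.
_IRMA_SHAPED_RULES = (
    "f1 = x3 + x5*x3\n"      # CBF1: activated by SWI5, repressed by ASH1
    "f2 = x1 + x4*x1\n"      # GAL4: activated by CBF1, repressed by GAL80
    "f3 = x2\n"              # SWI5: activated by GAL4
    "f4 = x3\n"              # GAL80: activated by SWI5
    "f5 = x3 + x4*x3\n"      # ASH1: activated by SWI5, repressed by GAL80
)


def _segment_polarity_shaped(n: int = 21) -> PolynomialModel:
    """A synthetic 21-variable model shaped like one parasegment of the fly
    segment-polarity system: sparse rules, gene -> protein chains and a few
    cross-repressions.  Structure only; not the published equations."""
    coords: list[BooleanPolynomial] = []
    for i in range(n):
        if i % 3 == 0:
            # "gene": activated by the previous block's protein, repressed
            # by its antagonist two blocks back
            a = (i - 1) % n
            b = (i - 7) % n
            p = BooleanPolynomial.parse(f"x{a + 1} + x{a + 1}*x{b + 1}", n)
        elif i % 3 == 1:
            # "protein": follows its gene
            p = BooleanPolynomial.parse(f"x{i}", n)  # x_i is 1-based name of idx i-1
        else:
            # "modified protein": needs the protein and a neighbour signal
            a = i - 1
            b = (i + 2) % n
            p = BooleanPolynomial.parse(f"x{a + 1}*x{b + 1}", n)
        coords.append(p)
    return PolynomialModel(coords)


def canned_fixtures() -> dict[str, dict]:
    """Three named small systems: a 3-node toggle/oscillator, a synthetic
    IRMA-shaped 5-gene network (with its gold wiring), and a synthetic
    21-variable parasegment-shaped model."""
    irma = PolynomialModel.from_text(_IRMA_SHAPED_RULES)
    out = {
        "toggle3": {
            "model": _toggle_oscillator(),
            "variables": ["x1", "x2", "x3"],
        },
        "irma_shaped": {
            "model": irma,
            "variables": list(_IRMA_SHAPED_GENES),
            "gold": GoldNetwork.from_adjacency(irma.adjacency()),
        },
        "parasegment_shaped": {
            "model": _segment_polarity_shaped(),
            "variables": [f"x{i + 1}" for i in range(21)],
        },
    }
    for entry in out.values():
        entry.setdefault("gold", GoldNetwork.from_adjacency(entry["model"].adjacency()))
    return out
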