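"""Evolutionary search for Boolean polynomial models.

The optimization is split coordinate-wise (divide and conquer): under a
synchronous update, predicting node ``i`` at time ``t`` needs only the full
observed state at ``t - 1``, so each coordinate function can be scored on
its own one-step fit.  The engine therefore maintains per-coordinate pools
of candidate polynomials, assembles whole models from them by n-point
crossover (one tournament per coordinate), scores the assembled models on
the full multi-objective fitness, clones an elite fraction unchanged into
the next generation, and mutates the rest by adding, removing or replacing
monomial terms drawn from the admissible set ``M``.

Every candidate ever constructed lies inside the restricted search space:
monomials are only drawn from ``M`` and coordinate sizes are capped.  A
single root seed drives all randomness, so identical inputs and
configuration reproduce the run bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .data import TimeSeriesSet, break_inconsistencies
from .polynomial import BooleanPolynomial, PolynomialModel
from .scoring import (
    FitnessReport,
    FitnessWeights,
    PackedData,
    PriorMatrix,
    _coordinate_hamming_packed,
    _model_hamming_packed,
    prior_row_score,
    prior_score,
)
from .search_space import SearchSpaceSpec

__all__ = [
    "EAConfig",
    "InferenceResult",
    "init_population",
    "mutate",
    "crossover_assemble",
    "evolve",
    "infer",
    "lhs_sample",
]


@dataclass(frozen=True)
class EAConfig:
    """Hyper-parameters of the evolutionary algorithm.

    ``xi`` is the tolerated noise fraction: a model whose free-run Hamming
    score ``H_f`` is at most ``xi`` is flagged data-consistent, and the run
    may stop early once such a model exists and the best total fitness has
    stagnated.
    """

    population_size: int = 200
    generations: int = 500
    mutation_rate: float = 0.2
    crossover_rate: float = 0.8
    clone_fraction: float = 0.05
    tournament_size: int = 3
    max_monomials_per_coordinate: int = 8
    weights: FitnessWeights = field(default_factory=FitnessWeights)
    xi: float = 0.05
    seed: int = 0
    output_family_size: int = 10
    stagnation_generations: int = 20
    stagnation_tol: float = 1e-9
    local_search: bool = True
    local_search_moves: int = 64

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        for name in ("mutation_rate", "crossover_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0 <= self.clone_fraction < 1:
            raise ValueError("clone_fraction must lie in [0, 1)")
        if self.tournament_size < 1 or self.max_monomials_per_coordinate < 1:
            raise ValueError("tournament_size and max_monomials_per_coordinate must be >= 1")
        if not 0 <= self.xi < 1:
            raise ValueError("xi must lie in [0, 1)")

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__ if k != "weights"}
        d["weights"] = {
            "w_hm": self.weights.w_hm,
            "w_hp": self.weights.w_hp,
            "w_c": self.weights.w_c,
            "w_b": self.weights.w_b,
            "w_re": self.weights.w_re,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EAConfig":
        d = dict(d)
        w = d.pop("weights", None)
        if w is not None:
            d["weights"] = FitnessWeights(**w)
        return cls(**d)


@dataclass
class InferenceResult:
    """Ranked family of inferred models with their fitness reports, the
    consensus wiring diagram (edge frequency over the family) and the run's
    provenance (search space, configuration, per-generation best fitness)."""

    family: list[tuple[PolynomialModel, FitnessReport]]
    consensus_adjacency: np.ndarray
    search_space: SearchSpaceSpec
    config: EAConfig
    log: list[float]
    generations_run: int

    @property
    def best_model(self) -> PolynomialModel:
        return self.family[0][0]

    @property
    def best_report(self) -> FitnessReport:
        return self.family[0][1]

    def consensus_edges(self, threshold: float = 0.5) -> np.ndarray:
        """Binary consensus network: edges present in at least ``threshold``
        of the family."""
        return (self.consensus_adjacency >= threshold).astype(np.int8)


# ---------------------------------------------------------------------------
# Variation operators
# ---------------------------------------------------------------------------


def _random_monomial_mask(
    masks: Sequence[int], phi: int, rho_row: np.ndarray | None, rng: np.random.Generator
) -> int:
    """A random monomial from M.

    Uniform over M without a prior.  With a prior row, the degree is drawn
    uniformly on 1..Phi and each variable slot sampled with weight
    ``max(rho_ij, 0.05)`` (with replacement; repeats collapse), so believed
    regulators dominate the sampled supports.
    """
    if rho_row is None or phi == 0:
        return masks[rng.integers(len(masks))]
    w = np.maximum(rho_row, 0.05)
    w = w / w.sum()
    d = int(rng.integers(1, phi + 1))
    mask = 0
    for j in rng.choice(len(rho_row), size=d, replace=True, p=w):
        mask |= 1 << int(j)
    return mask


def _random_polynomial(
    masks: Sequence[int],
    phi: int,
    rho_row: np.ndarray | None,
    config: EAConfig,
    rng: np.random.Generator,
    n: int,
) -> BooleanPolynomial:
    # size ~ geometric: regulatory rules are sparse, so small candidates
    # dominate the sampling while large ones stay reachable
    k = min(int(rng.geometric(0.5)), config.max_monomials_per_coordinate)
    chosen: set[int] = set()
    for _ in range(k):
        chosen ^= {_random_monomial_mask(masks, phi, rho_row, rng)}
    return BooleanPolynomial(chosen, n)


def init_population(
    spec: SearchSpaceSpec,
    config: EAConfig,
    prior: PriorMatrix | None = None,
    rng: np.random.Generator | None = None,
) -> list[list[BooleanPolynomial]]:
    """Seeded initial per-coordinate candidate pools.

    Every candidate is a random subset of 1..max_monomials_per_coordinate
    monomials of ``M``; with a prior, monomial supports are biased toward
    the believed regulators of each coordinate.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    pools: list[list[BooleanPolynomial]] = []
    for i in range(spec.n):
        masks = [mono.mask for mono in spec.monomials(i)]
        rho_row = prior.rho[i] if prior is not None else None
        pools.append(
            [
                _random_polynomial(masks, spec.phi_for(i), rho_row, config, rng, spec.n)
                for _ in range(config.population_size)
            ]
        )
    return pools


def mutate(
    p: BooleanPolynomial,
    masks: Sequence[int],
    config: EAConfig,
    rng: np.random.Generator,
) -> BooleanPolynomial:
    """With probability ``mutation_rate``, add, remove or replace one
    monomial term (uniform choice among the applicable operations); the
    result stays inside ``M`` and under the per-coordinate size cap."""
    if rng.random() >= config.mutation_rate:
        return p
    current = set(p.masks)
    ops = []
    if len(current) < config.max_monomials_per_coordinate:
        ops.append("add")
    if current:
        ops.append("remove")
        ops.append("replace")
    if not ops:
        return p
    op = ops[int(rng.integers(len(ops)))]
    if op in ("remove", "replace"):
        victim = sorted(current)[int(rng.integers(len(current)))]
        current.discard(victim)
    if op in ("add", "replace"):
        current ^= {masks[int(rng.integers(len(masks)))]}
    return BooleanPolynomial(current, p.n)


def _force_mutate(
    p: BooleanPolynomial,
    masks: Sequence[int],
    config: EAConfig,
    rng: np.random.Generator,
) -> BooleanPolynomial:
    """Unconditionally apply one variation op (used for pool offspring)."""
    forced = replace(config, mutation_rate=1.0)
    return mutate(p, masks, forced, rng)


def _tournament(
    scores: Sequence[float], k: int, rng: np.random.Generator
) -> int:
    idx = rng.integers(len(scores), size=min(k, len(scores)))
    best = int(idx[0])
    for j in idx[1:]:
        if scores[int(j)] > scores[best]:
            best = int(j)
    return best


def crossover_assemble(
    pools: Sequence[Sequence[BooleanPolynomial]],
    coord_scores: Sequence[Sequence[float]],
    config: EAConfig,
    rng: np.random.Generator,
) -> PolynomialModel:
    """n-point crossover: assemble a model by drawing coordinate ``i`` from
    pool ``i`` with a tournament on the coordinate-level fitness."""
    coords = [
        pools[i][_tournament(coord_scores[i], config.tournament_size, rng)]
        for i in range(len(pools))
    ]
    return PolynomialModel(coords)


# ---------------------------------------------------------------------------
# Main loop
# ---------------------------------------------------------------------------


def _rank_key(item: tuple[PolynomialModel, FitnessReport]) -> tuple:
    model, rep = item
    return (-rep.total, rep.complexity_mean, model.key())


def evolve(
    tss: TimeSeriesSet,
    config: EAConfig | None = None,
    bio_prior: PriorMatrix | None = None,
    reveng_prior: PriorMatrix | None = None,
    spec: SearchSpaceSpec | None = None,
) -> InferenceResult:
    """Run the evolutionary algorithm on an inconsistency-free data set.

    The loop per generation: (1) score the coordinate pools on one-step fit
    plus prior-row agreement and parsimony; (2) assemble models by n-point
    crossover (or clone-and-mutate a tournament-selected parent); (3) score
    the assembled models on the full fitness; (4) keep the elite unchanged
    and select the next population from parents and offspring; (5) mutate
    the non-elite pool entries.  Stops when the generation budget is spent,
    or when a data-consistent model (``H_f <= xi``) exists and the best
    total fitness has not improved for ``stagnation_generations``.
    """
    config = config or EAConfig()
    m = tss.total_length
    if m < 1:
        raise ValueError("no transitions in the data (m = 0): nothing to infer")
    if spec is None:
        spec = SearchSpaceSpec(n=tss.n, m=m)
    n = tss.n
    rng = np.random.default_rng(config.seed)
    packed = PackedData(tss)
    weights = config.weights
    coord_masks = [[mono.mask for mono in spec.monomials(i)] for i in range(n)]
    init_prior = bio_prior if bio_prior is not None else reveng_prior

    pools = init_population(spec, config, prior=init_prior, rng=rng)

    coord_cache: dict[tuple[int, frozenset[int]], float] = {}
    model_cache: dict[str, FitnessReport] = {}

    def coord_score(p: BooleanPolynomial, i: int) -> float:
        key = (i, p.masks)
        s = coord_cache.get(key)
        if s is None:
            h = _coordinate_hamming_packed(p, i, packed)
            phi_i = spec.phi_for(i)
            c = p.total_degree / phi_i if phi_i > 0 else 0.0
            s = weights.w_hp * (1.0 - h) + weights.w_c * (1.0 - c)
            if bio_prior is not None:
                s += weights.w_b * prior_row_score(p, bio_prior.rho[i])
            if reveng_prior is not None:
                s += weights.w_re * prior_row_score(p, reveng_prior.rho[i])
            coord_cache[key] = s
        return s

    def model_report(model: PolynomialModel) -> FitnessReport:
        key = model.key()
        rep = model_cache.get(key)
        if rep is None:
            h_f, d_mu = _model_hamming_packed(model, packed)
            h_fi = [_coordinate_hamming_packed(p, i, packed) for i, p in enumerate(model.coords)]
            per_c = [
                (p.total_degree / spec.phi_for(i) if spec.phi_for(i) > 0 else 0.0)
                for i, p in enumerate(model.coords)
            ]
            c_mean = float(np.mean(per_c))
            bio = prior_score(model, bio_prior)[1] if bio_prior is not None else None
            reveng = prior_score(model, reveng_prior)[1] if reveng_prior is not None else None
            total = (
                weights.w_hm * (1.0 - h_f)
                + weights.w_hp * float(np.mean([1.0 - h for h in h_fi]))
                + weights.w_c * (1.0 - c_mean)
                + (weights.w_b * bio if bio is not None else 0.0)
                + (weights.w_re * reveng if reveng is not None else 0.0)
            )
            rep = FitnessReport(
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
                data_consistent=h_f <= config.xi + 1e-12,
            )
            model_cache[key] = rep
        return rep

    def polish(model: PolynomialModel) -> PolynomialModel:
        """Memetic step: coordinate-wise hill-climbing on the coordinate
        fitness by toggling single monomials of M (full scan when M is
        small, a seeded random sample of moves otherwise)."""
        coords = list(model.coords)
        for i in range(n):
            while True:
                base = coord_score(coords[i], i)
                moves = coord_masks[i]
                if len(moves) > config.local_search_moves:
                    idx = rng.choice(len(moves), size=config.local_search_moves, replace=False)
                    moves = [moves[int(j)] for j in idx]
                best_p, best_s = coords[i], base
                for mask in moves:
                    masks_new = coords[i].masks ^ {mask}
                    if len(masks_new) > config.max_monomials_per_coordinate:
                        continue
                    cand = BooleanPolynomial(masks_new, n)
                    s = coord_score(cand, i)
                    if s > best_s + 1e-12:
                        best_p, best_s = cand, s
                if best_p is coords[i]:
                    break
                coords[i] = best_p
        return PolynomialModel(coords)

    P = config.population_size
    n_elite = max(1, int(round(config.clone_fraction * P)))
    population: list[tuple[PolynomialModel, FitnessReport]] = []
    log: list[float] = []
    gens_run = 0

    for gen in range(config.generations):
        gens_run = gen + 1
        coord_scores = [[coord_score(p, i) for p in pools[i]] for i in range(n)]

        offspring: list[PolynomialModel] = []
        model_scores = [rep.total for _, rep in population]
        while len(offspring) < P:
            if not population or rng.random() < config.crossover_rate:
                child = crossover_assemble(pools, coord_scores, config, rng)
            else:
                parent = population[_tournament(model_scores, config.tournament_size, rng)][0]
                child = PolynomialModel(
                    [mutate(p, coord_masks[i], config, rng) for i, p in enumerate(parent.coords)]
                )
            offspring.append(child)
        if config.local_search and population:
            offspring.append(polish(population[0][0]))

        merged: dict[str, tuple[PolynomialModel, FitnessReport]] = {}
        for model, rep in population:
            merged.setdefault(model.key(), (model, rep))
        for model in offspring:
            merged.setdefault(model.key(), (model, model_report(model)))
        population = sorted(merged.values(), key=_rank_key)[:P]
        best = population[0][1]
        log.append(best.total)

        # evolve each pool on its own coordinate fitness: elites survive
        # unchanged, surviving models feed their coordinates back in, the
        # rest comes from tournament-selected mutants plus a little fresh
        # random blood
        n_fresh = max(1, P // 20)
        for i in range(n):
            scores_i = coord_scores[i]
            order = sorted(
                range(len(pools[i])), key=lambda j: (-scores_i[j], str(pools[i][j]))
            )
            new_pool = [pools[i][j] for j in order[:n_elite]]
            for model, _ in population[:n_elite]:
                new_pool.append(model.coords[i])
            while len(new_pool) < P - n_fresh:
                parent = pools[i][_tournament(scores_i, config.tournament_size, rng)]
                new_pool.append(_force_mutate(parent, coord_masks[i], config, rng))
            while len(new_pool) < P:
                new_pool.append(
                    _random_polynomial(
                        coord_masks[i],
                        spec.phi_for(i),
                        init_prior.rho[i] if init_prior is not None else None,
                        config,
                        rng,
                        n,
                    )
                )
            pools[i] = new_pool[:P]

        g0 = gen - config.stagnation_generations
        if (
            best.h_f <= config.xi + 1e-12
            and g0 >= 0
            and log[-1] - log[g0] < config.stagnation_tol
        ):
            break

    family = population[: config.output_family_size]
    consensus = np.mean([model.adjacency() for model, _ in family], axis=0)
    return InferenceResult(
        family=family,
        consensus_adjacency=consensus,
        search_space=spec,
        config=config,
        log=log,
        generations_run=gens_run,
    )


def infer(
    tss: TimeSeriesSet,
    config: EAConfig | None = None,
    bio_prior: PriorMatrix | None = None,
    reveng_prior: PriorMatrix | None = None,
) -> InferenceResult:
    """Top-level entry point: break inconsistencies, then evolve."""
    return evolve(
        break_inconsistencies(tss),
        config=config,
        bio_prior=bio_prior,
        reveng_prior=reveng_prior,
    )


# ---------------------------------------------------------------------------
# Latin hypercube sampling of EA parameters
# ---------------------------------------------------------------------------

_INT_PARAMS = {
    "population_size",
    "generations",
    "tournament_size",
    "max_monomials_per_coordinate",
    "output_family_size",
    "stagnation_generations",
}
_WEIGHT_PARAMS = {"w_hm", "w_hp", "w_c", "w_b", "w_re"}


def lhs_sample(
    param_ranges: dict[str, tuple[float, float]],
    n_sets: int,
    seed: int = 0,
    base: EAConfig | None = None,
) -> list[EAConfig]:
    """Latin hypercube sample of EA parameter sets.

    Each parameter's range is split into ``n_sets`` equal strata with one
    uniform draw per stratum, and the strata are permuted independently per
    parameter, so every one-dimensional projection covers the whole range.
    Integer-valued parameters are rounded.  Weight names (``w_hm`` ...)
    address the fitness weights.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    base = base or EAConfig()
    rng = np.random.default_rng(seed)
    samples: dict[str, np.ndarray] = {}
    for name in sorted(param_ranges):
        lo, hi = param_ranges[name]
        strata = rng.permutation(n_sets)
        u = rng.random(n_sets)
        samples[name] = lo + (strata + u) / n_sets * (hi - lo)
    configs = []
    for k in range(n_sets):
        overrides: dict[str, object] = {}
        wd = {
            "w_hm": base.weights.w_hm,
            "w_hp": base.weights.w_hp,
            "w_c": base.weights.w_c,
            "w_b": base.weights.w_b,
            "w_re": base.weights.w_re,
        }
        touched_w = False
        for name, vals in samples.items():
            v = float(vals[k])
            if name in _WEIGHT_PARAMS:
                wd[name] = v
                touched_w = True
            elif name in _INT_PARAMS:
                overrides[name] = int(round(v))
            else:
                overrides[name] = v
        if touched_w:
            overrides["weights"] = FitnessWeights(**wd)
        configs.append(replace(base, **overrides))
    return configs
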