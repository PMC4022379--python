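"""Evolutionary engine: operators, reproducibility, convergence, LHS."""

import numpy as np
import pytest

from bpds import (
    EAConfig,
    FitnessWeights,
    FixtureSpec,
    PriorMatrix,
    SearchSpaceSpec,
    compare_networks,
    infer,
    lhs_sample,
    planted_fixture,
)
from bpds.ea import crossover_assemble, evolve, init_population, mutate
from bpds.search_space import support_bound


def small_config(seed=0, xi=0.0, **kw):
    kw.setdefault("population_size", 40)
    kw.setdefault("generations", 120)
    return EAConfig(seed=seed, xi=xi, **kw)


class TestInitPopulation:
    def test_contracts(self):
        spec = SearchSpaceSpec(n=5, m=49)
        cfg = small_config()
        pools = init_population(spec, cfg)
        assert len(pools) == 5 and all(len(p) == cfg.population_size for p in pools)
        for pool in pools:
            for poly in pool:
                assert poly.total_degree <= spec.phi
                assert 0 < len(poly.masks) <= cfg.max_monomials_per_coordinate or poly.is_zero

    def test_seed_reproducible(self):
        spec = SearchSpaceSpec(n=4, m=20)
        a = init_population(spec, small_config(seed=5))
        b = init_population(spec, small_config(seed=5))
        assert a == b

    def test_prior_bias_concentrates_on_believed_regulator(self):
        """With rho row (1, 0) nearly all sampled monomials for that
        coordinate involve only the believed regulator."""
        spec = SearchSpaceSpec(n=2, m=4)  # phi = 2
        prior = PriorMatrix(np.array([[1.0, 0.0], [0.5, 0.5]]))
        cfg = EAConfig(population_size=1000, generations=1, max_monomials_per_coordinate=1)
        rng = np.random.default_rng(0)
        pools = init_population(spec, cfg, prior=prior, rng=rng)
        only_x1 = sum(1 for p in pools[0] if p.support == frozenset({0}))
        assert only_x1 / len(pools[0]) >= 0.9


class TestMutate:
    def test_rate_zero_is_identity(self):
        spec = SearchSpaceSpec(n=4, m=20)
        masks = [m.mask for m in spec.monomials()]
        cfg = small_config(mutation_rate=0.0)
        rng = np.random.default_rng(1)
        pools = init_population(spec, cfg, rng=rng)
        for p in pools[0]:
            assert mutate(p, masks, cfg, rng) == p

    def test_stays_in_space_and_under_cap(self):
        spec = SearchSpaceSpec(n=5, m=20)  # phi = 4
        masks = [m.mask for m in spec.monomials()]
        cfg = small_config(mutation_rate=1.0, max_monomials_per_coordinate=3)
        rng = np.random.default_rng(2)
        pools = init_population(spec, replace_cap(cfg, 3), rng=rng)
        for p in pools[0]:
            q = p
            for _ in range(20):
                q = mutate(q, masks, cfg, rng)
                assert q.total_degree <= spec.phi
                assert len(q.masks) <= 3

    def test_seeded_double_run_identical(self):
        spec = SearchSpaceSpec(n=4, m=16)
        masks = [m.mask for m in spec.monomials()]
        cfg = small_config(mutation_rate=1.0)
        p = init_population(spec, cfg, rng=np.random.default_rng(3))[0][0]
        out1 = mutate(p, masks, cfg, np.random.default_rng(7))
        out2 = mutate(p, masks, cfg, np.random.default_rng(7))
        assert out1 == out2


def replace_cap(cfg, cap):
    from dataclasses import replace

    return replace(cfg, max_monomials_per_coordinate=cap)


class TestCrossover:
    def test_singleton_pools_give_unique_model(self):
        from bpds import BooleanPolynomial

        pools = [[BooleanPolynomial.parse("x2", 2)], [BooleanPolynomial.parse("x1", 2)]]
        model = crossover_assemble(pools, [[1.0], [1.0]], small_config(), np.random.default_rng(0))
        assert [str(p) for p in model.coords] == ["x2", "x1"]

    def test_coordinates_come_from_their_pools(self):
        spec = SearchSpaceSpec(n=3, m=10)
        cfg = small_config()
        rng = np.random.default_rng(4)
        pools = init_population(spec, cfg, rng=rng)
        scores = [[0.0] * len(p) for p in pools]
        for _ in range(10):
            model = crossover_assemble(pools, scores, cfg, rng)
            for i, p in enumerate(model.coords):
                assert p in pools[i]

    def test_planted_coordinates_assemble_to_planted_model(self, planted5):
        model, gold, tss, _ = planted5
        pools = [[p] for p in model.coords]
        assembled = crossover_assemble(
            pools, [[1.0]] * model.n, small_config(), np.random.default_rng(0)
        )
        assert assembled == model


class TestEvolve:
    def test_rejects_empty_data(self):
        import bpds

        tss = bpds.TimeSeriesSet([bpds.TimeSeries(np.array([[0, 1]]))])
        with pytest.raises(ValueError):
            evolve(tss, small_config())

    def test_reproducible(self, planted5):
        _, _, tss, _ = planted5
        cfg = small_config(seed=9, generations=15)
        r1 = evolve(tss, cfg)
        r2 = evolve(tss, cfg)
        assert r1.best_model == r2.best_model
        assert r1.log == r2.log
        assert (r1.consensus_adjacency == r2.consensus_adjacency).all()

    def test_elitism_best_fitness_never_decreases(self, planted5):
        _, _, tss, _ = planted5
        res = evolve(tss, small_config(seed=2, generations=40))
        assert all(b >= a - 1e-12 for a, b in zip(res.log, res.log[1:]))

    def test_all_family_models_in_restricted_space(self, planted5):
        _, _, tss, _ = planted5
        res = evolve(tss, small_config(seed=3, generations=20))
        for model, rep in res.family:
            assert max(p.total_degree for p in model.coords) <= res.search_space.phi
        totals = [rep.total for _, rep in res.family]
        assert totals == sorted(totals, reverse=True)

    def test_noiseless_fixture_reaches_exact_fit(self):
        """On the noiseless planted 5-node fixture the best model attains
        H_f = 0 in at least 2 of 3 seeded replicates."""
        model, gold, tss, _ = planted_fixture(FixtureSpec(seed=21))
        w = FitnessWeights.parsimony_safe(tss.total_points, support_bound(tss.total_length))
        hits = 0
        for seed in range(3):
            res = infer(tss, config=small_config(seed=seed, weights=w))
            hits += res.best_report.h_f == 0.0
        assert hits >= 2

    def test_full_topology_prior_gives_full_consensus_recall(self):
        """With the true wiring supplied as a certain biological prior the
        consensus network recovers every planted edge."""
        model, gold, tss, _ = planted_fixture(FixtureSpec(seed=22))
        prior = PriorMatrix(model.adjacency().astype(float))
        w = FitnessWeights.parsimony_safe(
            tss.total_points, support_bound(tss.total_length), w_b=1.0
        )
        res = infer(tss, config=small_config(seed=1, weights=w), bio_prior=prior)
        met = compare_networks(res.consensus_edges(), gold, include_self_loops=True)
        assert met.recall == 1.0


class TestLHS:
    def test_one_sample_per_stratum(self):
        cfgs = lhs_sample({"mutation_rate": (0.0, 1.0)}, 4, seed=0)
        vals = sorted(c.mutation_rate for c in cfgs)
        for k, v in enumerate(vals):
            assert k / 4 <= v < (k + 1) / 4

    def test_projection_property_five_parameters(self):
        ranges = {
            "mutation_rate": (0.0, 1.0),
            "crossover_rate": (0.5, 1.0),
            "clone_fraction": (0.0, 0.3),
            "population_size": (20, 220),
            "w_c": (0.0, 1.0),
        }
        n_sets = 6
        cfgs = lhs_sample(ranges, n_sets, seed=3)
        assert len(cfgs) == n_sets
        for name, (lo, hi) in ranges.items():
            if name == "w_c":
                vals = [c.weights.w_c for c in cfgs]
            else:
                vals = [getattr(c, name) for c in cfgs]
            strata = sorted(int((v - lo) / (hi - lo) * n_sets) for v in vals)
            strata = [min(s, n_sets - 1) for s in strata]
            assert strata == list(range(n_sets))
        assert all(isinstance(c.population_size, int) for c in cfgs)

    def test_seed_reproducible(self):
        a = lhs_sample({"xi": (0.0, 0.2)}, 5, seed=11)
        b = lhs_sample({"xi": (0.0, 0.2)}, 5, seed=11)
        assert [c.xi for c in a] == [c.xi for c in b]
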