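"""Containers, inconsistency breaking, noise injection, discretization, I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bpds import (
    ContinuousTimeSeries,
    TimeSeries,
    TimeSeriesSet,
    break_inconsistencies,
    discretize_interval,
    discretize_quantile,
    find_inconsistencies,
    inject_noise,
    read_timeseries,
    write_timeseries,
)


def tss_from_rows(*series, **kw):
    return TimeSeriesSet([TimeSeries(np.array(rows), label=f"s{i+1}") for i, rows in enumerate(series)], **kw)


class TestContainers:
    def test_counts(self, small_tss):
        assert small_tss.n == 3
        assert small_tss.mu0 == 3
        assert small_tss.ell == 2
        assert small_tss.total_points == 10
        assert small_tss.total_length == 7

    def test_validation(self):
        with pytest.raises(ValueError):
            TimeSeries(np.array([[0, 2]]))
        with pytest.raises(ValueError):
            TimeSeries(np.array([[0, 1]]), kind="knockout")  # missing target
        with pytest.raises(ValueError):
            TimeSeries(np.array([[0, 1]]), ko_target=0)  # target on wildtype
        with pytest.raises(ValueError):
            TimeSeriesSet([TimeSeries(np.zeros((2, 2)))], xi=1.0)


class TestInconsistencies:
    def test_across_series(self):
        tss = tss_from_rows([[0, 0], [1, 0]], [[0, 0], [0, 1]])
        found = find_inconsistencies(tss)
        assert len(found) == 1
        _, state, succ = found[0]
        assert state == (0, 0) and len(succ) == 2

    def test_deterministic_trajectory_is_clean(self, small_tss):
        assert find_inconsistencies(small_tss) == []

    def test_within_series(self):
        # u -> v and later u -> w
        tss = tss_from_rows([[0, 0], [1, 0], [0, 0], [1, 1]])
        found = find_inconsistencies(tss)
        assert [f[1] for f in found] == [(0, 0)]

    def test_knockout_pools_are_separate(self):
        # same state, different successors -- but in different KO pools
        a = TimeSeries(np.array([[0, 0], [1, 0]]), kind="knockout", ko_target=0, label="a")
        b = TimeSeries(np.array([[0, 0], [0, 1]]), kind="knockout", ko_target=1, label="b")
        assert find_inconsistencies(TimeSeriesSet([a, b])) == []


class TestBreaking:
    def test_all_transitions_from_bad_state_removed(self):
        tss = tss_from_rows([[0, 0], [1, 0], [0, 0], [1, 1]])  # u,v,u,w
        broken = break_inconsistencies(tss)
        lengths = sorted(ts.alpha for ts in broken.series)
        # fragments [u], [v,u], [w]: only one transition remains
        assert lengths == [1, 1, 2]
        assert broken.total_length == 1
        frag = next(ts for ts in broken.series if ts.alpha == 2)
        assert frag.points.tolist() == [[1, 0], [0, 0]]

    def test_consistent_set_unchanged(self, small_tss):
        assert break_inconsistencies(small_tss) is small_tss

    def test_conflicting_pair_loses_everything(self):
        tss = tss_from_rows([[0, 0], [1, 0]], [[0, 0], [0, 1]])
        broken = break_inconsistencies(tss)
        assert broken.total_length == 0

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        tss = tss_from_rows(rng.integers(0, 2, (8, 3)), rng.integers(0, 2, (8, 3)))
        once = break_inconsistencies(tss)
        assert find_inconsistencies(once) == []
        twice = break_inconsistencies(once)
        assert [t.points.tolist() for t in twice.series] == [
            t.points.tolist() for t in once.series
        ]


class TestNoise:
    def test_zero_noise_is_identity(self, small_tss):
        noisy, flips = inject_noise(small_tss, 0.0, seed=1)
        assert flips == []
        assert all(
            (a.points == b.points).all() for a, b in zip(noisy.series, small_tss.series)
        )

    def test_flip_count_follows_protocol(self):
        # 202 time points on 21 variables at 5% noise: round(0.05*202*21) = 212
        rng = np.random.default_rng(2)
        series = [TimeSeries(rng.integers(0, 2, (101, 21)), label=f"s{i}") for i in range(2)]
        tss = TimeSeriesSet(series)
        noisy, flips = inject_noise(tss, 0.05, seed=3)
        assert len(flips) == 212
        ham = sum(
            int((a.points != b.points).sum()) for a, b in zip(noisy.series, tss.series)
        )
        assert ham == 212  # distinct positions: Hamming distance == flip count

    def test_seeded_reproducibility(self, small_tss):
        f1 = inject_noise(small_tss, 0.2, seed=11)[1]
        f2 = inject_noise(small_tss, 0.2, seed=11)[1]
        assert f1 == f2

    def test_invalid_xi(self, small_tss):
        with pytest.raises(ValueError):
            inject_noise(small_tss, 1.0, seed=0)


class TestDiscretization:
    def test_quantile_binary(self):
        cts = ContinuousTimeSeries(np.array([[1.0], [2.0], [3.0], [4.0]]))
        assert discretize_quantile(cts, 2).points.ravel().tolist() == [0, 0, 1, 1]

    def test_quantile_constant_column(self):
        cts = ContinuousTimeSeries(np.full((4, 1), 3.3))
        assert discretize_quantile(cts, 2).points.ravel().tolist() == [0, 0, 0, 0]

    def test_quantile_ternary(self):
        cts = ContinuousTimeSeries(np.array([[0.0], [10.0], [20.0], [30.0], [40.0], [50.0]]))
        out = discretize_quantile(cts, 3)
        assert out.points.ravel().tolist() == [0, 0, 1, 1, 2, 2]

    def test_interval(self):
        assert discretize_interval(
            ContinuousTimeSeries(np.array([[0.0], [1.0], [2.0], [3.0]])), 2
        ).points.ravel().tolist() == [0, 0, 1, 1]
        assert discretize_interval(
            ContinuousTimeSeries(np.array([[0.0], [0.4], [2.0]])), 2
        ).points.ravel().tolist() == [0, 0, 1]
        assert discretize_interval(
            ContinuousTimeSeries(np.full((3, 1), 7.0)), 2
        ).points.ravel().tolist() == [0, 0, 0]

    def test_invalid_levels(self):
        cts = ContinuousTimeSeries(np.zeros((2, 1)))
        with pytest.raises(ValueError):
            discretize_quantile(cts, 1)
        with pytest.raises(ValueError):
            discretize_interval(cts, 1)

    def test_pooling_across_series(self):
        a = ContinuousTimeSeries(np.array([[0.0], [1.0]]))
        b = ContinuousTimeSeries(np.array([[2.0], [3.0]]))
        out = discretize_quantile([a, b], 2)
        assert out[0].points.ravel().tolist() == [0, 0]
        assert out[1].points.ravel().tolist() == [1, 1]

    @settings(derandomize=True, max_examples=40)
    @given(
        vals=st.lists(
            st.floats(-50, 50, allow_nan=False).map(lambda v: round(v, 3)),
            min_size=4,
            max_size=12,
            unique=True,
        )
    )
    def test_quantile_invariant_under_monotone_transforms(self, vals):
        col = np.array(vals)[:, None]
        base = discretize_quantile(ContinuousTimeSeries(col), 2).points.tolist()
        for g in (lambda x: x**3, lambda x: np.exp(x / 60.0), lambda x: 2 * x + 5):
            t = discretize_quantile(ContinuousTimeSeries(g(col)), 2).points.tolist()
            assert t == base


class TestIO:
    def make_sets(self):
        rng = np.random.default_rng(9)
        wt_only = TimeSeriesSet(
            [TimeSeries(rng.integers(0, 2, (5, 3)), label=f"wt{i}") for i in range(2)]
        )
        mixed = TimeSeriesSet(
            [
                TimeSeries(rng.integers(0, 2, (4, 3)), label="wt1"),
                TimeSeries(rng.integers(0, 2, (4, 3)), kind="knockout", ko_target=2, label="ko1"),
            ],
            xi=0.05,
        )
        fragments = break_inconsistencies(
            tss_from_rows([[0, 0], [1, 0], [0, 0], [1, 1]])
        )
        return [wt_only, mixed, fragments]

    def test_round_trip_byte_identical(self, tmp_path):
        for k, tss in enumerate(self.make_sets()):
            p1 = tmp_path / f"a{k}.tsv"
            p2 = tmp_path / f"b{k}.tsv"
            write_timeseries(tss, p1)
            back = read_timeseries(p1)
            write_timeseries(back, p2)
            assert p1.read_bytes() == p2.read_bytes()
            assert (p1.parent / (p1.name + ".manifest.json")).read_bytes() == (
                p2.parent / (p2.name + ".manifest.json")
            ).read_bytes()
            assert back.xi == tss.xi
            for a, b in zip(back.series, tss.series):
                assert a.points.tolist() == b.points.tolist()
                assert a.group == b.group
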