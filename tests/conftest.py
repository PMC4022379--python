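import numpy as np
import pytest

from bpds import FixtureSpec, PolynomialModel, TimeSeries, TimeSeriesSet, planted_fixture


@pytest.fixture
def toggle3() -> PolynomialModel:
    """3-node toggle: x1 and x2 repress each other, x3 copies x1."""
    return PolynomialModel.from_text("f1 = x2 + 1\nf2 = x1 + 1\nf3 = x1\n")


@pytest.fixture
def small_tss() -> TimeSeriesSet:
    """Two short wildtype series plus one knock-out series on 3 variables."""
    wt1 = TimeSeries(np.array([[0, 0, 0], [1, 1, 0], [0, 0, 1], [1, 1, 0]]), label="wt1")
    wt2 = TimeSeries(np.array([[1, 0, 1], [1, 0, 1], [1, 0, 1]]), label="wt2")
    ko = TimeSeries(
        np.array([[1, 1, 1], [0, 1, 1], [0, 0, 0]]), kind="knockout", ko_target=0, label="ko1"
    )
    return TimeSeriesSet([wt1, wt2, ko], xi=0.0)


@pytest.fixture
def planted5():
    """Default planted 5-node fixture (noiseless)."""
    return planted_fixture(FixtureSpec(seed=7))


def random_model_and_n(rng: np.random.Generator, n_max: int = 6):
    """A random polynomial model on 2..n_max variables (test helper)."""
    from bpds import BooleanPolynomial

    n = int(rng.integers(2, n_max + 1))
    coords = []
    for _ in range(n):
        k = int(rng.integers(1, 4))
        masks = {int(rng.integers(0, 1 << n)) for _ in range(k)}
        coords.append(BooleanPolynomial(masks, n))
    return PolynomialModel(coords)
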