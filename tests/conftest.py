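import numpy as np
import pytest

from sw1pers import ShapeSpec, TimeSeries, generate_shape, sample_times


@pytest.fixture(scope="session")
def times25():
    """25 evenly spaced samples over the default two-period record."""
    return sample_times(25)


@pytest.fixture(scope="session")
def cos25(times25):
    return generate_shape(ShapeSpec("cos"), times25)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260919)


def random_walk_series(rng, n=25, span=200.0, ident="rw"):
    """A smooth-ish aperiodic test signal (cumulative random walk)."""
    t = np.linspace(0.0, span, n)
    return TimeSeries(ident, t, rng.standard_normal(n).cumsum())
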