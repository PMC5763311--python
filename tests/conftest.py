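import numpy as np
import pytest

from tepcausal import ScalarSeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_series(name, values):
    return ScalarSeries(name, np.asarray(values, dtype=float))


@pytest.fixture
def random_series_pair(rng):
    """Two independent chaotic-looking but unrelated series of length 10."""
    x = make_series("x", rng.random(10))
    y = make_series("y", rng.random(10))
    return x, y
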