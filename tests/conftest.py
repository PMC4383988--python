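import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=40)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_points(rng):
    def _make(n=50, scale=10.0):
        return rng.normal(0.0, scale, (n, 3))

    return _make


@pytest.fixture
def random_rotation(rng):
    from quatsym.superpose import axis_angle_matrix

    def _make():
        axis = rng.normal(size=3)
        return axis_angle_matrix(axis, rng.uniform(0.1, np.pi))

    return _make
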