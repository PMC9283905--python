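import numpy as np
import pytest

from eegmetric.data import SynthConfig, generate_recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_informative_2d(n=200, noise=0.3, seed=0):
    """Two-class data where only coordinate 1 carries class information."""
    rng = np.random.default_rng(seed)
    y = rng.integers(1, 3, n)
    x1 = np.where(y == 1, -1.0, 1.0) + noise * rng.standard_normal(n)
    x2 = rng.standard_normal(n)
    return np.column_stack([x1, x2]), y


@pytest.fixture
def informative_2d():
    return make_informative_2d()


@pytest.fixture
def clusters8():
    """Two tight, far-separated 4-point clusters matched to labels."""
    offsets = np.array([[0.0, 0.0], [0.1, 0.0], [0.0, 0.1], [0.1, 0.1]])
    X = np.vstack([offsets, offsets + 10.0])
    y = np.array([1, 1, 1, 1, 2, 2, 2, 2])
    return X, y


@pytest.fixture(scope="session")
def small_recording():
    """A 60-trial synthetic session shared across tests."""
    return generate_recording(SynthConfig(n_trials=60, seed=0))
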