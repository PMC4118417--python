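import numpy as np
import pytest

from diffreg.spectral import FeatureCloud


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cloud(rng):
    """A generic random cloud in R^3."""
    return FeatureCloud(rng.normal(size=(24, 3)))


def random_clouds(seed, count, n_max=50, d=3):
    """Deterministic stream of random clouds for property tests."""
    rng = np.random.default_rng(seed)
    for _ in range(count):
        n = int(rng.integers(5, n_max + 1))
        yield FeatureCloud(rng.normal(size=(n, d)))
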