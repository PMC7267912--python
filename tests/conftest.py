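import numpy as np
import pytest

from icsearch.grid import build_grid
from icsearch.relevance import build_affinity, build_spectral_cache


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def cube3():
    """3x3x3 full grid, 26-connectivity."""
    return build_grid(np.ones((3, 3, 3), dtype=bool))


def random_problem(rng, p=20, n=12, seed_labels=True):
    """Random voxel x subject matrix with balanced binary labels."""
    X = rng.standard_normal((p, n))
    y = np.repeat([0, 1], [n // 2, n - n // 2])
    return X, y


@pytest.fixture
def small_problem(rng):
    X, y = random_problem(rng, p=27, n=20)
    return X, y


@pytest.fixture
def spectral_setup(small_problem):
    X, y = small_problem
    model = build_affinity(y)
    cache = build_spectral_cache(X, model, standardize=True)
    return X, y, model, cache
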