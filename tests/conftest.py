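import numpy as np
import pytest

from asmbplsda import AsmbPLSDA


def random_two_block(rng, n=40, m=(30, 10), n_groups=2, signal=1.5):
    """Random two-block dataset with a weak planted group shift."""
    blocks = [rng.standard_normal((n, mb)) for mb in m]
    y = rng.integers(0, n_groups, size=n)
    while len(np.unique(y)) < n_groups or np.min(np.bincount(y)) < 2:
        y = rng.integers(0, n_groups, size=n)
    for b in blocks:
        b[:, 0] += signal * y  # one informative feature per block
    return blocks, y


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def binary_data(rng):
    return random_two_block(rng)


@pytest.fixture
def multiclass_data(rng):
    return random_two_block(rng, n=60, n_groups=3)


@pytest.fixture
def fitted_binary(binary_data):
    X, y = binary_data
    return AsmbPLSDA(n_components=2, quantiles=[0.5, 0.5]).fit(X, y), X, y


@pytest.fixture
def fitted_multiclass(multiclass_data):
    X, y = multiclass_data
    return AsmbPLSDA(n_components=2, quantiles=[0.5, 0.5]).fit(X, y), X, y
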