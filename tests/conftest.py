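import numpy as np
import pytest

from chromascope.matrixio import BinTable, ContactMatrix


@pytest.fixture
def uniform_matrix():
    """16-bin uniform positive contact map (every entry 2.0)."""
    n = 16
    return ContactMatrix(BinTable.uniform(n, 10_000),
                         np.full((n, n), 2.0), 10_000, balanced=True)


@pytest.fixture
def two_block_matrix():
    """Two 10-bin uniform blocks of intensity 3.0 with zero cross-contacts."""
    n = 20
    v = np.zeros((n, n))
    v[:10, :10] = 3.0
    v[10:, 10:] = 3.0
    return ContactMatrix(BinTable.uniform(n, 10_000), v, 10_000, balanced=True)


def random_symmetric(n, rng, positive=True):
    a = rng.random((n, n))
    a = (a + a.T) / 2
    if positive:
        a += 0.1
    return a


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
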