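import numpy as np
import pytest

from bwnet import worked_toy


@pytest.fixture
def toy():
    """Fixed 3x4 dataset: d1-{m1,m2}, d2-{m2,m3}, d3-{m4}."""
    return worked_toy()


@pytest.fixture
def toy_A(toy):
    return toy.adjacency


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def identity_kernels():
    """Kernels of the 2x2 identity adjacency: off-diagonal exp(-2)."""
    e2 = np.exp(-2.0)
    K = np.array([[1.0, e2], [e2, 1.0]])
    return K.copy(), K.copy()
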