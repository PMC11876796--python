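import numpy as np
import pytest

from stgate.autodiff import tune_allocator

tune_allocator()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_adjacency(rng):
    """4-node adjacency with self-loops and a few cross edges."""
    A = (rng.random((4, 4)) < 0.5).astype(float) * rng.uniform(0.2, 1, (4, 4))
    np.fill_diagonal(A, 1.0)
    return A
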