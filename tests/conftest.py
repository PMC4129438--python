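import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_digraph(rng, n, p):
    """Dense 0/1 adjacency of a directed G(n, p) without self-loops."""
    A = (rng.random((n, n)) < p).astype(np.int8)
    np.fill_diagonal(A, 0)
    return A
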