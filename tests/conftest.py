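import numpy as np
import pytest
import scipy.sparse as sp

from surewalk.graph_io import Graph, row_normalize


def random_digraph(rng, n_max=50, n_min=5, density=None, allow_dangling=False):
    """Random weighted digraph for oracle comparisons."""
    n = int(rng.integers(n_min, n_max + 1))
    dens = density if density is not None else float(rng.uniform(0.08, 0.35))
    mask = rng.random((n, n)) < dens
    np.fill_diagonal(mask, False)
    weights = rng.random((n, n)) * mask
    if not allow_dangling:
        for i in range(n):
            if weights[i].sum() == 0:
                j = int(rng.integers(n - 1))
                j = j if j < i else j + 1
                weights[i, j] = float(rng.random()) + 0.1
    g = Graph(adjacency=sp.csr_matrix(weights))
    if g.m == 0:
        return random_digraph(rng, n_max=n_max, n_min=n_min,
                              density=0.5, allow_dangling=allow_dangling)
    return g


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def two_node_cycle():
    """s <-> u cycle: analytic fixed point r_s = 1 / (2 - c_s)."""
    g = Graph(adjacency=sp.csr_matrix(np.array([[0.0, 1.0], [1.0, 0.0]])))
    return g, row_normalize(g)


@pytest.fixture
def path4():
    """Undirected 4-node path 0-1-2-3."""
    a = np.zeros((4, 4))
    for u, v in ((0, 1), (1, 2), (2, 3)):
        a[u, v] = a[v, u] = 1.0
    g = Graph(adjacency=sp.csr_matrix(a), directed=False)
    return g, row_normalize(g)
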