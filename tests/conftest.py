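import numpy as np
import pytest

from rewirenet import WeightedGraph


def graph_from_edges(n, edges, binary=None):
    """Build a WeightedGraph from (i, j, w) triples."""
    A = np.zeros((n, n))
    for i, j, w in edges:
        A[i, j] = A[j, i] = w
    if binary is None:
        binary = bool(np.all(np.isin(A, (0.0, 1.0))))
    return WeightedGraph(A, is_binary=binary)


@pytest.fixture
def triangle_binary():
    return graph_from_edges(3, [(0, 1, 1), (1, 2, 1), (0, 2, 1)])


@pytest.fixture
def weighted_triangle():
    # strengths: s0 = 1+2 = 3, s1 = 1+1 = 2... edges (0-1: 1), (1-2: 1), (0-2: 2)
    return graph_from_edges(3, [(0, 1, 1), (1, 2, 1), (0, 2, 2)])


@pytest.fixture
def path4():
    return graph_from_edges(4, [(0, 1, 1), (1, 2, 1), (2, 3, 1)])


@pytest.fixture
def star5():
    return graph_from_edges(5, [(0, i, 1) for i in range(1, 5)])


@pytest.fixture
def two_cliques():
    """Two disjoint binary 4-cliques."""
    edges = []
    for block in (range(4), range(4, 8)):
        block = list(block)
        edges += [(i, j, 1) for a, i in enumerate(block) for j in block[a + 1:]]
    return graph_from_edges(8, edges)


@pytest.fixture
def bridged_cliques():
    """Two 4-cliques joined by a single bridge edge."""
    edges = []
    for block in (range(4), range(4, 8)):
        block = list(block)
        edges += [(i, j, 1) for a, i in enumerate(block) for j in block[a + 1:]]
    edges.append((3, 4, 1))
    return graph_from_edges(8, edges)


def random_weighted_graph(n, p, seed, weights="uniform"):
    """ER-style random graph with positive random weights (test helper)."""
    rng = np.random.default_rng(seed)
    A = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    mask = rng.random(iu.size) < p
    w = rng.uniform(0.2, 1.0, mask.sum()) if weights == "uniform" else np.ones(mask.sum())
    A[iu[mask], ju[mask]] = w
    A[ju[mask], iu[mask]] = w
    return WeightedGraph(A, is_binary=weights == "binary")
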