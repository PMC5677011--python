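import numpy as np
import pytest

from mpdlink import (
    AdjacencyMatrix,
    SbmSpec,
    WeightedDigraph,
    karate_club_graph,
    sbm_graph,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20251101)


@pytest.fixture(scope="session")
def karate():
    return karate_club_graph()


@pytest.fixture
def path4():
    """Undirected unit-weight path a-b-c-d."""
    links = {}
    for u, v in [("a", "b"), ("b", "c"), ("c", "d")]:
        links[(u, v)] = links[(v, u)] = 1.0
    return WeightedDigraph(["a", "b", "c", "d"], links, directed=False)


@pytest.fixture(scope="session")
def sbm_small():
    """50-node assortative 2-block SBM used across pipeline tests."""
    return sbm_graph(SbmSpec([25, 25], 0.3, 0.05, directed=False, seed=5))


def random_adjacency(rng, n, density=0.3, directed=True, weighted=True):
    """Random valid adjacency matrix (nonnegative, zero diagonal)."""
    mask = rng.random((n, n)) < density
    w = rng.uniform(0.5, 3.0, size=(n, n)) if weighted else np.ones((n, n))
    m = np.where(mask, w, 0.0)
    if not directed:
        m = np.triu(m, 1)
        m = m + m.T
    np.fill_diagonal(m, 0.0)
    return AdjacencyMatrix(m)
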