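import networkx as nx
import numpy as np
import pytest

import modprune as mp


@pytest.fixture
def g4():
    """Triangle a-b-c with pendant d attached to c; 2m = 8."""
    return mp.Graph(4, [(0, 1), (1, 2), (0, 2), (2, 3)])


@pytest.fixture
def g4_split():
    """The {a,b,c}{d} bipartition of g4."""
    return mp.Partition([0, 0, 0, 1])


@pytest.fixture
def two_triangles():
    return mp.Graph(6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])


@pytest.fixture(scope="session")
def karate():
    """The unweighted Zachary karate club network."""
    return mp.Graph(34, list(nx.karate_club_graph().edges()))


@pytest.fixture
def g4_chain(g4):
    """Two identical g4 layers coupled as a temporal chain."""
    return mp.MultilayerNetwork([g4, g4], mp.TEMPORAL_CHAIN)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_graph(rng, n, p=0.3, weighted=False):
    iu, ju = np.triu_indices(n, k=1)
    pick = rng.random(iu.size) < p
    w = rng.integers(1, 4, size=int(pick.sum())) if weighted else np.ones(int(pick.sum()))
    edges = list(zip(iu[pick].tolist(), ju[pick].tolist(), w.tolist()))
    if not edges:  # quality functions need some edge weight
        edges = [(0, 1, 1.0)]
    return mp.Graph(n, edges)
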