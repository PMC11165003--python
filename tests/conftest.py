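import numpy as np
import pytest

from syncpath import (
    ClusterSpec,
    WeightedGraph,
    eigendecompose,
    planted_cluster_graph,
    three_orbit_demo_graph,
)


def adjacency(n, edges):
    a = np.zeros((n, n))
    for i, j, *w in edges:
        a[i, j] = a[j, i] = w[0] if w else 1.0
    return a


@pytest.fixture
def p3():
    """Path 1-2-3 with unit weights."""
    return WeightedGraph(["1", "2", "3"], adjacency(3, [(0, 1), (1, 2)]))


@pytest.fixture
def k4():
    return WeightedGraph(
        ["1", "2", "3", "4"],
        adjacency(4, [(i, j) for i in range(4) for j in range(i + 1, 4)]),
    )


@pytest.fixture
def f4():
    """4-node fixture with edges {1-3, 1-4, 2-3, 2-4, 3-4}: cells {1,2} and {3,4}."""
    return WeightedGraph(
        ["1", "2", "3", "4"],
        adjacency(4, [(0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]),
    )


@pytest.fixture(scope="session")
def demo10():
    """Three-orbit weighted 10-node graph with spectrum {0,1,1,1,4,4,4,6,6,6}."""
    return three_orbit_demo_graph()


@pytest.fixture(scope="session")
def demo10_spectrum(demo10):
    return eigendecompose(demo10)


@pytest.fixture(scope="session")
def planted_small():
    """23-node planted fixture: one 3-node cluster of external degree 2."""
    return planted_cluster_graph(20, [ClusterSpec(3, 2)], seed=2)


@pytest.fixture(scope="session")
def planted_medium():
    """50-node planted fixture: clusters of sizes 8 (degree 4) and 4 (degree 2)."""
    return planted_cluster_graph(38, [ClusterSpec(8, 4), ClusterSpec(4, 2)], seed=5)
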