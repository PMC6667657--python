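import numpy as np
import pytest

from tinnet.containers import BinaryGraph


def graph_from_edges(n, edges):
    a = np.zeros((n, n), dtype=int)
    for i, j in edges:
        a[i, j] = a[j, i] = 1
    return BinaryGraph(a)


@pytest.fixture
def two_triangles():
    return graph_from_edges(6, [(0, 1), (1, 2), (0, 2),
                                (3, 4), (4, 5), (3, 5)])


@pytest.fixture
def path3():
    return graph_from_edges(3, [(0, 1), (1, 2)])


@pytest.fixture
def k4_minus_edge():
    return graph_from_edges(4, [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3)])


@pytest.fixture
def k5():
    return graph_from_edges(5, [(i, j) for i in range(5)
                                for j in range(i + 1, 5)])
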