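import numpy as np
import pytest
import scipy.sparse as sp

from stforge.plate import CellPlate, NeighborGraph, build_graph, generate_plate


@pytest.fixture(scope="session")
def unit_square():
    return np.array([[0.0, 1.0], [0.0, 1.0]])


@pytest.fixture(scope="session")
def small_plate():
    """1000 uniform cells on the unit square."""
    return generate_plate(1000, "random", seed=42)


@pytest.fixture(scope="session")
def small_graph(small_plate):
    return build_graph(small_plate, "knn", 6)


@pytest.fixture()
def path_graph_4():
    """Path a-b-c-d with evenly spaced collinear coordinates."""
    coords = np.array([[0.1, 0.5], [0.35, 0.5], [0.6, 0.5], [0.85, 0.5]])
    plate = CellPlate(coords, np.array([[0.0, 1.0], [0.0, 1.0]]))
    adj = sp.csr_matrix(
        np.array(
            [[0, 1, 0, 0], [1, 0, 1, 0], [0, 1, 0, 1], [0, 0, 1, 0]], dtype=np.int8
        )
    )
    return plate, NeighborGraph(adj, "knn", 1)


@pytest.fixture()
def two_triangles():
    """Two disconnected triangles (nodes 0-2 and 3-5)."""
    block = np.ones((3, 3), dtype=np.int8) - np.eye(3, dtype=np.int8)
    adj = sp.block_diag([block, block]).tocsr()
    return NeighborGraph(adj, "knn", 2)


@pytest.fixture(scope="session")
def cortex_fixture():
    from stforge.expression import starmap_like_fixture

    return starmap_like_fixture(seed=0)
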