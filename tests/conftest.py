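import numpy as np
import pytest

from graphesi import (
    adjacency_from_mesh,
    build_icosphere_source_space,
    eigendecompose,
    laplacian,
    synthesize_lead_field,
)


@pytest.fixture(scope="session")
def icosahedron():
    """12-vertex icosahedron source space (subdivisions=0)."""
    return build_icosphere_source_space(0, 80.0)


@pytest.fixture(scope="session")
def ico2():
    """162-vertex icosphere source space."""
    return build_icosphere_source_space(2, 80.0)


@pytest.fixture(scope="session")
def ico2_graph(ico2):
    return adjacency_from_mesh(ico2, neighbor_order=1)


@pytest.fixture(scope="session")
def ico2_leadfield(ico2):
    return synthesize_lead_field(ico2, n_electrodes=32, scalp_radius_mm=100.0, seed=0)

@pytest.fixture(scope="session")
def ico2_basis(ico2_graph):
    return eigendecompose(laplacian(ico2_graph))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def path_graph_adjacency():
    """Path graph 0-1-2 with unit weights."""
    return np.array([[0.0, 1, 0], [1, 0, 1], [0, 1, 0]])
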