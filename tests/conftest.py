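import warnings

import numpy as np
import pytest
import scipy.sparse as sp

from tipdrift.geometry import GeometrySpec, Mesh, build_geometry, canonical_specs
from tipdrift.model import ReactionModel, ReactionSpec, SpeciesSpec

# mesh-quality warnings are expected on coarse test meshes
warnings.filterwarnings("ignore", message=".*stiffness edge weight clipped.*")


@pytest.fixture(scope="session")
def sphere_mesh():
    """Coarse base sphere (r = 2 um) with its tip frame."""
    spec = canonical_specs(target_edge_length=0.5)["sphere"]
    return build_geometry(spec)


@pytest.fixture(scope="session")
def projection_mesh():
    """Short-projection geometry (late stage) with its tip frame."""
    spec = canonical_specs(target_edge_length=0.5)["projection2"]
    return build_geometry(spec)


@pytest.fixture(scope="session")
def single_tet_mesh():
    """One regular tetrahedron (edge 1) as a 4-voxel mesh."""
    verts = np.array([
        [1.0, 1.0, 1.0],
        [1.0, -1.0, -1.0],
        [-1.0, 1.0, -1.0],
        [-1.0, -1.0, 1.0],
    ]) / np.sqrt(8.0)  # edge length 1
    tets = np.array([[0, 1, 2, 3]])
    a, b, c, d = verts
    if np.dot(np.cross(b - a, c - a), d - a) < 0:
        tets = np.array([[0, 1, 3, 2]])
    tris = np.array([[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]])
    return Mesh(vertices=verts, tetrahedra=tets, boundary_triangles=tris)


@pytest.fixture
def decay_diffusion_chain():
    """3-voxel chain: birth + death + diffusion of one species.

    Returns (model, volumes, jump matrix dict) for manual_system; the state
    space is effectively finite (birth is slow), enabling a master-equation
    oracle.
    """
    model = ReactionModel(
        name="chain3",
        species=[SpeciesSpec("X", "cytoplasm", D_cyt=1.0)],
        reactions=[
            ReactionSpec("birth", (), (("X", 1),), 0.05, region="everywhere"),
            ReactionSpec("death", (("X", 1),), (), 0.3, region="everywhere"),
        ],
    )
    volumes = np.array([1.0, 2.0, 1.0])
    # reciprocal rates: V_i d_ij = V_j d_ji
    d = np.zeros((3, 3))
    d[0, 1] = 1.0
    d[1, 0] = 0.5
    d[1, 2] = 0.5
    d[2, 1] = 1.0
    return model, volumes, {"X": sp.csr_matrix(d)}


@pytest.fixture
def membrane_exchange_model():
    """Two-species attach/detach model used across engine tests."""
    return ReactionModel(
        name="exchange",
        species=[
            SpeciesSpec("C", "cytoplasm", D_cyt=10.0),
            SpeciesSpec("Mm", "membrane", D_mem=0.02),
        ],
        reactions=[
            ReactionSpec("on", (("C", 1),), (("Mm", 1),), 0.5),
            ReactionSpec("off", (("Mm", 1),), (("C", 1),), 0.25),
        ],
        moieties={"total": {"C", "Mm"}},
    )
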