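import numpy as np
import pytest

from septumfem import (
    Material,
    RunConfig,
    build_idealized_outline,
    mesh_outline,
    run_pipeline,
)
from septumfem.geometry import LabeledMesh, SeptumOutline


@pytest.fixture(scope="session")
def material():
    return Material()


@pytest.fixture(scope="session")
def outline():
    return build_idealized_outline()


@pytest.fixture(scope="session")
def mesh(outline):
    return mesh_outline(outline, 2e-3)


@pytest.fixture(scope="session")
def spring_run():
    """Default spring-supported model, anteroposterior couple."""
    return run_pipeline(RunConfig())


@pytest.fixture(scope="session")
def free_run():
    return run_pipeline(RunConfig(tip_condition="free"))


@pytest.fixture(scope="session")
def spring_pressure_run():
    return run_pipeline(RunConfig(load_case="dorsal_caudal_pressure"))


@pytest.fixture(scope="session")
def free_pressure_run():
    return run_pipeline(RunConfig(tip_condition="free", load_case="dorsal_caudal_pressure"))


def make_rectangle_outline(a_mm: float = 30.0, b_mm: float = 20.0) -> SeptumOutline:
    """Rectangle with the tip at the top-right corner and ANS bottom-right."""
    verts = np.array([[0.0, 0.0], [a_mm, 0.0], [a_mm, b_mm], [0.0, b_mm]])
    labels = ["hard_palate", "caudal_free", "dorsal_free", "ethmoid"]
    return SeptumOutline(verts, labels, np.array([a_mm, b_mm]), np.array([a_mm, 0.0]), 14.0)


@pytest.fixture(scope="session")
def two_triangle_mesh() -> LabeledMesh:
    """Unit-square toy mesh (m): two triangles, left edge fixed-labelled."""
    nodes = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
    tris = np.array([[0, 1, 2], [0, 2, 3]])
    node_sets = {
        "ethmoid": np.array([0, 3]),
        "vomer": np.array([], dtype=int),
        "nasal_bone": np.array([], dtype=int),
        "hard_palate": np.array([0, 1]),
        "dorsal_free": np.array([2, 3]),
        "caudal_free": np.array([1, 2]),
        "tip": np.array([2]),
        "ans": np.array([1]),
    }
    boundary_edges = {
        "hard_palate": np.array([[0, 1]]),
        "caudal_free": np.array([[1, 2]]),
        "dorsal_free": np.array([[2, 3]]),
        "ethmoid": np.array([[3, 0]]),
        "vomer": np.zeros((0, 2), dtype=int),
        "nasal_bone": np.zeros((0, 2), dtype=int),
    }
    return LabeledMesh(nodes, tris, node_sets, boundary_edges, np.full(2, 2e-3))
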