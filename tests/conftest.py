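import numpy as np
import pytest

from occlucontact.jaw_alignment import AlignedJawPair
from occlucontact.mesh_io import LandmarkSet, SurfaceMesh
from occlucontact.synthetic_data import (
    JawPhantomParams,
    make_analytic_fixture,
    make_jaw_pair,
)


@pytest.fixture
def tetrahedron() -> SurfaceMesh:
    """Minimal closed mesh: 4 vertices, 4 faces."""
    vertices = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
    faces = np.array([[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]])
    return SurfaceMesh(vertices, faces, "tetra")


@pytest.fixture
def landmarks() -> LandmarkSet:
    return LandmarkSet(
        incisal_point=np.array([5.0, 0.0, 0.0]),
        left_molar_cusp=np.array([0.0, 20.0, 0.0]),
        right_molar_cusp=np.array([10.0, 20.0, 0.0]),
    )


@pytest.fixture(scope="session")
def plate_pair() -> tuple:
    """Parallel plates, gap 0.05 mm, with the exact area step function."""
    return make_analytic_fixture("parallel_plates", side=10.0, gap=0.05)


@pytest.fixture(scope="session")
def jaw_phantom() -> tuple[AlignedJawPair, LandmarkSet]:
    """One deterministic cusped jaw phantom shared across tests."""
    return make_jaw_pair(JawPhantomParams(seed=42))


@pytest.fixture(scope="session")
def bumpy_phantom() -> AlignedJawPair:
    """A jittered phantom with uneven cusp heights (irregular contacts)."""
    pair, _ = make_jaw_pair(JawPhantomParams(
        seed=7, height_jitter=0.25, position_jitter=0.6))
    return pair
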