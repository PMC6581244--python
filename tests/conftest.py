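import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from infantfem import anatomy as an
from infantfem import materials as mat
from infantfem import mesh as mm
from infantfem import phantom as ph
from infantfem import solver as sv


@pytest.fixture(scope="session")
def phantom_4mo():
    params = ph.preset("4mo")
    image, landmarks = ph.generate_femur(params)
    return params, image, landmarks


@pytest.fixture(scope="session")
def phantom_7mo():
    params = ph.preset("7mo")
    image, landmarks = ph.generate_femur(params)
    return params, image, landmarks


@pytest.fixture(scope="session")
def mesh_4mo(phantom_4mo):
    _, image, landmarks = phantom_4mo
    return mm.mesh_from_labels(image, 2.5, landmarks)


@pytest.fixture(scope="session")
def materials_4mo(phantom_4mo, mesh_4mo):
    _, image, _ = phantom_4mo
    return mat.build_material_field(image, mesh_4mo)


@pytest.fixture(scope="session")
def frame_4mo(phantom_4mo, mesh_4mo):
    _, _, landmarks = phantom_4mo
    return an.build_frame(mesh_4mo, landmarks)


@pytest.fixture(scope="session")
def solver_4mo(mesh_4mo, materials_4mo):
    return sv.StaticSolver(mesh_4mo, materials_4mo)


@pytest.fixture(scope="session")
def torsion_4mo(phantom_4mo, mesh_4mo, frame_4mo, solver_4mo):
    _, _, landmarks = phantom_4mo
    bcs = an.make_load_case(frame_4mo, landmarks, mesh_4mo, "torsion")
    return bcs, solver_4mo.solve(bcs)


@pytest.fixture()
def single_tet():
    coords = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
    return mm.promote_to_quadratic(
        coords, np.array([[0, 1, 2, 3]]), np.array([mm.REGION_DIAPHYSIS])
    )
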