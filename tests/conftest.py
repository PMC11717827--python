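import numpy as np
import pytest

from dentofuse import PhantomSpec, make_phantom
from dentofuse.mesh_core import TriMesh

# unit cube centered at the origin, outward-wound faces
_CUBE_VERTS = np.array(
    [
        [-0.5, -0.5, -0.5],
        [0.5, -0.5, -0.5],
        [0.5, 0.5, -0.5],
        [-0.5, 0.5, -0.5],
        [-0.5, -0.5, 0.5],
        [0.5, -0.5, 0.5],
        [0.5, 0.5, 0.5],
        [-0.5, 0.5, 0.5],
    ]
)
_CUBE_FACES = np.array(
    [
        [0, 2, 1], [0, 3, 2],  # bottom z-
        [4, 5, 6], [4, 6, 7],  # top z+
        [0, 1, 5], [0, 5, 4],
        [1, 2, 6], [1, 6, 5],
        [2, 3, 7], [2, 7, 6],
        [3, 0, 4], [3, 4, 7],
    ]
)


@pytest.fixture
def cube() -> TriMesh:
    return TriMesh(_CUBE_VERTS.copy(), _CUBE_FACES.copy())


@pytest.fixture
def cube_with_top_region() -> TriMesh:
    m = TriMesh(_CUBE_VERTS.copy(), _CUBE_FACES.copy())
    m.regions["top"] = np.array([4, 5, 6, 7])
    return m


@pytest.fixture(scope="session")
def phantom():
    return make_phantom(PhantomSpec())


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
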