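import numpy as np
import pytest
import trimesh

from surfmorph.mesh import TriangleMesh
from surfmorph.synthetic import tube_mesh


def icosphere(subdivisions=3, radius=1.0) -> TriangleMesh:
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriangleMesh(np.asarray(ico.vertices), np.asarray(ico.faces))


@pytest.fixture(scope="session")
def unit_sphere():
    return icosphere(subdivisions=4)


@pytest.fixture(scope="session")
def tube():
    """Right circular tube, radius 2 mm, length 10 mm."""
    return tube_mesh(radius=2.0, length=10.0, n_axial=30, n_circ=24)


@pytest.fixture(scope="session")
def tube_param(tube):
    from surfmorph.conformal import parameterize
    return parameterize(tube)
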