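import numpy as np
import pytest
import trimesh

from vbb import FemurParams, SurfaceMesh, generate_femur


@pytest.fixture(scope="session")
def femur_default():
    """Standard synthetic right femur (a=80, b=60, c=62), noise-free."""
    return generate_femur(FemurParams(seed=1))


@pytest.fixture(scope="session")
def femur_coarse():
    """Cheap coarse femur for tests that only need plausible geometry."""
    return generate_femur(FemurParams(seed=1, resolution_mm=2.5))


@pytest.fixture(scope="session")
def sphere20():
    """Closed icosphere of radius 20 mm centered at the origin."""
    tm = trimesh.creation.icosphere(subdivisions=4, radius=20.0)
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


@pytest.fixture(scope="session")
def unit_cube():
    tm = trimesh.creation.box((1.0, 1.0, 1.0))
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


def random_rigid(rng):
    """Uniform random proper rigid transform (helper, not a fixture)."""
    from scipy.spatial.transform import Rotation

    from vbb import RigidTransform

    return RigidTransform(Rotation.random(rng=rng).as_matrix(),
                          rng.uniform(-50, 50, 3))
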