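import numpy as np
import pytest

from mitomorph3d import ShapeSpec, voxelize
from mitomorph3d.synthetic import CohortSpec, generate_cohort, generate_fiber_volume


@pytest.fixture(scope="session")
def sphere_phantom():
    """Voxelized 500 nm-radius sphere at the reference anisotropic voxel size."""
    return voxelize(ShapeSpec("sphere", {"radius": 500.0}))


@pytest.fixture(scope="session")
def capsule_phantom():
    """Thin voxelized capsule (r = 100 nm tube) for radius-profile tests."""
    return voxelize(ShapeSpec("capsule", {"radius": 100.0, "length": 1000.0, "axis": "x"}))


@pytest.fixture(scope="session")
def resolved_capsule_phantom():
    """Mitochondrion-scale capsule (r = 200 nm, length 2000 nm): thick enough
    in the 30 nm section axis for meshing oracles to hold."""
    return voxelize(ShapeSpec("capsule", {"radius": 200.0, "length": 2000.0, "axis": "x"}))


@pytest.fixture(scope="session")
def dumbbell_phantom():
    """Two 300 nm-radius bodies joined by a 100 nm x 800 nm tube."""
    return voxelize(
        ShapeSpec(
            "nanotunnel_dumbbell",
            {"body_radius": 300.0, "tube_radius": 50.0, "tube_length": 800.0},
        )
    )


@pytest.fixture(scope="session")
def control_cohort():
    """Default healthy-control + disease cohort draw, fixed seed."""
    return generate_cohort(CohortSpec(seed=7))


@pytest.fixture(scope="session")
def fiber_phantom():
    """Small sarcomere-registered network phantom with truth table."""
    return generate_fiber_volume(
        n_columns=(3, 3),
        n_planes=2,
        occupancy=1.0,
        nanotunnel_rate_per_100=25.0,
        seed=1,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
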