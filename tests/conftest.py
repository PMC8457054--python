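import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from netskel.volume_io import VoxelGeometry

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def unit_geometry():
    """Isotropic unit voxels in sigma units."""
    return VoxelGeometry(1.0, 1.0, 1.0, "sigma")


@pytest.fixture
def aniso_geometry():
    """Anisotropic confocal-like voxels (dz > dx = dy), micrometres."""
    return VoxelGeometry(0.1, 0.1, 0.25, "um")


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
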