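import numpy as np
import pytest

from strutdiff.frap import RecoveryCurve
from strutdiff.frap_synth import BleachScenario
from strutdiff.geometry import ScaffoldSpec, VoxelGrid

# measured free-solution diffusivity of a 3-kDa dextran probe, cm^2/s
D_DEXTRAN_WATER = 1.28e-6


@pytest.fixture
def water_scenario():
    """Noise-free bleach scenario at the water diffusivity of the probe."""
    return BleachScenario(d_true=D_DEXTRAN_WATER, omega=50.0, domain_width=600.0)


@pytest.fixture
def soumpasis_curve():
    """Closed-form uniform-disk recovery sampled on a realistic frame grid."""
    from strutdiff.frap_synth import soumpasis_recovery

    times = np.arange(0.0, 40.0, 0.25)
    f = soumpasis_recovery(times, 50.0, D_DEXTRAN_WATER)
    return RecoveryCurve(times=times, f=f, omega=50.0)


@pytest.fixture
def column_grid():
    """A 1-voxel-wide all-culture column, 1000 um deep at 10 um voxels."""
    return VoxelGrid(strut=np.zeros((1, 1, 100), dtype=bool), voxel_size=10.0)


@pytest.fixture
def small_spec():
    """A small scaffold spec sized for fast coupled runs."""
    return ScaffoldSpec(
        alpha=0.5, pitch=200.0, voxel_size=10.0, total_thickness=300.0, layer_height=50.0
    )
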