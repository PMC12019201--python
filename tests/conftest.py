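import numpy as np
import pytest

from pacbs import (
    AcousticMedium,
    CBSConfig,
    Disk,
    OpticalThermalParams,
    SimGrid,
)


@pytest.fixture(scope="session")
def optical():
    return OpticalThermalParams()


@pytest.fixture(scope="session")
def rbc_disk():
    """Single erythrocyte-sized absorber at the domain center."""
    return Disk(center=(0.0, 0.0), radius=2.75)


@pytest.fixture(scope="session")
def test_grid():
    """Reduced lattice (512 x 512 at 100 nm pitch) used throughout the test
    suite so full-grid solves run in seconds."""
    return SimGrid(n=512, h_um=0.1)


@pytest.fixture(scope="session")
def test_config():
    """Solver settings matching the reference setup except for the ABL
    depth, which scales with the reduced lattice (same pitch, same sigmoid
    steepness, 128-pixel frame)."""
    return CBSConfig(abl_thickness=128)


def medium_for(vs: float) -> AcousticMedium:
    return AcousticMedium(vf=1500.0, vs=vs, rho_f=1000.0, rho_s=1000.0)


@pytest.fixture(scope="session")
def water_medium():
    return medium_for(1500.0)


def first_local_minimum(values: np.ndarray) -> int:
    """Index of the first strict local minimum of a 1D sequence."""
    interior = (values[1:-1] < values[:-2]) & (values[1:-1] < values[2:])
    idx = np.flatnonzero(interior)
    if idx.size == 0:
        raise ValueError("no local minimum found")
    return int(idx[0] + 1)
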