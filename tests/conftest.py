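import numpy as np
import pytest

from ccbrachy import physics_data as pd


@pytest.fixture(scope="session")
def water():
    return pd.water()


@pytest.fixture(scope="session")
def bone():
    return pd.cortical_bone()


@pytest.fixture(scope="session")
def air():
    return pd.air()


@pytest.fixture(scope="session")
def ir_spectrum():
    return pd.ir192_spectrum()


@pytest.fixture(scope="session")
def mono_spectrum():
    """Single 0.3565 MeV line (the emission-weighted mean line energy)."""
    return pd.PhotonSpectrum(np.array([0.3565]), np.array([1.0]))


def radial_grid(phantom):
    """Full (nx,ny,nz) distance-from-source grid for a phantom."""
    x, y, z = phantom.voxel_centers()
    s = phantom.source_position
    return np.sqrt((x - s[0]) ** 2 + (y - s[1]) ** 2 + (z - s[2]) ** 2)
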