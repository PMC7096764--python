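import numpy as np
import pytest

from mpgsim import Geometry, GratingSpec, Grid1D, bct_system, transmission_profile


@pytest.fixture(scope="session")
def talbot_grating():
    """4-um binary pi phase grating at 25 keV on a fine symmetric grid."""
    spec = GratingSpec(
        pitch_um=4.0, duty=0.5, phase_low=np.pi, phase_high=np.pi,
        modulation="none", design_energy_kev=25.0,
    )
    grid = Grid1D.centered(256.0, 0.01)
    return spec, transmission_profile(spec, grid, 25.0)


@pytest.fixture(scope="session")
def bct():
    """The breast-CT reference interferometer (point source, W' = 150 um)."""
    return bct_system()


@pytest.fixture(scope="session")
def bct_point_profile(bct):
    return bct.point_intensity()


@pytest.fixture(scope="session")
def point_geometry():
    return Geometry(d_sg=250.0, d_gd=600.0)
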