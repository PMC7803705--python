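import numpy as np
import pytest

from eptpipe import (
    AcquisitionParams,
    VoxelGrid,
    assign_tissue_properties,
    generate_label_phantom,
    generate_planewave_field,
    larmor_omega,
)
from eptpipe.config import PhantomConfig
from eptpipe.phantom import NestedEllipsoidGeometry, ShellSpec

OMEGA = larmor_omega()


@pytest.fixture(scope="session")
def default_phantom():
    """Full-size three-compartment brain phantom with literature properties."""
    cfg = PhantomConfig()
    phantom = generate_label_phantom(cfg.grid(), cfg.geometry())
    return assign_tissue_properties(phantom, cfg.frequency_hz)


@pytest.fixture(scope="session")
def default_field(default_phantom):
    return generate_planewave_field(
        default_phantom, OMEGA, PhantomConfig().field_direction
    )


@pytest.fixture(scope="session")
def wm_block():
    """Homogeneous all-WM ellipsoid on a compact grid — boundary-free except
    for the air interface."""
    grid = VoxelGrid((64, 64, 12))
    geom = NestedEllipsoidGeometry(
        semi_axes_mm=(70.0, 70.0, 13.0), shells=(ShellSpec(1, None),)
    )
    return assign_tissue_properties(generate_label_phantom(grid, geom))


@pytest.fixture
def noiseless_acq():
    return AcquisitionParams(
        snr=None, seed=0, slice_offset_scale=0.0, acquisition_matrix=None
    )
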