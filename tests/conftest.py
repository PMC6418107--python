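import numpy as np
import pytest

import femstrength as fs
from femstrength.voxel_fe import MaterialCurve, mesh_from_mask


@pytest.fixture(scope="session")
def scanner():
    return fs.ScannerModel(scanner_id="scanner-0", hu_slope=0.8,
                           hu_intercept=10.0, noise_sd=0.0)


@pytest.fixture(scope="session")
def subject():
    return fs.generate_cohort("astronaut", 1, seed=1)[0]


@pytest.fixture(scope="session")
def calibrated_volume(subject, scanner):
    """Noiseless calibrated femur volume at 5 mm (shared; treat as
    read-only)."""
    vol = fs.generate_volume(subject, scanner, voxel_mm=5.0, seed=2)
    fit = fs.fit_phantom_calibration(vol)
    return fs.apply_calibration(vol, fit)


def make_bar_mesh(nz: int, side_mm: float = 10.0, density: float = 1.0,
                  load_direction=(0, 0, -1)):
    """1x1xnz voxel bar; bottom nodes distal, top nodes head."""
    mask = np.ones((1, 1, nz), bool)
    dens = np.full((1, 1, nz), density)
    # node flat index = x*(2*(nz+1)) + y*(nz+1) + z
    nzp = nz + 1
    bottom = [x * 2 * nzp + y * nzp for x in range(2) for y in range(2)]
    top = [i + nz for i in bottom]
    return mesh_from_mask(mask, (side_mm,) * 3, dens, head_nodes=top,
                          distal_nodes=bottom, load_direction=load_direction)


@pytest.fixture
def linear_curve():
    """Curve with linear density laws and no Poisson coupling, for which
    uniaxial oracles are closed-form."""
    return MaterialCurve(a=10000.0, b=1.0, c=100.0, d=1.0,
                         plateau_strain=0.005, softening_modulus=1000.0,
                         residual_fraction=0.3, poisson=0.0)
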