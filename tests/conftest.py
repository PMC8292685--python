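import numpy as np
import pytest

from phantomiq import (DiskInsert, GridSpec, NoiseModel, PhantomSpec,
                       catphan_presets, generate_stack)

# all grids keep the reference pixel spacing, 400/1024 = 0.390625 mm/px
PIXEL_SPACING = 0.390625


@pytest.fixture(scope="session")
def small_grid():
    """128-px grid (50-mm FOV): one centred 12-mm disk fits with margin."""
    return GridSpec(matrix_size=128, field_of_view=50.0)


@pytest.fixture(scope="session")
def mid_grid():
    """320-px grid (125-mm FOV): full sensitometry layout plus a 256^2 ROI."""
    return GridSpec(matrix_size=320, field_of_view=125.0)


@pytest.fixture(scope="session")
def nps_grid():
    """256-px grid (100-mm FOV): the noise ROI is the whole slice."""
    return GridSpec(matrix_size=256, field_of_view=100.0)


def centered_disk_spec(grid, contrast_hu=120.0, diameter=12.0,
                       blur_sigma_mm=0.0, sigma_hu=0.0, seed=0, n_slices=1,
                       label="disk"):
    return PhantomSpec(
        grid=grid,
        inserts=(DiskInsert((0.0, 0.0), diameter, contrast_hu, label),),
        blur_sigma_mm=blur_sigma_mm,
        noise=NoiseModel(sigma_hu=sigma_hu, seed=seed),
        n_slices=n_slices,
    )


@pytest.fixture(scope="session")
def noisy_sensitometry_stack(mid_grid):
    """Sensitometry module, 15-HU white noise, 50 slices (shared, read-only)."""
    spec = catphan_presets("sensitometry", grid=mid_grid,
                           noise=NoiseModel(sigma_hu=15.0, seed=11),
                           n_slices=50)
    return spec, generate_stack(spec)


def gaussian_f(p: float, sigma_mm: float) -> float:
    """Frequency where a Gaussian MTF exp(-2 pi^2 s^2 f^2) falls to p."""
    return float(np.sqrt(np.log(1.0 / p) / (2.0 * np.pi ** 2 * sigma_mm ** 2)))
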