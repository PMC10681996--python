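import numpy as np
import pandas as pd
import pytest

from aspstrat import (
    AcquisitionSpec,
    GridSpec,
    ShapeSpec,
    make_phantom,
)


@pytest.fixture(scope="session")
def sphere_phantom():
    """Noiseless two-valued sphere phantom: r=10 mm on a 1 mm grid, bg 2."""
    shape = ShapeSpec("sphere", radius=10.0)
    grid = GridSpec((32, 32, 32))
    acq = AcquisitionSpec(tumor_suv=10.0, background_suv=2.0, seed=0)
    vol, gt = make_phantom(shape, grid, acq)
    return vol, gt


@pytest.fixture(scope="session")
def blurred_sphere_phantom():
    """Sphere phantom with a 2-voxel-FWHM PSF, no noise."""
    shape = ShapeSpec("sphere", radius=10.0)
    grid = GridSpec((32, 32, 32))
    acq = AcquisitionSpec(tumor_suv=10.0, background_suv=2.0, psf_fwhm_mm=2.0, seed=0)
    vol, gt = make_phantom(shape, grid, acq)
    return vol, gt


@pytest.fixture(scope="session")
def survival_fixture():
    """Seeded 80-patient survival dataset with a continuous marker effect."""
    rng = np.random.default_rng(2024)
    n = 80
    marker = rng.gamma(4.0, 5.0, size=n)
    t = rng.exponential(1.0 / (0.01 * np.exp(0.03 * marker)))
    c = rng.uniform(10.0, 80.0, size=n)
    records = pd.DataFrame(
        {
            "patient_id": [f"S{i:03d}" for i in range(n)],
            "time": np.minimum(t, c),
            "event": (t <= c).astype(int),
        }
    )
    return records, pd.Series(marker, name="marker")


def digitized_ball(radius_vox: int, offset: float = 0.0):
    """Binary ball mask on a unit grid with a 6-voxel padding margin."""
    n = int(2 * radius_vox + 12)
    c = (n - 1) / 2 + offset
    x, y, z = np.mgrid[:n, :n, :n]
    return (x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2 < radius_vox**2
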