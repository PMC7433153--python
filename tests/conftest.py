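import numpy as np
import pytest

from dectpeel import CalibrationMatrix, PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def calib():
    return CalibrationMatrix(s_low=48.0, s_high=15.0)


@pytest.fixture(scope="session")
def noiseless_phantom(calib):
    return generate_phantom(PhantomSpec(noise_sd=0.0, seed=0), calib)


@pytest.fixture(scope="session")
def noiseless_rim_phantom(calib):
    return generate_phantom(PhantomSpec(noise_sd=0.0, rim=True, seed=0), calib)


@pytest.fixture(scope="session")
def noisy_phantom(calib):
    return generate_phantom(PhantomSpec(noise_sd=5.0, seed=7), calib)


def make_sphere(radius_mm, spacing=0.5, margin_mm=6.0, center_offset=(0, 0, 0)):
    """Rasterized sphere mask (voxel-center semantics) with padding."""
    n = int(np.ceil(2 * (radius_mm + margin_mm) / spacing)) + 1
    c = (n - 1) / 2.0
    idx = np.indices((n, n, n)).astype(float)
    r = np.sqrt(((idx[0] - c - center_offset[0]) ** 2)
                + ((idx[1] - c - center_offset[1]) ** 2)
                + ((idx[2] - c - center_offset[2]) ** 2)) * spacing
    return r <= radius_mm, (spacing,) * 3


@pytest.fixture(scope="session")
def sphere10():
    """10-mm sphere at 0.5-mm isotropic voxels."""
    return make_sphere(10.0, spacing=0.5)
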