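import numpy as np
import pytest

from alphadose.kernel import generate_kernel, radial_average
from alphadose.physics import AT211, load_water_stopping_power


@pytest.fixture(scope="session")
def water():
    return load_water_stopping_power()


@pytest.fixture(scope="session")
def small_kernel(water):
    """Full-chain 1-µm kernel at modest statistics (shared across tests)."""
    return generate_kernel(AT211, water, 50_000, voxel_um=1.0,
                           half_extent_um=75.0, seed=42)


@pytest.fixture(scope="session")
def small_kernel_avg(small_kernel):
    return radial_average(small_kernel)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def blob_image(shape=(64, 64), seed=0, n_blobs=1, smooth=2.0):
    """Smooth asymmetric test image with positive support away from edges."""
    from scipy import ndimage
    rng = np.random.default_rng(seed)
    img = np.zeros(shape)
    for _ in range(n_blobs):
        cy = rng.integers(shape[0] // 4, 3 * shape[0] // 4)
        cx = rng.integers(shape[1] // 4, 3 * shape[1] // 4)
        h = rng.integers(6, shape[0] // 5)
        w = rng.integers(6, shape[1] // 5)
        img[cy - h // 2:cy + h // 2, cx - w // 2:cx + w // 2] += \
            1.0 + rng.random((2 * (h // 2), 2 * (w // 2)))
    return ndimage.gaussian_filter(img, smooth)
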