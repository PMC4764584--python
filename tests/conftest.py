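import numpy as np
import pytest


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def sphere_mask():
    """Digital sphere r=10 in a 32^3 grid."""
    z, y, x = np.mgrid[0:32, 0:32, 0:32]
    return ((z - 16) ** 2 + (y - 16) ** 2 + (x - 16) ** 2) <= 100


@pytest.fixture()
def bent_slab():
    """Sinusoidally bent slab with two surface-touching empty spheres.

    Returns (image, true_top, true_bottom) on a (80, 48, 48) grid.
    """
    gen = np.random.default_rng(2)
    nz, ny, nx = 80, 48, 48
    yy, _ = np.mgrid[0:ny, 0:nx]
    top = 10 + 8 * np.sin(yy / 12.0)
    bot = top + 50
    zz = np.mgrid[0:nz][:, None, None]
    img = np.where((zz >= top[None]) & (zz <= bot[None]), 100.0, 5.0)
    Z, Y, X = np.mgrid[0:nz, 0:ny, 0:nx]
    for (cy, cx) in [(15, 15), (35, 30)]:
        cz = top[cy, cx] + 3
        img[((Z - cz) ** 2 + (Y - cy) ** 2 + (X - cx) ** 2) < 64] = 5.0
    img += gen.normal(0, 3, img.shape)
    return img, top, bot
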