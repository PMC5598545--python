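import numpy as np
import pytest

import vascniche as v

SPACING = (2.0, 0.5, 0.5)  # anisotropic two-photon-like voxel geometry


@pytest.fixture(scope="session")
def tree():
    """Depth-3 binary tree (15 segments) in a 96 um cube."""
    return v.make_vessel_tree((96.0, 96.0, 96.0), depth=3, root_radius=4.0,
                              taper=0.8, seed=1)


@pytest.fixture(scope="session")
def small_tree():
    """Depth-2 tree in a 48 um cube; fits a (24, 96, 96) grid at default
    spacing for fast tests."""
    return v.make_vessel_tree((48.0, 48.0, 48.0), depth=2, root_radius=3.0,
                              taper=0.8, seed=1)


@pytest.fixture(scope="session")
def clean_stack(tree):
    """Noise-free, unblurred stack with 30% extravasation: pre-blur fields
    are exact, so mass bookkeeping oracles apply."""
    return v.render_stack(tree, (48, 192, 192), spacing=SPACING,
                          leak_fraction=0.3, psf_sigma_um=None, noise=None,
                          n_cells=0, seed=2)


@pytest.fixture(scope="session")
def blurred_stack(tree):
    """PSF-blurred but noise-free stack, no extravasation."""
    return v.render_stack(tree, (48, 192, 192), spacing=SPACING,
                          leak_fraction=0.0, psf_sigma_um=(1.5, 0.4, 0.4),
                          noise=None, n_cells=0, seed=2)


def cylinder_mask(radius_vox: float, length: int = 60, pad: int = 4,
                  spacing=(1.0, 1.0, 1.0)) -> v.BinaryMask:
    """Solid axis-aligned cylinder along x, axis at the (z, y) centre."""
    half = int(np.ceil(radius_vox)) + pad
    nz = ny = 2 * half + 1
    zz, yy = np.mgrid[0:nz, 0:ny]
    disc = (zz - half) ** 2 + (yy - half) ** 2 <= radius_vox**2
    mask = np.repeat(disc[:, :, None], length, axis=2)
    return v.BinaryMask(mask, spacing=spacing)
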