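import numpy as np
import pytest

from optgauss.beams import BeamParameters, make_kernel_stamp
from optgauss.projection import ScanGeometry


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_geometry():
    """64-pixel grid, 1 mm field of view, 40 angles over a full turn."""
    return ScanGeometry.full_turn(grid_size=64, field_of_view=1000.0,
                                       n_angles=40)


@pytest.fixture
def dirac_stamp(small_geometry):
    params = BeamParameters(dirac=True)
    return make_kernel_stamp(params, small_geometry.pixel_pitch,
                             small_geometry.diagonal + small_geometry.pixel_pitch)


@pytest.fixture
def gbm_stamp(small_geometry):
    """Thresholded zero-offset Gaussian kernel on the small grid."""
    return make_kernel_stamp(BeamParameters(), small_geometry.pixel_pitch,
                             small_geometry.diagonal + small_geometry.pixel_pitch,
                             apply_threshold=True)


def disk_image(n, radius_px, center=None, value=1.0):
    c = n // 2 if center is None else center
    yy, xx = np.mgrid[0:n, 0:n]
    if np.isscalar(c):
        cy = cx = c
    else:
        cy, cx = c
    img = np.zeros((n, n))
    img[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius_px ** 2] = value
    return img
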