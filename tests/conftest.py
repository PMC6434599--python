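import numpy as np
import pytest

from ectoquant.imquant import RegionSet
from ectoquant.simgen import TissueSimParams, make_tissue_image


def rect(x0, y0, x1, y1):
    return np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]], dtype=float)


@pytest.fixture
def full_frame_regions():
    return RegionSet(roi_polygons=[rect(0, 0, 64, 64)])


@pytest.fixture
def small_tissue_params():
    return TissueSimParams(height_px=96, width_px=96, seed=11)


@pytest.fixture
def small_image(small_tissue_params):
    return make_tissue_image(small_tissue_params)


def pixel_count_oracle(mask):
    """Exhaustive pure-Python pixel loop; the independent area oracle."""
    n = 0
    for row in np.asarray(mask):
        for v in row:
            if v:
                n += 1
    return n
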