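import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rootquant.image_io import GreyImage
from rootquant.segmentation import RootMask

settings.register_profile(
    "deterministic", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.function_scoped_fixture])
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def random_blob_mask(rng, shape=(40, 40), density=0.45, smooth=True):
    """Random binary mask, lightly closed so components are blob-like."""
    from scipy import ndimage
    m = rng.random(shape) < density
    if smooth:
        m = ndimage.binary_closing(m)
        m = ndimage.binary_opening(m)
    return m


def mask_from_array(arr, px_per_mm=None):
    return RootMask(np.asarray(arr, dtype=bool), px_per_mm=px_per_mm)


def grey_from_array(arr, px_per_mm=None):
    return GreyImage(np.asarray(arr, dtype=np.uint8), px_per_mm=px_per_mm)
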