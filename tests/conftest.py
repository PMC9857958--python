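import numpy as np
import pytest

from sffnet.semi_sp import ImageSlice, LesionMask
from sffnet.synthetic import PhantomSpec


@pytest.fixture(scope="session")
def default_spec() -> PhantomSpec:
    return PhantomSpec(seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture()
def blob_slice_and_mask(rng):
    """A 96x96 slice with a filled, irregular blob mask away from borders."""
    h = w = 96
    pixels = rng.random((h, w)).astype(np.float32)
    rows, cols = np.mgrid[0:h, 0:w]
    mask = ((rows - 50) ** 2 / 18**2 + (cols - 42) ** 2 / 11**2) <= 1.0
    sl = ImageSlice(pixels, patient_id="p0", lesion_id="l0", slice_index=0, class_label="HCC")
    return sl, LesionMask(mask.astype(np.uint8))
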