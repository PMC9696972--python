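import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("default")

from simlbp.transform import PixelWindow3x3


@pytest.fixture
def worked_window() -> PixelWindow3x3:
    """The hand-worked 3x3 window: columns (10,40,70), (20,50,80), (30,60,90)."""
    return PixelWindow3x3(SL=(10, 40, 70), SC=(20, 50, 80), SR=(30, 60, 90))


@pytest.fixture
def worked_image() -> np.ndarray:
    """Row-major image whose single interior window is `worked_window`."""
    return np.array([[10, 20, 30], [40, 50, 60], [70, 80, 90]], dtype=np.uint8)


def random_image(rng: np.random.Generator, lo=0, hi=256, shape=None) -> np.ndarray:
    if shape is None:
        shape = (int(rng.integers(8, 65)), int(rng.integers(8, 65)))
    return rng.integers(lo, hi, shape, dtype=np.int64).astype(np.uint8)
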