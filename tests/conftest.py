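import numpy as np
import pytest

from mammocad.io_formats import GrayImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_image(rng, h=8, w=8, max_value=255):
    return GrayImage(rng.integers(0, max_value + 1, size=(h, w),
                                  dtype=np.int64).astype(np.uint8), max_value)


@pytest.fixture
def small_random_image(rng):
    return random_image(rng)
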