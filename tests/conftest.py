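import numpy as np
import pytest

from arkfcm import GrayImage, NeighborhoodSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def spec3():
    return NeighborhoodSpec(window_edge=3)


@pytest.fixture
def random_image(rng):
    """A 16x16 strictly positive random image."""
    return GrayImage(pixels=rng.uniform(10.0, 200.0, size=(16, 16)))
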