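import numpy as np
import pytest

from cervitex.image_prep import RGBImage, quantize


@pytest.fixture
def rng():
    return np.random.default_rng(20230314)


@pytest.fixture
def random_image(rng):
    """A 16x16 random RGB image."""
    return RGBImage(pixels=rng.integers(0, 256, (16, 16, 3), dtype=np.uint8).copy())


def make_random_image(rng, h=16, w=16, label=None):
    return RGBImage(
        pixels=rng.integers(0, 256, (h, w, 3), dtype=np.uint8), label=label
    )


def make_quantized(grid, ng):
    """Wrap an already-quantized integer grid without rescaling."""
    from cervitex.image_prep import QuantizedChannel

    return QuantizedChannel(grid=np.asarray(grid, dtype=np.int64), ng=ng)
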