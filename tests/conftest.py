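import numpy as np
import pytest

from gfpquant import Ellipse, EmbryoPhantomSpec, IntensityImage, MassDisk


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def constant_image():
    def make(value: float, shape=(32, 32)) -> IntensityImage:
        return IntensityImage(np.full(shape, float(value)))

    return make


@pytest.fixture
def basic_spec():
    """A small embryo phantom: dim yolk plus one bright mass."""
    return EmbryoPhantomSpec(
        image_size=(128, 128),
        yolk=Ellipse(center=(64, 64), semi_axes=(50, 60), plateau=20),
        masses=(MassDisk(center=(64, 64), radius=10, intensity=180),),
    )
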