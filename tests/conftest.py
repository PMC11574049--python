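import numpy as np
import pytest

from punctafiber import SyntheticSpec, make_ground_truth, render_image


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spec():
    return SyntheticSpec(image_shape=(128, 128), seed=7)


@pytest.fixture
def small_truth(small_spec):
    return make_ground_truth(small_spec)


@pytest.fixture
def small_channels(small_truth):
    """(fiber_channel, spot_channel) rendered from the small ground truth."""
    return render_image(small_truth)


def random_mask(rng, shape, p=0.5):
    return rng.random(shape) < p
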