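import numpy as np
import pytest

from plasmonet import synthetic
from plasmonet.images import BridgeROI


@pytest.fixture
def clean_string_movie():
    """Noise-free, blur-free string-footprint crossing movie (exact pixels)."""
    spec = synthetic.CrossingMovieSpec(
        footprint="string", noise_sd=0.0, blur_sigma_px=0.0, seed=2
    )
    return synthetic.make_crossing_movie(spec)


@pytest.fixture
def realistic_string_movie():
    """String-footprint crossing movie with camera noise and optics blur."""
    spec = synthetic.CrossingMovieSpec(footprint="string", seed=2)
    return synthetic.make_crossing_movie(spec)


def full_roi(stack_or_image) -> BridgeROI:
    shape = getattr(stack_or_image, "frame_shape", None) or stack_or_image.shape
    return BridgeROI(0, 0, shape[0], shape[1])
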