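import numpy as np
import pytest

from chromafill.colorspace import rgb_to_opponent
from chromafill.receptive_fields import GaussianKernelSpec, compute_channels
from chromafill.stimuli import SquareStimulusSpec, make_square


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def smooth_zero_border(n: int = 32) -> np.ndarray:
    """A smooth 2-D test plane that vanishes on the image border."""
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    window = np.sin(np.pi * yy / (n - 1)) * np.sin(np.pi * xx / (n - 1))
    bump = np.exp(-((xx - n / 2) ** 2 + (yy - n / 3) ** 2) / (n / 3) ** 2)
    return window * (0.5 + bump)


@pytest.fixture
def smooth_plane():
    return smooth_zero_border(32)


@pytest.fixture
def red_square_channels():
    """Receptive-field channels of a small red square (16x16 canvas)."""
    spec = SquareStimulusSpec(canvas=(16, 16), side=6)
    img = make_square(spec)
    return compute_channels(rgb_to_opponent(img), GaussianKernelSpec(11, 3.0))
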