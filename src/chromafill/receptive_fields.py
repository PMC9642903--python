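"""Single- and double-opponent receptive-field filtering.

Single-opponent (SO) cells integrate color over a wide receptive field and
are modeled as a normalized Gaussian low-pass of each opponent plane.
Double-opponent (DO) cells signal chromatic contrast and are modeled as a
discrete Laplacian high-pass.  Both filters use replicate-edge padding so a
spatially constant stimulus is an exact fixed point of the SO filter and
produces a zero DO response; zero padding would inject artificial contrast
at the image frame.

The printed Laplacian kernel has +4 at the center, i.e. it is the negative
of the conventional five-point nabla-squared stencil.  The filling-in module
consumes the DO planes with the matching sign convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from chromafill.colorspace import OpponentImage

#: Discrete Laplacian used for double-opponent receptive fields
#: (negative of the standard 5-point nabla-squared stencil).
LAPLACIAN_KERNEL = np.array(
    [
        [0.0, -1.0, 0.0],
        [-1.0, 4.0, -1.0],
        [0.0, -1.0, 0.0],
    ]
)


@dataclass(frozen=True)
class GaussianKernelSpec:
    """Window size W (odd, pixels) and width sigma (pixels) of the SO filter.

    The model default is W=21, sigma=5; a smaller preset W=11, sigma=3 is
    provided for parameter-sensitivity runs.
    """

    W: int = 21
    sigma: float = 5.0

    def __post_init__(self) -> None:
        if self.W < 3 or self.W % 2 == 0:
            raise ValueError("W must be an odd integer >= 3")
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")


#: Named presets for the SO receptive-field size.
KERNEL_PRESETS = {
    "default": GaussianKernelSpec(21, 5.0),
    "small": GaussianKernelSpec(11, 3.0),
}


@dataclass
class ChannelSet:
    """The six filtered planes feeding the perception pipeline.

    ``so_rg``, ``so_by``, ``i_lpf`` are the Gaussian low-pass (single
    opponent) planes; ``do_rg``, ``do_by``, ``i_onoff`` the Laplacian
    (double opponent / on-off) planes.
    """

    so_rg: np.ndarray
    so_by: np.ndarray
    i_lpf: np.ndarray
    do_rg: np.ndarray
    do_by: np.ndarray
    i_onoff: np.ndarray

    def __post_init__(self) -> None:
        shapes = {
            p.shape
            for p in (self.so_rg, self.so_by, self.i_lpf, self.do_rg, self.do_by, self.i_onoff)
        }
        if len(shapes) != 1:
            raise ValueError("all channel planes must share one shape")

    def as_dict(self) -> dict:
        return {
            "so_rg": self.so_rg,
            "so_by": self.so_by,
            "i_lpf": self.i_lpf,
            "do_rg": self.do_rg,
            "do_by": self.do_by,
            "i_onoff": self.i_onoff,
        }


def make_gaussian_kernel(spec: GaussianKernelSpec) -> np.ndarray:
    """Normalized Gaussian kernel exp(-(x^2+y^2)/(2 sigma^2)) / N on the
    W x W support s = {-floor(W/2), ..., +floor(W/2)}, with N the in-support
    sum.  Symmetric under x <-> -x, y <-> -y and x <-> y; sums to 1."""
    half = spec.W // 2
    coords = np.arange(-half, half + 1, dtype=float)
    xx, yy = np.meshgrid(coords, coords)
    kernel = np.exp(-(xx**2 + yy**2) / (2.0 * spec.sigma**2))
    return kernel / kernel.sum()


def _convolve(plane: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    # Both kernels are point-symmetric, so convolution == correlation.
    return ndimage.convolve(plane, kernel, mode="nearest")


def single_opponent(
    opp: OpponentImage, spec: GaussianKernelSpec = GaussianKernelSpec()
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gaussian low-pass of each opponent plane: (SO_RG, SO_BY, I_LPF)."""
    kernel = make_gaussian_kernel(spec)
    h, w = opp.shape
    if spec.W > h or spec.W > w:
        raise ValueError(f"kernel ({spec.W}px) larger than image ({h}x{w})")
    return tuple(_convolve(p, kernel) for p in (opp.rg, opp.by, opp.intensity))


def double_opponent(opp: OpponentImage) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Laplacian of each opponent plane: (DO_RG, DO_BY, I_on-off).

    Zero in the interior for constant or linear-ramp planes; positive at
    the center of a bright-center stimulus (positive-center kernel).
    """
    h, w = opp.shape
    if h < 3 or w < 3:
        raise ValueError("image must be at least 3 x 3")
    return tuple(_convolve(p, LAPLACIAN_KERNEL) for p in (opp.rg, opp.by, opp.intensity))


def compute_channels(
    opp: OpponentImage, spec: GaussianKernelSpec = GaussianKernelSpec()
) -> ChannelSet:
    """Full receptive-field pass: all six filtered planes from one stimulus."""
    so_rg, so_by, i_lpf = single_opponent(opp, spec)
    do_rg, do_by, i_onoff = double_opponent(opp)
    return ChannelSet(so_rg, so_by, i_lpf, do_rg, do_by, i_onoff)
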