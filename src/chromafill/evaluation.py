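"""Retinex baseline and image-comparison metrics.

The baseline is a single-scale, non-logarithmic Retinex: each RGB channel
minus its Gaussian-blurred self,

    Retinex(x, y, s) = I(x, y) - (I * G)(x, y),

with G(x, y, s) = exp(-(x^2 + y^2) / s^2) normalized to sum 1 over the full
image support.  Small s approaches a delta kernel (output -> 0); large s
subtracts a near-global mean, leaving most of the chromatic content.  The
raw output is signed; :func:`retinex_display` shifts by mid-gray 0.5 and
clips, the standard rendering for difference-of-Gaussian images.

The perceptual distance is a feature-space weighted squared L2 contract:
mean over pixels of sum_l || w_l * (Phi_l(a) - Phi_l(b)) ||^2.  The shipped
default extractor is the identity (pixel space) with unit weight, which
makes the distance a plain mean squared error; learned extractors can be
plugged in through :class:`MetricSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.signal import fftconvolve

from chromafill.colorspace import D65_UV, rgb_to_upvp

_RETINEX_SIZE_CAP = 512 * 512  # full-support kernels get quadratically large


@dataclass(frozen=True)
class RetinexSpec:
    """Spatial scale s (pixels) of the Gaussian surround; applied to each
    of the three image channels separately."""

    s: float = 5.0

    def __post_init__(self) -> None:
        if not self.s > 0:
            raise ValueError("s must be positive")


def _retinex_kernel(shape: tuple[int, int], s: float) -> np.ndarray:
    """Full-support surround kernel exp(-(x^2+y^2)/s^2), sum-normalized.

    The realized support is rounded up to odd dimensions so the kernel has
    an exact center pixel and convolution is alignment-exact (a delta kernel
    reproduces the image)."""
    h, w = shape
    kh = h if h % 2 == 1 else h + 1
    kw = w if w % 2 == 1 else w + 1
    ys = np.arange(kh, dtype=float) - kh // 2
    xs = np.arange(kw, dtype=float) - kw // 2
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    g = np.exp(-(xx**2 + yy**2) / s**2)
    return g / g.sum()


def retinex(img: np.ndarray, spec: RetinexSpec) -> np.ndarray:
    """Signed single-scale Retinex response, per channel.

    The blur uses replicate-edge padding so a constant image yields an
    identically zero response.  Images above 512 x 512 are rejected (the
    explicit full-support kernel would be prohibitive).
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError("expected an H x W x 3 image")
    h, w = img.shape[:2]
    if h * w > _RETINEX_SIZE_CAP:
        raise ValueError("image too large for a full-support surround kernel")
    g = _retinex_kernel((h, w), spec.s)
    pad_h, pad_w = g.shape[0] // 2, g.shape[1] // 2
    out = np.empty_like(img)
    for c in range(3):
        padded = np.pad(img[..., c], ((pad_h, pad_h), (pad_w, pad_w)), mode="edge")
        blur = fftconvolve(padded, g, mode="valid")
        out[..., c] = img[..., c] - blur
    return out


def retinex_display(img: np.ndarray, spec: RetinexSpec) -> np.ndarray:
    """Display variant: signed response shifted by mid-gray and clipped."""
    return np.clip(retinex(img, spec) + 0.5, 0.0, 1.0)


def _identity_features(img: np.ndarray) -> list[np.ndarray]:
    return [np.asarray(img, dtype=float)]


@dataclass
class MetricSpec:
    """Pluggable feature-distance: extractor mapping an image to feature
    layers, and one weight vector (broadcastable) per layer.  The default is
    the identity extractor with unit weight, i.e. pixel-space MSE."""

    feature_extractor: Callable[[np.ndarray], Sequence[np.ndarray]] = _identity_features
    layer_weights: Optional[Sequence] = None


def perceptual_distance(a: np.ndarray, b: np.ndarray, metric: Optional[MetricSpec] = None) -> float:
    """Mean over pixels of the weighted squared feature difference.

    Nonnegative, symmetric, and zero iff the feature stacks agree (iff the
    images agree, under the default identity extractor).
    """
    if metric is None:
        metric = MetricSpec()
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    feats_a = metric.feature_extractor(a)
    feats_b = metric.feature_extractor(b)
    weights = metric.layer_weights or [1.0] * len(feats_a)
    total = 0.0
    for fa, fb, w in zip(feats_a, feats_b, weights):
        diff = np.asarray(w) * (fa - fb)
        n_pixels = diff.shape[0] * diff.shape[1] if diff.ndim >= 2 else diff.size
        total += float(np.sum(diff**2)) / n_pixels
    return total


def chroma_summary(img: np.ndarray, region_mask: Optional[np.ndarray] = None) -> float:
    """Mean u'v' chroma distance from the D65 achromatic point over a region.

    Zero for a pure gray region; undefined (zero-luminance) pixels are
    excluded, and an all-undefined region is an error.
    """
    up, vp, defined = rgb_to_upvp(img)
    if region_mask is None:
        region_mask = np.ones(defined.shape, dtype=bool)
    region_mask = np.asarray(region_mask, dtype=bool)
    if not region_mask.any():
        raise ValueError("empty region mask")
    use = region_mask & defined
    if not use.any():
        raise ValueError("no pixel in the region has defined chromaticity")
    return float(
        np.hypot(up[use] - D65_UV[0], vp[use] - D65_UV[1]).mean()
    )
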