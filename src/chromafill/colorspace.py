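"""Linear opponent color transform, its inverse, and CIE 1976 u'v'
chromaticity for evaluation.

The working color space of the model is a linear opponent space with three
channels: red-green (RG), blue-yellow (BY) and achromatic intensity (I).
The transform is a fixed 3x3 matrix applied per pixel; the intensity row
uses the Rec. 601 luminance weights.  Stored RGB values are treated as the
model's working space throughout the pipeline; gamma decoding is applied
only inside the u'v' chromaticity conversion used for evaluation, which
assumes sRGB primaries and a D65 white.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# Rec. 601 luminance weights used for the achromatic row.
LUMA_R, LUMA_G, LUMA_B = 0.2989, 0.587, 0.114

#: Opponent transform: rows map RGB to (RG, BY, I).
OPPONENT_MATRIX = np.array(
    [
        [1.0 / 2.0, -1.0 / 2.0, 0.0],
        [1.0 / 6.0, 1.0 / 6.0, -2.0 / 6.0],
        [LUMA_R, LUMA_G, LUMA_B],
    ]
)

_OPPONENT_INVERSE = np.linalg.inv(OPPONENT_MATRIX)
assert np.allclose(OPPONENT_MATRIX @ _OPPONENT_INVERSE, np.eye(3), atol=1e-12)

# sRGB (D65) linear-RGB -> XYZ matrix.
_SRGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)


@dataclass
class OpponentImage:
    """Co-registered opponent planes of one stimulus.

    For an RGB image in [0, 1], ``rg`` lies in [-0.5, 0.5], ``by`` in
    [-1/3, 1/3] and ``intensity`` in [0, 0.9999] (the transform's row sums).
    """

    rg: np.ndarray
    by: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        if not (self.rg.shape == self.by.shape == self.intensity.shape):
            raise ValueError("opponent planes must share one shape")

    @property
    def shape(self) -> tuple:
        return self.rg.shape

    def stack(self) -> np.ndarray:
        """Planes as an H x W x 3 array in (RG, BY, I) order."""
        return np.stack([self.rg, self.by, self.intensity], axis=-1)


def _check_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError(f"expected an H x W x 3 array, got shape {img.shape}")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    return img


def rgb_to_opponent(img: np.ndarray) -> OpponentImage:
    """Apply the opponent transform per pixel.

    Linear: the transform of a sum of images equals the sum of transforms.
    Achromatic pixels (r == g == b) map to rg = by = 0.
    """
    img = _check_rgb(img)
    opp = img @ OPPONENT_MATRIX.T
    return OpponentImage(rg=opp[..., 0], by=opp[..., 1], intensity=opp[..., 2])


def opponent_to_rgb(opp: OpponentImage, clip: bool = False) -> np.ndarray:
    """Invert the opponent transform.

    Without clipping this is the exact inverse of :func:`rgb_to_opponent`.
    Filled-in surfaces can push the inverse out of [0, 1]; ``clip=True``
    clamps to the displayable gamut and is intended only for final export,
    never for intermediate algebra.
    """
    rgb = opp.stack() @ _OPPONENT_INVERSE.T
    if clip:
        rgb = np.clip(rgb, 0.0, 1.0)
    return rgb


def _srgb_decode(c: np.ndarray) -> np.ndarray:
    c = np.asarray(c, dtype=float)
    return np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)


def rgb_to_upvp(
    img: np.ndarray, decode_gamma: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pixel CIE 1976 u'v' chromaticity of an sRGB image in [0, 1].

    Chain: sRGB gamma decode -> linear RGB -> XYZ (D65) ->
    u' = 4X / (X + 15Y + 3Z), v' = 9Y / (X + 15Y + 3Z).

    ``decode_gamma=False`` treats the input as already-linear RGB, under
    which chromaticity is exactly invariant to uniform intensity scaling.

    Returns ``(u_prime, v_prime, defined)`` where ``defined`` is a boolean
    mask marking pixels with a nonzero chromaticity denominator.  Undefined
    pixels carry NaN in the coordinate planes and False in the mask; they
    are flagged rather than silently propagated.
    """
    img = _check_rgb(img)
    linear = _srgb_decode(img) if decode_gamma else img
    xyz = linear @ _SRGB_TO_XYZ.T
    x, y, z = xyz[..., 0], xyz[..., 1], xyz[..., 2]
    denom = x + 15.0 * y + 3.0 * z
    defined = denom > 1e-12
    safe = np.where(defined, denom, 1.0)
    up = np.where(defined, 4.0 * x / safe, np.nan)
    vp = np.where(defined, 9.0 * y / safe, np.nan)
    return up, vp, defined


def _d65_uv() -> tuple[float, float]:
    up, vp, _ = rgb_to_upvp(np.ones((1, 1, 3)))
    return float(up[0, 0]), float(vp[0, 0])


#: The D65 achromatic point in (u', v'); distance from it quantifies chroma.
D65_UV = _d65_uv()


def chroma_distance(pt, ref) -> float:
    """Euclidean distance between two (u', v') chromaticity points."""
    pt = np.asarray(pt, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if not (np.all(np.isfinite(pt)) and np.all(np.isfinite(ref))):
        raise ValueError("chromaticity point is undefined")
    return float(np.hypot(pt[0] - ref[0], pt[1] - ref[1]))
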