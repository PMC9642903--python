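"""Synthetic stimulus generators and spatial-profile extraction.

Generators cover the stimuli used to characterize the model: uniform
squares of 5-80 px (filling-in experiments), color-assimilation grids
(a colored 45-degree line family superimposed on a grayscale base), and
globally tinted scenes (color-constancy experiments).  Profile extraction
mirrors the analysis applied to mesoscale cortical recordings: a cut
through the stimulus, averaged over a few parallel lines and smoothed with
a 1-D Gaussian, compared across conditions by ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage, stats

from chromafill.colorspace import OpponentImage, opponent_to_rgb, rgb_to_opponent


@dataclass(frozen=True)
class SquareStimulusSpec:
    """A centered uniform square on a uniform background."""

    canvas: tuple[int, int] = (100, 100)
    side: int = 20
    fill_rgb: tuple[float, float, float] = (1.0, 0.0, 0.0)
    background_rgb: tuple[float, float, float] = (0.5, 0.5, 0.5)

    def __post_init__(self) -> None:
        if self.side < 1:
            raise ValueError("side must be >= 1")
        if self.side > min(self.canvas):
            raise ValueError("square does not fit in canvas")


def make_square(spec: SquareStimulusSpec) -> np.ndarray:
    """Exact centered square: side**2 fill-colored pixels, deterministic."""
    h, w = spec.canvas
    img = np.empty((h, w, 3))
    img[:] = spec.background_rgb
    r0 = (h - spec.side) // 2
    c0 = (w - spec.side) // 2
    img[r0 : r0 + spec.side, c0 : c0 + spec.side] = spec.fill_rgb
    return img


def square_mask(spec: SquareStimulusSpec) -> np.ndarray:
    """Boolean mask of the square's pixels on the canvas."""
    h, w = spec.canvas
    mask = np.zeros((h, w), dtype=bool)
    r0 = (h - spec.side) // 2
    c0 = (w - spec.side) // 2
    mask[r0 : r0 + spec.side, c0 : c0 + spec.side] = True
    return mask


@dataclass
class GridIllusionSpec:
    """Color-assimilation grid: a colored oblique line family over the
    grayscale version of a color image.

    Grid lines take their color from ``color_source`` with chroma amplified
    by ``saturation_ratio`` (applied in opponent space: RG and BY scaled,
    intensity preserved); off-grid pixels are exactly the grayscale base.
    """

    color_source: np.ndarray
    line_width: int = 3
    angle: float = 45.0
    step: int = 15
    saturation_ratio: float = 4.0

    def __post_init__(self) -> None:
        self.color_source = np.asarray(self.color_source, dtype=float)
        if self.color_source.ndim != 3 or self.color_source.shape[-1] != 3:
            raise ValueError("color_source must be H x W x 3")
        if self.step <= self.line_width:
            raise ValueError("step must exceed line_width")


def grid_mask(spec: GridIllusionSpec) -> np.ndarray:
    """Boolean mask of the grid-line pixels.

    Lines run along the given angle; ``step`` is the perpendicular spacing,
    so the covered fraction of a large canvas is ~ line_width / step.
    """
    h, w = spec.color_source.shape[:2]
    theta = np.deg2rad(spec.angle)
    rr, cc = np.mgrid[0:h, 0:w]
    u = cc * np.cos(theta) + rr * np.sin(theta)  # signed distance across lines
    return np.mod(u, spec.step) < spec.line_width


def grayscale_base(color_source: np.ndarray) -> np.ndarray:
    """Achromatic version: zero the chromatic opponent planes, invert back."""
    opp = rgb_to_opponent(color_source)
    gray = OpponentImage(
        rg=np.zeros_like(opp.rg), by=np.zeros_like(opp.by), intensity=opp.intensity
    )
    return opponent_to_rgb(gray, clip=True)


def make_assimilation_grid(spec: GridIllusionSpec) -> np.ndarray:
    """Composite the chroma-amplified grid over the grayscale base."""
    base = grayscale_base(spec.color_source)
    opp = rgb_to_opponent(spec.color_source)
    boosted = OpponentImage(
        rg=spec.saturation_ratio * opp.rg,
        by=spec.saturation_ratio * opp.by,
        intensity=opp.intensity,
    )
    colored = opponent_to_rgb(boosted, clip=True)
    mask = grid_mask(spec)
    out = base.copy()
    out[mask] = colored[mask]
    return out


def apply_illumination(img: np.ndarray, tint_rgb, strength: float) -> np.ndarray:
    """Multiplicative global tint, interpolated with identity by strength.

    strength 0 returns the input; strength 1 multiplies each channel by the
    tint.  A synthetic stand-in for scenes photographed under colored
    illuminants."""
    if not 0.0 <= strength <= 1.0:
        raise ValueError("strength must lie in [0, 1]")
    tint = np.asarray(tint_rgb, dtype=float)
    factor = (1.0 - strength) + strength * tint
    return np.asarray(img, dtype=float) * factor


@dataclass(frozen=True)
class ProfileCut:
    """A cut through a plane: mean over 2*half_width+1 parallel lines around
    ``position`` along ``axis``, then 1-D Gaussian smoothing."""

    axis: str = "row"  # "row": profile along x at a given row
    position: int = 0
    half_width: int = 2
    smoothing_sigma: float = 2.0

    def __post_init__(self) -> None:
        if self.axis not in ("row", "column"):
            raise ValueError("axis must be 'row' or 'column'")
        if self.half_width < 0 or self.smoothing_sigma < 0:
            raise ValueError("half_width and smoothing_sigma must be >= 0")


def extract_profile(plane: np.ndarray, cut: ProfileCut) -> np.ndarray:
    """Averaged, smoothed 1-D spatial profile of a plane along a cut."""
    plane = np.asarray(plane, dtype=float)
    n_across = plane.shape[0] if cut.axis == "row" else plane.shape[1]
    lo = cut.position - cut.half_width
    hi = cut.position + cut.half_width + 1
    if lo < 0 or hi > n_across:
        raise ValueError("cut extends outside the image")
    band = plane[lo:hi, :] if cut.axis == "row" else plane[:, lo:hi].T
    profile = band.mean(axis=0)
    if cut.smoothing_sigma > 0:
        profile = ndimage.gaussian_filter1d(profile, cut.smoothing_sigma, mode="nearest")
    return profile


@dataclass
class ProfileComparison:
    r_squared: float
    p_value: float
    slope: float
    intercept: float
    n: int
    defined: bool = True  # False when a profile has zero variance


def compare_profiles(
    sim: np.ndarray,
    ref: np.ndarray,
    sim_edge: Optional[int] = None,
    ref_edge: Optional[int] = None,
) -> ProfileComparison:
    """Ordinary least-squares fit of a reference profile on a simulated one.

    If edge indices are given, the profiles are shifted so the marked
    stimulus-edge positions coincide and the non-overlapping ends are
    cropped.  A zero-variance profile makes R^2 undefined; this is flagged
    rather than reported as a spurious fit.
    """
    sim = np.asarray(sim, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if sim_edge is not None and ref_edge is not None:
        shift = sim_edge - ref_edge
        sim_al = sim[shift:] if shift >= 0 else sim
        ref_al = ref if shift >= 0 else ref[-shift:]
        n = min(sim_al.size, ref_al.size)
        sim_al, ref_al = sim_al[:n], ref_al[:n]
    else:
        if sim.size != ref.size:
            raise ValueError("profiles must have equal length when no edges are given")
        sim_al, ref_al = sim, ref
    if sim_al.size < 3:
        raise ValueError("aligned profiles too short for regression")
    if np.ptp(sim_al) == 0 or np.ptp(ref_al) == 0:
        return ProfileComparison(
            r_squared=np.nan, p_value=np.nan, slope=np.nan, intercept=np.nan,
            n=sim_al.size, defined=False,
        )
    fit = stats.linregress(sim_al, ref_al)
    return ProfileComparison(
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n=sim_al.size,
    )


def make_color_scene(
    shape: tuple[int, int] = (90, 120), n_patches: int = 6, seed: int = 0
) -> np.ndarray:
    """A simple synthetic colored scene: saturated rectangular patches on a
    mid-gray ground.  Stands in for the photographs used in perceptual
    demonstrations, which are third-party images."""
    rng = np.random.default_rng(seed)
    h, w = shape
    img = np.full((h, w, 3), 0.5)
    for _ in range(n_patches):
        ph = rng.integers(h // 6, h // 2)
        pw = rng.integers(w // 6, w // 2)
        r0 = rng.integers(0, h - ph)
        c0 = rng.integers(0, w - pw)
        color = rng.uniform(0.0, 1.0, size=3)
        # push toward saturation so chroma is non-trivial
        color = np.clip(0.5 + 1.5 * (color - 0.5), 0.0, 1.0)
        img[r0 : r0 + ph, c0 : c0 + pw] = color
    return img
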