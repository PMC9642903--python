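"""Raster and checkpoint I/O: PNG images mapped to [0, 1] floats and a
multi-plane binary container (NumPy .npz) for pipeline intermediates."""

from __future__ import annotations

import numpy as np
import imageio.v3 as iio


def read_png(path) -> np.ndarray:
    """Read an 8- or 16-bit PNG as floats scaled linearly to [0, 1]."""
    arr = iio.imread(path)
    if arr.dtype == np.uint8:
        scale = 255.0
    elif arr.dtype == np.uint16:
        scale = 65535.0
    else:
        raise ValueError(f"unsupported PNG sample type {arr.dtype}")
    img = arr.astype(float) / scale
    if img.ndim == 2:
        img = np.repeat(img[..., None], 3, axis=-1)
    return img[..., :3]  # drop alpha if present


def write_png(path, img: np.ndarray, bitdepth: int = 8) -> None:
    """Write a float image in [0, 1] as a PNG.

    RGB images are written at 8 bits; 16-bit output is supported for
    single-plane (grayscale) images only.  Lossless float round trips go
    through :func:`save_planes` instead.
    """
    img = np.clip(np.asarray(img, dtype=float), 0.0, 1.0)
    if bitdepth == 8:
        out = np.round(img * 255.0).astype(np.uint8)
    elif bitdepth == 16:
        if img.ndim != 2:
            raise ValueError("16-bit PNG output is supported for single-plane images only")
        out = np.round(img * 65535.0).astype(np.uint16)
    else:
        raise ValueError("bitdepth must be 8 or 16")
    iio.imwrite(path, out, extension=".png")


def save_planes(path, **planes: np.ndarray) -> None:
    """Save named float planes losslessly (checkpoint container)."""
    np.savez(path, **planes)


def load_planes(path) -> dict:
    with np.load(path) as data:
        return {k: data[k] for k in data.files}
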