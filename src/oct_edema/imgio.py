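"""Grayscale image I/O: 8/16-bit PNG and TIFF, internal [0, 1] floats.

Integer images are scaled by the maximum representable value of their bit
depth on read and the inverse on write, so an 8-bit round trip is lossless.
Multi-channel inputs are collapsed to a single channel by the mean of the
first three channels, with a logged warning.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

__all__ = ["read_image", "write_image", "write_mask", "read_mask"]

logger = logging.getLogger(__name__)

_TIFF_SUFFIXES = {".tif", ".tiff"}


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale image as float64 in [0, 1]."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        arr = tifffile.imread(path)
    else:
        with Image.open(path) as im:
            arr = np.asarray(im)
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / np.iinfo(arr.dtype).max
    else:
        arr = np.clip(arr.astype(np.float64), 0.0, 1.0)
    if arr.ndim == 3:
        logger.warning("%s: multi-channel input, converting to luminance average", path)
        arr = arr[..., :3].mean(axis=2)
    if arr.ndim != 2:
        raise ValueError(f"{path}: unsupported image dimensionality {arr.ndim}")
    return arr


def write_image(image: np.ndarray, path: str | Path, bit_depth: int = 8) -> None:
    """Write a [0, 1] float image as 8- or 16-bit grayscale PNG/TIFF."""
    path = Path(path)
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if bit_depth == 8:
        dtype = np.uint8
    elif bit_depth == 16:
        dtype = np.uint16
    else:
        raise ValueError(f"unsupported bit depth {bit_depth}")
    maxval = np.iinfo(dtype).max
    quantized = np.clip(np.rint(image * maxval), 0, maxval).astype(dtype)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        tifffile.imwrite(path, quantized)
    else:
        Image.fromarray(quantized).save(path)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as 0/255 8-bit PNG (or TIFF)."""
    write_image(np.asarray(mask, dtype=bool).astype(float), path, bit_depth=8)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a mask image; any nonzero pixel counts as foreground."""
    return read_image(path) > 0.5
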