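"""Image standardization: greyscale conversion, canonical resizing, contrast stretch.

Every downstream stage assumes an 8-bit greyscale raster of exactly
1024 x 1280 pixels (the capture resolution the segmentation offsets were
designed for).  Standardization is: collapse RGB by ITU-R BT.601 luma
weights, scale isotropically to fit the canonical frame, centre-pad with the
median border intensity, then linearly stretch the 1st..99th intensity
percentiles onto [0, 255].

Rounding convention throughout the pipeline: round half away from zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.transform import resize

from .errors import UnsupportedFormatError

logger = logging.getLogger(__name__)

CANONICAL_SHAPE = (1024, 1280)  # (rows, cols)

LUMA_WEIGHTS = (0.299, 0.587, 0.114)

STRETCH_PERCENTILES = (1.0, 99.0)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round half away from zero (values here are non-negative)."""
    return np.floor(np.asarray(x) + 0.5)


@dataclass
class StandardizedImage:
    """Canonical 8-bit greyscale raster plus provenance."""

    raster: np.ndarray                    # uint8, CANONICAL_SHAPE
    source_path: str = "<array>"
    intensity_stretch: tuple[float, float] = (0.0, 255.0)

    def __post_init__(self):
        if self.raster.shape != CANONICAL_SHAPE:
            raise ValueError(f"raster shape {self.raster.shape} != {CANONICAL_SHAPE}")


def to_greyscale(raster: np.ndarray) -> np.ndarray:
    """Collapse an 8-bit image to one channel by 0.299/0.587/0.114 luma."""
    arr = np.asarray(raster)
    if arr.ndim == 2:
        return arr.astype(np.uint8)
    if arr.ndim == 3 and arr.shape[2] == 3:
        w = np.asarray(LUMA_WEIGHTS)
        grey = arr.astype(np.float64) @ w
        return _round_half_away(grey).astype(np.uint8)
    if arr.ndim == 3 and arr.shape[2] == 1:
        return arr[:, :, 0].astype(np.uint8)
    raise UnsupportedFormatError(
        f"expected 1- or 3-channel 8-bit image, got shape {arr.shape}")


def resize_and_pad(raster: np.ndarray,
                   canonical_shape: tuple[int, int] = CANONICAL_SHAPE) -> np.ndarray:
    """Scale isotropically into the canonical frame; centre-pad the rest.

    Padding uses the median intensity of the input's border pixels so the
    pad blends with the background rather than introducing a hard edge.
    """
    arr = np.asarray(raster)
    if arr.size == 0:
        raise UnsupportedFormatError("empty raster")
    rows, cols = arr.shape
    tr, tc = canonical_shape
    scale = min(tr / rows, tc / cols)
    new_rows = int(round(rows * scale))
    new_cols = int(round(cols * scale))
    if (new_rows, new_cols) == (rows, cols):
        content = arr.astype(np.uint8)
    else:
        scaled = resize(arr.astype(np.float64), (new_rows, new_cols), order=1,
                        mode="edge", anti_aliasing=scale < 1.0)
        content = np.clip(_round_half_away(scaled), 0, 255).astype(np.uint8)

    if (new_rows, new_cols) == (tr, tc):
        return content

    border = np.concatenate([arr[0, :], arr[-1, :], arr[:, 0], arr[:, -1]])
    fill = int(np.median(border))
    out = np.full(canonical_shape, fill, dtype=np.uint8)
    off_r = (tr - new_rows) // 2
    off_c = (tc - new_cols) // 2
    out[off_r:off_r + new_rows, off_c:off_c + new_cols] = content
    return out


def adjust_intensity(raster: np.ndarray) -> tuple[np.ndarray, tuple[float, float]]:
    """Linear contrast stretch of the 1st..99th percentile onto [0, 255].

    Returns the stretched raster and the ``(low_in, high_in)`` grey levels
    used.  A constant image is returned unchanged (with a warning) since no
    stretch is defined.
    """
    arr = np.asarray(raster).astype(np.float64)
    low_in, high_in = np.percentile(arr, STRETCH_PERCENTILES)
    if high_in <= low_in:
        logger.warning("constant image: intensity adjustment skipped")
        return np.asarray(raster).astype(np.uint8), (float(low_in), float(high_in))
    out = 255.0 * (arr - low_in) / (high_in - low_in)
    out = np.clip(_round_half_away(np.clip(out, 0.0, 255.0)), 0, 255)
    return out.astype(np.uint8), (float(low_in), float(high_in))


def standardize(raster: np.ndarray, source_path: str = "<array>") -> StandardizedImage:
    """Full standardization: greyscale -> canonical size -> contrast stretch."""
    grey = to_greyscale(raster)
    sized = resize_and_pad(grey)
    stretched, bounds = adjust_intensity(sized)
    return StandardizedImage(raster=stretched, source_path=source_path,
                             intensity_stretch=bounds)


def standardize_file(path: str | Path) -> StandardizedImage:
    """Read a PNG/JPEG/TIFF micrograph and standardize it."""
    arr = iio.imread(path)
    return standardize(arr, source_path=str(path))
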