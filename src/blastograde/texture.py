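"""Grey-level co-occurrence matrices and Haralick-style statistics on masked regions.

Intensities are first requantized to 8 grey shades (equal-width bins,
``level = floor(v / 32)``).  The GLCM ``P(i, j)`` is the joint distribution
of quantized levels of pixel pairs at offset distance ``d`` over a set of
angles, counting only pairs where *both* pixels lie inside the region mask,
accumulated symmetrically and normalized to sum 1.  Defaults: ``d = 1`` and
the four standard angles 0/45/90/135 degrees averaged together.

Statistics follow the classic definitions:

* contrast     = sum (i-j)^2 p(i,j)
* correlation  = sum (i-mu_i)(j-mu_j) p(i,j) / (sigma_i sigma_j)
* energy       = sum p(i,j)^2            (angular second moment)
* homogeneity  = sum p(i,j) / (1 + |i-j|)

A region with zero intensity variance has undefined correlation; it is set
to 1 by convention so feature vectors stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyRegionError

LEVELS = 8

#: angle -> (row, col) pixel offset per unit distance, skimage convention
ANGLE_OFFSETS = {
    0: (0, 1),
    45: (-1, 1),
    90: (-1, 0),
    135: (-1, -1),
}

DEFAULT_ANGLES = (0, 45, 90, 135)


@dataclass
class GLCM:
    P: np.ndarray = field(repr=False)   # (LEVELS, LEVELS) probabilities
    d: int = 1
    angles: tuple[int, ...] = DEFAULT_ANGLES
    levels: int = LEVELS


@dataclass
class TextureStats:
    contrast: float
    correlation: float
    energy: float
    homogeneity: float


def quantize8(raster: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Requantize an 8-bit raster to 8 levels: ``floor(v / 32)``."""
    if mask is not None and not np.any(mask):
        raise EmptyRegionError("quantize8: empty mask")
    return (np.asarray(raster).astype(np.int64) // 32).astype(np.uint8)


def compute_glcm(quantized: np.ndarray, mask: np.ndarray, d: int = 1,
                 angles: tuple[int, ...] = DEFAULT_ANGLES) -> GLCM:
    """Symmetric, normalized co-occurrence matrix over a masked region.

    Every ordered pair of pixels at the offset of each listed angle is
    counted when both endpoints are in ``mask``; the transposed pair is
    added for symmetry before normalization.
    """
    q = np.asarray(quantized, dtype=np.intp)
    m = np.asarray(mask, dtype=bool)
    if d < 1:
        raise ValueError("d must be >= 1")
    if not m.any():
        raise EmptyRegionError("compute_glcm: empty mask")
    counts = np.zeros((LEVELS, LEVELS), dtype=np.float64)
    rows, cols = q.shape
    for angle in angles:
        dr, dc = ANGLE_OFFSETS[angle]
        dr, dc = dr * d, dc * d
        # overlap slices: base pixel at (r, c), neighbour at (r+dr, c+dc)
        br0, br1 = max(0, -dr), min(rows, rows - dr)
        bc0, bc1 = max(0, -dc), min(cols, cols - dc)
        if br0 >= br1 or bc0 >= bc1:
            continue
        base = (slice(br0, br1), slice(bc0, bc1))
        nbr = (slice(br0 + dr, br1 + dr), slice(bc0 + dc, bc1 + dc))
        valid = m[base] & m[nbr]
        if not valid.any():
            continue
        i = q[base][valid]
        j = q[nbr][valid]
        np.add.at(counts, (i, j), 1.0)
        np.add.at(counts, (j, i), 1.0)
    total = counts.sum()
    if total == 0:
        raise EmptyRegionError("compute_glcm: mask contains no valid pixel pair")
    return GLCM(P=counts / total, d=d, angles=tuple(angles))


def texture_stats(glcm: GLCM) -> TextureStats:
    """Contrast, correlation, energy and homogeneity of a GLCM."""
    p = glcm.P
    idx = np.arange(glcm.levels, dtype=np.float64)
    i = idx[:, None]
    j = idx[None, :]
    contrast = float(np.sum((i - j) ** 2 * p))
    energy = float(np.sum(p ** 2))
    homogeneity = float(np.sum(p / (1.0 + np.abs(i - j))))
    mu_i = float(np.sum(i * p))
    mu_j = float(np.sum(j * p))
    var_i = float(np.sum((i - mu_i) ** 2 * p))
    var_j = float(np.sum((j - mu_j) ** 2 * p))
    denom = np.sqrt(var_i * var_j)
    if denom <= 0:
        correlation = 1.0  # degenerate (constant) region convention
    else:
        correlation = float(np.sum((i - mu_i) * (j - mu_j) * p) / denom)
    return TextureStats(contrast=contrast, correlation=correlation,
                        energy=energy, homogeneity=homogeneity)


def region_texture(raster: np.ndarray, mask: np.ndarray, d: int = 1,
                   angles: tuple[int, ...] = DEFAULT_ANGLES) -> TextureStats:
    """Quantize, build the GLCM and evaluate its statistics in one call."""
    return texture_stats(compute_glcm(quantize8(raster, mask), mask, d=d, angles=angles))
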