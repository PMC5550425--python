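"""Embryo localisation and the ER / RR / TE region masks.

The embryo is found from a smoothed gradient-magnitude edge map: Otsu
threshold, morphological closing (disk radius 5), hole filling, largest
connected component.  Its centre is the component centroid and its radius
the equivalent-circle radius ``sqrt(area / pi)`` — robust to zona
irregularities that would inflate a max centroid-boundary distance.

Region masks derived from the fitted circle (pixel-centre membership rule,
Euclidean distance <= radius):

* ER — expanded radius, circle radius + 5 px
* RR — reduced radius, circle radius - 40 px
* TE — the annulus between them (ER and not RR), 45 px wide

The +5 / -40 pixel offsets are fixed constants meaningful at the canonical
1024 x 1280 resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import filters, morphology

from .errors import EmbryoNotFoundError, EmbryoTooSmallError
from .standardize import StandardizedImage

ER_OFFSET = 5.0
RR_OFFSET = 40.0

#: minimum embryo-component area as a fraction of the frame
MIN_AREA_FRACTION = 0.01

_EDGE_SMOOTH_SIGMA = 2.0
_CLOSING_RADIUS = 5


@dataclass
class EmbryoGeometry:
    """Fitted embryo circle and the derived ER/RR/TE masks."""

    center: tuple[float, float]       # (row, col)
    radius: float
    frame_shape: tuple[int, int]
    er_mask: np.ndarray = field(repr=False)
    rr_mask: np.ndarray = field(repr=False)
    te_mask: np.ndarray = field(repr=False)

    @property
    def er_radius(self) -> float:
        return self.radius + ER_OFFSET

    @property
    def rr_radius(self) -> float:
        return self.radius - RR_OFFSET


def _raster(img) -> np.ndarray:
    return img.raster if isinstance(img, StandardizedImage) else np.asarray(img)


def detect_embryo(img: StandardizedImage | np.ndarray) -> tuple[tuple[float, float], float]:
    """Locate the embryo; returns ``((row, col), radius)``.

    Raises :class:`EmbryoNotFoundError` when no connected edge component
    covers at least 1% of the frame (e.g. a blank image).
    """
    raster = _raster(img).astype(np.float64)
    smoothed = ndimage.gaussian_filter(raster, _EDGE_SMOOTH_SIGMA)
    # sqrt-compressed gradient magnitude: Otsu then separates faint but
    # contiguous boundary edges from noise instead of being dominated by
    # the few very strong interior edges
    edges = np.sqrt(filters.sobel(smoothed))
    if edges.max() <= 0:
        raise EmbryoNotFoundError("no embryo found: image has no edges")
    binary = edges > filters.threshold_otsu(edges)
    closed = morphology.closing(binary, morphology.disk(_CLOSING_RADIUS))
    filled = ndimage.binary_fill_holes(closed)
    labels, n = ndimage.label(filled)
    if n == 0:
        raise EmbryoNotFoundError("no embryo found: empty edge map")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    best = 1 + int(np.argmax(sizes))
    area = float(sizes[best - 1])
    if area < MIN_AREA_FRACTION * raster.size:
        raise EmbryoNotFoundError(
            f"no embryo found: largest component covers {area:.0f} px "
            f"(< {MIN_AREA_FRACTION:.0%} of the frame)")
    cr, cc = ndimage.center_of_mass(labels == best)
    radius = float(np.sqrt(area / np.pi))
    # report at pixel precision: sub-pixel jitter in the centroid/area would
    # otherwise propagate into mask rasterization and make downstream
    # region statistics unstable under pure image translation
    return (float(round(cr)), float(round(cc))), float(round(radius))


def _disk_mask(center: tuple[float, float], radius: float,
               frame_shape: tuple[int, int]) -> np.ndarray:
    rows = np.arange(frame_shape[0], dtype=np.float64)[:, None] - center[0]
    cols = np.arange(frame_shape[1], dtype=np.float64)[None, :] - center[1]
    return rows ** 2 + cols ** 2 <= radius ** 2


def build_masks(center: tuple[float, float], radius: float,
                frame_shape: tuple[int, int]) -> EmbryoGeometry:
    """Build the ER/RR/TE masks for a fitted circle, clipped to the frame."""
    if radius <= RR_OFFSET:
        raise EmbryoTooSmallError(
            f"embryo too small: radius {radius:.1f} <= {RR_OFFSET:.0f} px")
    er = _disk_mask(center, radius + ER_OFFSET, frame_shape)
    rr = _disk_mask(center, radius - RR_OFFSET, frame_shape)
    te = er & ~rr
    return EmbryoGeometry(center=center, radius=float(radius),
                          frame_shape=frame_shape,
                          er_mask=er, rr_mask=rr, te_mask=te)


def segment(img: StandardizedImage | np.ndarray) -> EmbryoGeometry:
    """Detect the embryo and build its region masks in one call."""
    raster = _raster(img)
    center, radius = detect_embryo(raster)
    return build_masks(center, radius, raster.shape)
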