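"""Watershed transform inside the embryo region and inner-cell-mass extraction.

The intensity surface (dark = deep) restricted to the ER mask is smoothed
(Gaussian, sigma 2 px) and its shallow minima are suppressed with an
h-minima transform (h = 4 grey levels) so that sensor noise does not
shatter the region into thousands of basins.  Flooding from the remaining
minima partitions the ER mask into labelled drainage basins.  The inner
cell mass — a comparatively homogeneous dark region — produces the deepest
wide basin, so the largest basin is taken as the ICM mask.  The basin count
(after suppression) is the WSN feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import measure, morphology, segmentation as skseg

from .errors import EmptyRegionError
from .segmentation import EmbryoGeometry
from .standardize import StandardizedImage

SMOOTH_SIGMA = 2.0
H_MINIMA_DEPTH = 4.0


@dataclass
class WatershedResult:
    label_raster: np.ndarray = field(repr=False)  # 0 outside ER, 1..K basins
    wsn: int = 0
    icm_mask: np.ndarray = field(repr=False, default=None)
    icm_area: int = 0


@dataclass
class ICMStats:
    convex_icm: float    # solidity = area / convex hull area
    eccen_icm: float     # moment-ellipse eccentricity
    mean_icm: float      # mean grey level over the mask


def _raster(img) -> np.ndarray:
    return img.raster if isinstance(img, StandardizedImage) else np.asarray(img)


def watershed_embryo(img: StandardizedImage | np.ndarray, geom: EmbryoGeometry,
                     smooth_sigma: float = SMOOTH_SIGMA,
                     h: float = H_MINIMA_DEPTH) -> WatershedResult:
    """Partition the ER region into drainage basins; largest basin = ICM."""
    raster = _raster(img).astype(np.float64)
    mask = geom.er_mask
    if not mask.any():
        raise EmptyRegionError("watershed_embryo: empty ER mask")

    # crop to the mask bounding box for speed
    rr, cc = np.nonzero(mask)
    r0, r1 = rr.min(), rr.max() + 1
    c0, c1 = cc.min(), cc.max() + 1
    sub = raster[r0:r1, c0:c1]
    submask = mask[r0:r1, c0:c1]

    surface = ndimage.gaussian_filter(sub, smooth_sigma)
    # outside the mask the surface is a high plateau so no minima leak in
    high = surface.max() + h + 1.0
    surface = np.where(submask, surface, high)
    suppressed = _suppressed(surface, h)

    minima = morphology.local_minima(suppressed) & submask
    markers, k = ndimage.label(minima)
    if k == 0:
        # constant region: a single basin covering the whole mask
        labels_sub = submask.astype(np.int32)
        k = 1
    else:
        labels_sub = skseg.watershed(suppressed, markers=markers, mask=submask)

    label_raster = np.zeros(raster.shape, dtype=np.int32)
    label_raster[r0:r1, c0:c1] = labels_sub
    areas = np.bincount(label_raster.ravel(), minlength=k + 1)[1:]
    best = 1 + int(np.argmax(areas))
    icm_mask = label_raster == best
    return WatershedResult(label_raster=label_raster, wsn=int(k),
                           icm_mask=icm_mask, icm_area=int(areas[best - 1]))


def _suppressed(surface: np.ndarray, h: float) -> np.ndarray:
    """Surface with minima shallower than ``h`` removed (fill-by-reconstruction)."""
    if h <= 0:
        return surface
    filled = morphology.reconstruction(surface + h, surface, method="erosion")
    return filled


def icm_stats(img: StandardizedImage | np.ndarray, icm_mask: np.ndarray) -> ICMStats:
    """Solidity, moment-ellipse eccentricity and mean intensity of the ICM."""
    raster = _raster(img)
    m = np.asarray(icm_mask, dtype=bool)
    if not m.any():
        raise EmptyRegionError("icm_stats: empty ICM mask")
    props = measure.regionprops(m.astype(np.uint8), intensity_image=raster)[0]
    return ICMStats(convex_icm=float(props.solidity),
                    eccen_icm=float(props.eccentricity),
                    mean_icm=float(props.intensity_mean))


def write_basin_overlay(path: str | Path, result: WatershedResult, seed: int = 0):
    """Write a random-colour-per-basin PNG visualisation of the watershed."""
    import imageio.v3 as iio

    rng = np.random.default_rng(seed)
    k = int(result.label_raster.max())
    lut = np.zeros((k + 1, 3), dtype=np.uint8)
    lut[1:] = rng.integers(40, 255, size=(k, 3), dtype=np.uint8)
    iio.imwrite(Path(path), lut[result.label_raster])
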