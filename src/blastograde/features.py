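"""Assembly of the canonical 36-variable feature vector per embryo image.

Variables are computed over three concentric regions derived from the
fitted embryo circle — ER (expanded radius, +5 px), RR (reduced radius,
-40 px) and TE (the 45 px annulus between them) — plus the watershed-derived
inner cell mass:

* per region ER/RR/TE: GLCM correlation, energy, homogeneity; mean; mode
  (ties -> smallest grey level); "mean count" (pixels within +/-5 grey
  levels of the region mean); "bright" (pixels >= 200)   -> 21 variables
* GLCM contrast for RR and TE                            -> 2
* C1..C4 and Mean C1..Mean C4: the TE annulus split into four equal-width
  concentric sub-rings, C1 outermost; Ck counts sub-ring pixels darker than
  the ER mean, Mean Ck is the sub-ring mean intensity     -> 8
* Sum: total intensity over the ER mask                  -> 1
* WSN: watershed basin count                             -> 1
* Convex ICM (solidity), Eccen ICM, Mean ICM             -> 3

The 24 variables that survive collinearity pruning are fixed by name in
:data:`SURVIVING_24`; the remaining 12 complete the natural grid of
region x statistic combinations (GLCM contrast over ER is excluded so the
roster lands on exactly 36).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import icm as icm_mod
from . import segmentation as seg_mod
from . import texture as tex_mod
from .errors import EmptyRegionError
from .standardize import StandardizedImage, standardize_file

BRIGHT_THRESHOLD = 200
MEAN_COUNT_TOLERANCE = 5
N_SUBRINGS = 4

REGIONS = ("ER", "RR", "TE")

#: canonical order of the full 36-variable roster
FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"{stat} {region}" for region in REGIONS
     for stat in ("Correlation", "Energy", "Homogeneity", "Mean", "Mode",
                  "Mean Count", "Bright")]
    + ["Contrast RR", "Contrast TE"]
    + [name for k in range(1, N_SUBRINGS + 1) for name in (f"C{k}", f"Mean C{k}")]
    + ["Sum", "WSN", "Convex ICM", "Eccen ICM", "Mean ICM"]
)

#: the 24 variables that survive the collinearity analysis, by exact name
SURVIVING_24: tuple[str, ...] = (
    "Correlation RR", "Energy RR", "Correlation TE", "Homogeneity TE",
    "C1", "Mean C1", "C2", "Mean C2", "C3", "Mean C3", "C4", "Mean C4",
    "Sum", "Mean ER", "Mode RR", "Mean Count RR", "Bright RR",
    "Mode TE", "Mean Count TE", "Bright TE",
    "WSN", "Convex ICM", "Eccen ICM", "Mean ICM",
)

assert len(FEATURE_NAMES) == 36 and len(set(FEATURE_NAMES)) == 36
assert set(SURVIVING_24) <= set(FEATURE_NAMES)


def intensity_stats(img: StandardizedImage | np.ndarray,
                    mask: np.ndarray) -> tuple[float, int, int, int]:
    """``(mean, mode, mean_count, bright)`` over a masked region.

    mode ties break to the smallest grey level; mean_count counts pixels
    within +/-5 grey levels of the mean; bright counts pixels >= 200.
    """
    raster = img.raster if isinstance(img, StandardizedImage) else np.asarray(img)
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise EmptyRegionError("intensity_stats: empty mask")
    vals = raster[m].astype(np.int64)
    mean = float(vals.mean())
    hist = np.bincount(vals, minlength=256)
    mode = int(np.argmax(hist))  # argmax returns the first (smallest) maximum
    mean_count = int(np.count_nonzero(np.abs(vals - mean) <= MEAN_COUNT_TOLERANCE))
    bright = int(np.count_nonzero(vals >= BRIGHT_THRESHOLD))
    return mean, mode, mean_count, bright


def ring_descriptors(img: StandardizedImage | np.ndarray,
                     geom: seg_mod.EmbryoGeometry) -> dict[str, float]:
    """C1..C4 and Mean C1..Mean C4 over four equal-width TE sub-rings.

    Sub-ring k spans radii ``[er - k*w, er - (k-1)*w)`` with
    ``w = (er - rr) / 4`` so C1 is outermost and C4 innermost.  A pixel
    counts toward Ck when it is strictly darker than the ER-region mean.
    An empty sub-ring contributes count 0 and the ER mean as its mean.
    """
    raster = img.raster if isinstance(img, StandardizedImage) else np.asarray(img)
    er_mean = float(raster[geom.er_mask].mean())
    cr, cc = geom.center
    rows = np.arange(raster.shape[0], dtype=np.float64)[:, None] - cr
    cols = np.arange(raster.shape[1], dtype=np.float64)[None, :] - cc
    dist2 = rows ** 2 + cols ** 2
    width = (geom.er_radius - geom.rr_radius) / N_SUBRINGS
    out: dict[str, float] = {}
    for k in range(1, N_SUBRINGS + 1):
        outer = geom.er_radius - (k - 1) * width
        inner = geom.er_radius - k * width
        ring = geom.te_mask & (dist2 <= outer ** 2) & (dist2 > inner ** 2)
        if k == N_SUBRINGS:  # include the inner boundary circle itself
            ring = geom.te_mask & (dist2 <= outer ** 2) & (dist2 > geom.rr_radius ** 2)
        vals = raster[ring]
        if vals.size == 0:
            out[f"C{k}"] = 0.0
            out[f"Mean C{k}"] = er_mean
        else:
            out[f"C{k}"] = float(np.count_nonzero(vals < er_mean))
            out[f"Mean C{k}"] = float(vals.mean())
    return out


def extract_all(img: StandardizedImage | np.ndarray,
                geom: seg_mod.EmbryoGeometry | None = None,
                watershed: icm_mod.WatershedResult | None = None) -> pd.Series:
    """Compute the canonical 36-variable vector for one standardized image.

    Segmentation and watershed results may be passed in when already
    computed (e.g. by a harness that also inspects them); otherwise they
    are derived here.  Returns a :class:`pandas.Series` indexed by
    :data:`FEATURE_NAMES` in canonical order.
    """
    raster = img.raster if isinstance(img, StandardizedImage) else np.asarray(img)
    if geom is None:
        geom = seg_mod.segment(raster)
    if watershed is None:
        watershed = icm_mod.watershed_embryo(raster, geom)

    values: dict[str, float] = {}
    masks = {"ER": geom.er_mask, "RR": geom.rr_mask, "TE": geom.te_mask}
    quantized = tex_mod.quantize8(raster)
    for region, mask in masks.items():
        stats = tex_mod.texture_stats(tex_mod.compute_glcm(quantized, mask))
        values[f"Correlation {region}"] = stats.correlation
        values[f"Energy {region}"] = stats.energy
        values[f"Homogeneity {region}"] = stats.homogeneity
        if region in ("RR", "TE"):
            values[f"Contrast {region}"] = stats.contrast
        mean, mode, mean_count, bright = intensity_stats(raster, mask)
        values[f"Mean {region}"] = mean
        values[f"Mode {region}"] = float(mode)
        values[f"Mean Count {region}"] = float(mean_count)
        values[f"Bright {region}"] = float(bright)

    values.update(ring_descriptors(raster, geom))
    values["Sum"] = float(raster[geom.er_mask].astype(np.int64).sum())
    values["WSN"] = float(watershed.wsn)
    stats = icm_mod.icm_stats(raster, watershed.icm_mask)
    values["Convex ICM"] = stats.convex_icm
    values["Eccen ICM"] = stats.eccen_icm
    values["Mean ICM"] = stats.mean_icm

    vec = pd.Series([values[name] for name in FEATURE_NAMES],
                    index=list(FEATURE_NAMES), dtype=float)
    if not np.isfinite(vec.to_numpy()).all():
        bad = [n for n, v in vec.items() if not np.isfinite(v)]
        raise ValueError(f"non-finite feature values: {bad}")
    return vec


def extract_directory(image_dir: str | Path, manifest: str | Path | None = None,
                      out_csv: str | Path | None = None) -> pd.DataFrame:
    """Extract features for every image in a manifest (or directory).

    Returns a table ``file, grade, <36 features>``; grade is NaN when no
    manifest provides it.
    """
    image_dir = Path(image_dir)
    if manifest is not None:
        man = pd.read_csv(manifest)
        files = list(man["file"])
        grades = list(man["grade"])
    else:
        files = sorted(p.name for p in image_dir.iterdir()
                       if p.suffix.lower() in (".png", ".jpg", ".jpeg", ".tif", ".tiff")
                       and not p.stem.endswith("_icm"))
        grades = [np.nan] * len(files)

    rows = []
    for fname, grade in zip(files, grades):
        std = standardize_file(image_dir / fname)
        vec = extract_all(std)
        row = {"file": fname, "grade": grade}
        row.update(vec.to_dict())
        rows.append(row)
    table = pd.DataFrame(rows, columns=["file", "grade", *FEATURE_NAMES])
    if out_csv is not None:
        table.to_csv(out_csv, index=False)
    return table
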