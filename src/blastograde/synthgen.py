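"""Seeded generator of synthetic bright-field blastocyst micrographs.

Real expanded bovine blastocysts photographed on an inverted microscope show
a roughly centred circular embryo: a bright zona pellucida ring at the
boundary, a textured trophectoderm annulus of dark cell profiles just inside
it, a lighter fluid-filled blastocoel, and one compact dark eccentric inner
cell mass (ICM).  Quality degrades from IETS grade 1 (excellent/good) through
2 (fair) to 3 (poor) as the ICM shrinks and loses contrast, the
trophectoderm texture coarsens and the outline grows irregular.

The generator plants exactly those structures with grade-dependent
degradation knobs drawn from *overlapping* distributions, so downstream
classification is learnable but not trivial — mimicking the disagreement of
human raters.  Every image carries its ground truth (grade, circle geometry,
ICM mask) for use as an oracle by segmentation and classification tests.

All randomness flows from ``SynthParams.seed``; identical parameters give
bit-identical rasters.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .errors import ConfigurationError

CANONICAL_WIDTH = 1280
CANONICAL_HEIGHT = 1024

#: margin (pixels) that must separate the embryo from the frame edge
FRAME_MARGIN = 20

# Grade-degradation knob schedules, linear in a continuous "degradation
# level" centred on the nominal grade (1, 2 or 3) with jitter sd 0.3 so the
# grade distributions overlap.  Values chosen to look like 32x bright-field
# capture: background ~180 grey, blastocoel slightly lighter, ICM 60-100
# grey below the blastocoel for a grade-1 embryo.
_ICM_RADIUS_FRAC = (0.40, -0.075)      # fraction of embryo radius: a + b*(level-1)
_ICM_INTENSITY = (88.0, 30.0)          # grey level of ICM interior
_TE_BLOB_DEPTH = (70.0, -17.0)         # contrast of trophectoderm cell blobs
_TE_BLOB_SIGMA = (4.0, 2.2)            # blob scale (px)
_TE_BLOB_COUNT = (90.0, -18.0)
_BOUNDARY_WOBBLE = (2.0, 3.0)          # zona ring radial irregularity (px)

_BACKGROUND_MEAN = 180.0
_BLASTOCOEL_MEAN = 196.0
_ZONA_GAIN = 42.0
_ZONA_SIGMA = 5.0


@dataclass(frozen=True)
class SynthParams:
    """Parameters of one synthetic micrograph."""

    seed: int
    grade: int
    width: int = CANONICAL_WIDTH
    height: int = CANONICAL_HEIGHT
    embryo_radius_range: tuple[float, float] = (180.0, 260.0)
    noise_sd: float = 6.0
    background_gradient_amplitude: float = 18.0
    center_jitter: float = 40.0

    def __post_init__(self):
        if self.grade not in (1, 2, 3):
            raise ConfigurationError(f"grade must be 1, 2 or 3, got {self.grade}")
        r_lo, r_hi = self.embryo_radius_range
        if not (0 < r_lo <= r_hi):
            raise ConfigurationError("embryo_radius_range must be positive and ordered")
        half = min(self.width, self.height) / 2.0
        if r_hi + self.center_jitter + FRAME_MARGIN > half:
            raise ConfigurationError(
                f"radius range {self.embryo_radius_range} with jitter "
                f"{self.center_jitter} cannot fit a {self.width}x{self.height} frame "
                f"with a {FRAME_MARGIN}px margin"
            )


@dataclass
class SynthTruth:
    """Planted ground truth accompanying a generated image."""

    grade: int
    center: tuple[float, float]          # (row, col)
    radius: float
    icm_mask: np.ndarray = field(repr=False)  # bool, full frame
    icm_centroid: tuple[float, float] = (0.0, 0.0)


def _knob(schedule: tuple[float, float], level: float) -> float:
    a, b = schedule
    return a + b * (level - 1.0)


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int],
                  scale: float, sd: float) -> np.ndarray:
    """Band-limited noise: coarse Gaussian grid bilinearly upsampled."""
    coarse_shape = (max(2, int(np.ceil(shape[0] / scale)) + 1),
                    max(2, int(np.ceil(shape[1] / scale)) + 1))
    coarse = rng.normal(0.0, sd, size=coarse_shape)
    zoom = (shape[0] / coarse_shape[0], shape[1] / coarse_shape[1])
    out = ndimage.zoom(coarse, zoom, order=1, grid_mode=True, mode="nearest")
    return out[: shape[0], : shape[1]]


def generate_image(params: SynthParams) -> tuple[np.ndarray, SynthTruth]:
    """Render one synthetic blastocyst micrograph.

    Returns an 8-bit greyscale raster ``(height, width)`` and the
    :class:`SynthTruth` describing everything that was planted.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.height, params.width

    radius = float(rng.uniform(*params.embryo_radius_range))
    jitter = params.center_jitter
    cr = h / 2.0 + float(rng.uniform(-jitter, jitter))
    cc = w / 2.0 + float(rng.uniform(-jitter, jitter))

    level = float(np.clip(params.grade + rng.normal(0.0, 0.3), 0.6, 3.4))

    # background: mean grey with a random-direction linear gradient
    theta = rng.uniform(0, 2 * np.pi)
    rows = np.arange(h, dtype=np.float64)[:, None]
    cols = np.arange(w, dtype=np.float64)[None, :]
    plane = ((rows - h / 2) * np.sin(theta) + (cols - w / 2) * np.cos(theta))
    plane /= max(np.abs(plane).max(), 1.0)
    canvas = _BACKGROUND_MEAN + params.background_gradient_amplitude * plane

    # work on a crop around the embryo for speed
    pad = int(radius + 25)
    r0, r1 = int(cr) - pad, int(cr) + pad + 1
    c0, c1 = int(cc) - pad, int(cc) + pad + 1
    r0, c0 = max(r0, 0), max(c0, 0)
    r1, c1 = min(r1, h), min(c1, w)
    yy = np.arange(r0, r1, dtype=np.float64)[:, None] - cr
    xx = np.arange(c0, c1, dtype=np.float64)[None, :] - cc
    dist = np.hypot(yy, xx)
    ang = np.arctan2(yy, xx)

    # irregular outline: low-order harmonic wobble of the boundary radius
    wob_amp = _knob(_BOUNDARY_WOBBLE, level)
    ph = rng.uniform(0, 2 * np.pi, size=3)
    wobble = (np.sin(2 * ang + ph[0]) + 0.6 * np.sin(3 * ang + ph[1])
              + 0.4 * np.sin(5 * ang + ph[2]))
    local_r = radius + wob_amp * wobble

    crop = canvas[r0:r1, c0:c1]
    inside = dist < local_r

    # blastocoel interior: lighter than background, mottled so the
    # intensity surface has several shallow drainage basins
    interior = _BLASTOCOEL_MEAN - 6.0 * (dist / radius) ** 2
    interior += _smooth_noise(rng, crop.shape, scale=24.0, sd=8.0)
    crop[inside] = interior[inside]

    # trophectoderm annulus: dark cell-profile blobs hugging the boundary
    n_blobs = max(6, int(round(_knob(_TE_BLOB_COUNT, level))))
    depth0 = _knob(_TE_BLOB_DEPTH, level)
    sigma0 = _knob(_TE_BLOB_SIGMA, level)
    blob_r = rng.uniform(0.78, 0.97, size=n_blobs) * radius
    blob_a = rng.uniform(0, 2 * np.pi, size=n_blobs)
    blob_depth = depth0 * rng.uniform(0.6, 1.2, size=n_blobs)
    blob_sigma = sigma0 * rng.uniform(0.7, 1.3, size=n_blobs)
    ch, cw = crop.shape
    for k in range(n_blobs):
        br = cr + blob_r[k] * np.sin(blob_a[k]) - r0
        bc = cc + blob_r[k] * np.cos(blob_a[k]) - c0
        s = blob_sigma[k]
        win = int(np.ceil(3 * s))
        wr0, wr1 = max(int(br) - win, 0), min(int(br) + win + 1, ch)
        wc0, wc1 = max(int(bc) - win, 0), min(int(bc) + win + 1, cw)
        if wr0 >= wr1 or wc0 >= wc1:
            continue
        gy = np.arange(wr0, wr1, dtype=np.float64)[:, None] - br
        gx = np.arange(wc0, wc1, dtype=np.float64)[None, :] - bc
        g = np.exp(-(gy ** 2 + gx ** 2) / (2 * s * s))
        sub = crop[wr0:wr1, wc0:wc1]
        sub -= blob_depth[k] * g * inside[wr0:wr1, wc0:wc1]

    # inner cell mass: one dark eccentric ellipse with a soft edge
    icm_r = _knob(_ICM_RADIUS_FRAC, level) * radius
    icm_r = max(icm_r, 0.08 * radius)
    icm_level = _knob(_ICM_INTENSITY, level)
    icm_off = rng.uniform(0.35, 0.50) * radius
    icm_ang = rng.uniform(0, 2 * np.pi)
    # keep the blob strictly inside the embryo circle
    icm_off = min(icm_off, 0.92 * radius - icm_r)
    icm_cr = cr + icm_off * np.sin(icm_ang)
    icm_cc = cc + icm_off * np.cos(icm_ang)
    ratio = rng.uniform(0.65, 0.9)
    rot = rng.uniform(0, np.pi)
    uy = yy - (icm_cr - cr)
    ux = xx - (icm_cc - cc)
    ry = uy * np.cos(rot) - ux * np.sin(rot)
    rx = uy * np.sin(rot) + ux * np.cos(rot)
    icm_d = np.sqrt((ry / icm_r) ** 2 + (rx / (icm_r * ratio)) ** 2)
    icm_in = icm_d < 1.0
    soft = np.clip((1.08 - icm_d) / 0.16, 0.0, 1.0)  # smooth 3-4 px rim
    crop += soft * (icm_level - crop) * inside
    crop += icm_in * _smooth_noise(rng, crop.shape, scale=10.0, sd=4.0)

    # bright zona pellucida shell just inside the boundary, so the planted
    # radius marks the embryo's outer extent
    crop += _ZONA_GAIN * np.exp(-((dist - (local_r - _ZONA_SIGMA)) / _ZONA_SIGMA) ** 2)

    canvas += rng.normal(0.0, params.noise_sd, size=canvas.shape)
    raster = np.clip(np.floor(canvas + 0.5), 0, 255).astype(np.uint8)

    icm_mask = np.zeros((h, w), dtype=bool)
    icm_mask[r0:r1, c0:c1] = icm_in & inside
    lab, _ = ndimage.label(icm_mask)
    if lab.max() > 1:  # keep the largest component (wobble could clip)
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, np.arange(1, lab.max() + 1))
        icm_mask = lab == (1 + int(np.argmax(sizes)))
    cy, cx = ndimage.center_of_mass(icm_mask)

    truth = SynthTruth(grade=params.grade, center=(cr, cc), radius=radius,
                       icm_mask=icm_mask, icm_centroid=(float(cy), float(cx)))
    return raster, truth


def generate_dataset(n_per_grade: int, seed: int, out_dir: str | Path,
                     image_format: str = "png", **param_overrides):
    """Write ``3 * n_per_grade`` images, their ICM masks and a CSV manifest.

    Grades cycle 1,2,3 so any prefix of the manifest is balanced.  Returns
    the manifest as a list of dict rows (also written to ``manifest.csv``
    with header ``file,grade,center_row,center_col,radius``).
    """
    if n_per_grade < 1:
        raise ConfigurationError("n_per_grade must be >= 1")
    if image_format not in ("png", "jpeg", "jpg"):
        raise ConfigurationError(f"unsupported image format: {image_format}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = "png" if image_format == "png" else "jpg"

    rows = []
    for k in range(3 * n_per_grade):
        grade = 1 + k % 3
        params = SynthParams(seed=seed + k, grade=grade, **param_overrides)
        raster, truth = generate_image(params)
        name = f"embryo_{k:04d}_g{grade}.{ext}"
        iio.imwrite(out_dir / name, raster)
        iio.imwrite(out_dir / f"embryo_{k:04d}_g{grade}_icm.png",
                    truth.icm_mask.astype(np.uint8) * 255)
        rows.append({
            "file": name,
            "grade": grade,
            "center_row": f"{truth.center[0]:.2f}",
            "center_col": f"{truth.center[1]:.2f}",
            "radius": f"{truth.radius:.2f}",
        })

    with open(out_dir / "manifest.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["file", "grade", "center_row",
                                                "center_col", "radius"])
        writer.writeheader()
        writer.writerows(rows)
    return rows
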