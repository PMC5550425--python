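"""Shared fixtures.

The expensive fixtures are session-scoped and computed once:

* ``study300`` — a 300-image synthetic study (100 per grade, seeds 0-299)
  pushed through the full pipeline (standardize, segment, watershed,
  36-variable extraction), keeping per-image detection/ICM recovery metrics
  alongside the feature table.
* ``ga_run300`` — a desk-scale genetic architecture search (population 20,
  30 generations) on the 24 surviving variables of that study.
"""

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from blastograde import features as feat_mod
from blastograde import gasearch, icm, neuralnet, segmentation, synthgen
from blastograde.standardize import standardize

settings.register_profile(
    "suite", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("suite")

N_STUDY = 300          # 100 images per grade
STUDY_SEED0 = 0        # images use seeds 0..299
SPLIT_SEED = 7


@pytest.fixture(scope="session")
def one_image():
    """A single canonical grade-1 micrograph with its planted truth."""
    raster, truth = synthgen.generate_image(synthgen.SynthParams(seed=1, grade=1))
    return SimpleNamespace(raster=raster, truth=truth,
                           std=standardize(raster))


@pytest.fixture(scope="session")
def small_frame_kwargs():
    """Generator overrides for quick small-frame images in unit tests."""
    return dict(width=420, height=420, embryo_radius_range=(110.0, 140.0),
                center_jitter=15.0)


@pytest.fixture(scope="session")
def study300():
    """Full-pipeline synthetic study: features plus recovery metrics."""
    rows, meta = [], []
    for k in range(N_STUDY):
        grade = 1 + k % 3
        raster, truth = synthgen.generate_image(
            synthgen.SynthParams(seed=STUDY_SEED0 + k, grade=grade))
        std = standardize(raster)
        geom = segmentation.segment(std)
        ws = icm.watershed_embryo(std, geom)
        vec = feat_mod.extract_all(std, geom, ws)
        inter = int((ws.icm_mask & truth.icm_mask).sum())
        dice = 2.0 * inter / (int(ws.icm_mask.sum()) + int(truth.icm_mask.sum()))
        rows.append({"grade": grade, **vec.to_dict()})
        meta.append({
            "grade": grade,
            "radius_err_frac": abs(geom.radius - truth.radius) / truth.radius,
            "center_err": float(np.hypot(geom.center[0] - truth.center[0],
                                         geom.center[1] - truth.center[1])),
            "dice": dice,
            "planted_icm_area": int(truth.icm_mask.sum()),
        })
    table = pd.DataFrame(rows, columns=["grade", *feat_mod.FEATURE_NAMES])
    return SimpleNamespace(features=table, meta=pd.DataFrame(meta))


@pytest.fixture(scope="session")
def split300(study300):
    return neuralnet.split(len(study300.features), SPLIT_SEED)


@pytest.fixture(scope="session")
def ga_run300(study300, split300):
    """Desk-scale architecture search on the synthetic study."""
    x = study300.features[list(feat_mod.SURVIVING_24)]
    y = study300.features["grade"].to_numpy(dtype=int)
    cfg = gasearch.GAConfig(population_size=20, generations=30,
                            seed=SPLIT_SEED, fitness_max_epochs=60)
    return gasearch.evolve(cfg, x, y, split300)


@pytest.fixture(scope="session")
def toy_separable():
    """Linearly separable 2-cluster dataset: 24 variables, 60 samples."""
    rng = np.random.default_rng(11)
    n_half = 30
    centre = rng.normal(0.0, 1.0, size=24)
    x = np.vstack([rng.normal(-1.0, 0.35, size=(n_half, 24)) + centre,
                   rng.normal(+1.0, 0.35, size=(n_half, 24)) + centre])
    y = np.array([1] * n_half + [2] * n_half)
    perm = rng.permutation(2 * n_half)
    return SimpleNamespace(x=x[perm], y=y[perm],
                           split=neuralnet.split(2 * n_half, seed=3))
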