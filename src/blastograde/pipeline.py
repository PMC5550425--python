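"""End-to-end reproducible pipeline: synth -> extract -> vif -> evolve -> evaluate.

Driven by a flat TOML config (all keys optional except ``seed``)::

    seed = 1
    out_dir = "run"
    n_per_grade = 100
    population = 20
    generations = 30
    fitness_max_epochs = 60
    fitness_partition = "test"   # or "validation"
    refit_vif = false            # true: recompute survivors on this data

By default networks are trained on the fixed 24-variable schema that the
collinearity analysis of the original dataset retained (so models are
portable); ``refit_vif`` switches to the survivors recomputed on the data
at hand.  Every artifact is written under ``out_dir`` and hashed into
``report.json`` so a rerun with the same config is byte-comparable.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from . import collinearity, evaluation, features as feat_mod, gasearch, neuralnet, synthgen
from .errors import ConfigurationError

_DEFAULTS = {
    "n_per_grade": 100,
    "population": 20,
    "generations": 30,
    "fitness_max_epochs": 60,
    "fitness_partition": "test",
    "refit_vif": False,
    "out_dir": "blastograde_run",
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path: str | Path) -> dict:
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    if "seed" not in cfg:
        raise ConfigurationError("config must define an integer 'seed'")
    out = dict(_DEFAULTS)
    out.update(cfg)
    return out


def run_pipeline(config: str | Path | dict) -> dict:
    """Run every stage; returns the report dict (also written to report.json)."""
    cfg = load_config(config) if not isinstance(config, dict) else {**_DEFAULTS, **config}
    if "seed" not in cfg or cfg["seed"] is None:
        raise ConfigurationError("config must define an integer 'seed'")
    seed = int(cfg["seed"])
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    stage = "synth"
    try:
        img_dir = out_dir / "images"
        synthgen.generate_dataset(int(cfg["n_per_grade"]), seed, img_dir)

        stage = "extract"
        table = feat_mod.extract_directory(img_dir, manifest=img_dir / "manifest.csv",
                                           out_csv=out_dir / "features.csv")

        stage = "vif"
        variables = list(feat_mod.SURVIVING_24)
        if len(table) > len(feat_mod.FEATURE_NAMES) + 1:
            report_vif = collinearity.eliminate(table[list(feat_mod.FEATURE_NAMES)])
            report_vif.to_json(out_dir / "vif_report.json")
            if cfg["refit_vif"]:
                variables = report_vif.surviving
        else:  # too few rows for the regression design; keep the fixed schema
            with open(out_dir / "vif_report.json", "w") as fh:
                json.dump({"skipped": "rows <= variables"}, fh)

        stage = "evolve"
        grades = table["grade"].to_numpy(dtype=int)
        x = table[variables]
        data_split = neuralnet.split(len(grades), seed)
        ga_cfg = gasearch.GAConfig(
            population_size=int(cfg["population"]),
            generations=int(cfg["generations"]),
            fitness_partition=str(cfg["fitness_partition"]),
            seed=seed, fitness_max_epochs=int(cfg["fitness_max_epochs"]))
        run = gasearch.evolve(ga_cfg, x, grades, data_split)
        gen_rows = [{"generation": r.generation, "best_fitness": r.best_fitness,
                     "mean_fitness": r.mean_fitness} for r in run.history]
        pd.DataFrame(gen_rows).to_csv(out_dir / "generations.csv", index=False)
        model_paths = []
        for rank, model in enumerate(run.top_models, 1):
            p = out_dir / f"model_{rank}.json"
            model.save(p)
            model_paths.append(p)

        stage = "evaluate"
        test_idx = np.asarray(data_split.test, dtype=int)
        ref = grades[test_idx]
        x_test = x.iloc[test_idx]
        eval_block: dict = {"models": []}
        model_grades = []
        for model in run.top_models:
            scores, pred = model.predict(x_test)
            cm = evaluation.confusion(ref, pred)
            rocs = evaluation.roc_one_vs_rest(scores, ref)
            eval_block["models"].append({
                "total_success_pct": cm.total_success,
                "per_class_success_pct": cm.per_class_success,
                "serious_error_pct": cm.serious_error_pct,
                "auc": {g: (r.auc if r.defined else None) for g, r in rocs.items()},
            })
            model_grades.append(pred)
        if len(model_grades) == 3:
            consensus = _majority(np.stack(model_grades), np.stack(
                [m.predict(x_test)[0] for m in run.top_models]))
            cm = evaluation.confusion(ref, consensus)
            eval_block["ensemble_total_success_pct"] = cm.total_success
            ratings = np.stack(model_grades, axis=1)
            eval_block["inter_model_kappa"] = evaluation.kappa_fleiss(ratings).kappa
    except Exception as exc:
        partial = {"failed_stage": stage, "error": str(exc)}
        with open(out_dir / "partial_manifest.json", "w") as fh:
            json.dump(partial, fh, indent=2)
        raise

    report = {
        "config": {k: cfg[k] for k in sorted(cfg)},
        "best_fitness": run.history[-1].best_fitness if run.history else None,
        "top_genomes": [g.to_dict() for g in run.top_genomes],
        "top_fitness": run.top_fitness,
        "evaluation": eval_block,
        "artifacts": {},
    }
    for p in sorted([out_dir / "features.csv", out_dir / "vif_report.json",
                     out_dir / "generations.csv", *model_paths]):
        report["artifacts"][p.name] = _sha256(p)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    return report


def _majority(model_grades: np.ndarray, model_scores: np.ndarray) -> np.ndarray:
    """Per-sample majority of three model grades; all-different falls back to
    the model with the largest top-score margin."""
    n = model_grades.shape[1]
    out = np.empty(n, dtype=int)
    for k in range(n):
        votes = model_grades[:, k]
        vals, counts = np.unique(votes, return_counts=True)
        if counts.max() >= 2:
            out[k] = int(vals[np.argmax(counts)])
        else:
            margins = []
            for m in range(3):
                s = np.sort(model_scores[m, k])[::-1]
                margins.append(s[0] - s[1])
            out[k] = int(votes[int(np.argmax(margins))])
    return out
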