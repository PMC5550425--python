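"""Iterative variance-inflation-factor pruning of redundant feature variables.

The VIF of variable i is ``1 / (1 - R_i^2)`` where ``R_i^2`` is the
coefficient of determination of an OLS regression (with intercept) of i on
all other variables.  Variables with VIF above 10 are considered collinear;
elimination removes the single worst offender per iteration (ties break to
earlier canonical order) until every survivor's VIF is at or below the
threshold.  Features are z-scored before regression for numerical
stability — VIF is invariant to affine rescaling, so this changes nothing
mathematically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateEliminationError, UnderdeterminedDesignError

VIF_THRESHOLD = 10.0

_EXACT_COLLINEARITY_TOL = 1e-12


@dataclass
class EliminationStep:
    removed_variable: str
    vif: float
    all_vifs: dict[str, float]


@dataclass
class CollinearityReport:
    iterations: list[EliminationStep] = field(default_factory=list)
    surviving: list[str] = field(default_factory=list)
    final_vifs: dict[str, float] = field(default_factory=dict)
    threshold: float = VIF_THRESHOLD

    @property
    def removed(self) -> list[str]:
        return [step.removed_variable for step in self.iterations]

    @property
    def n_iterations(self) -> int:
        """Removal steps plus the terminal all-clear check."""
        return len(self.iterations) + 1

    def to_json(self, path=None) -> str:
        payload = {
            "threshold": self.threshold,
            "iterations": [
                {"removed_variable": s.removed_variable, "vif": s.vif,
                 "all_vifs": s.all_vifs}
                for s in self.iterations
            ],
            "surviving": self.surviving,
            "final_vifs": self.final_vifs,
        }
        text = json.dumps(payload, indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (x - x.mean(axis=0)) / sd


def _all_vifs(x: np.ndarray) -> np.ndarray:
    """VIF of every column of a z-scored design matrix."""
    n, p = x.shape
    ones = np.ones((n, 1))
    vifs = np.empty(p)
    for i in range(p):
        others = np.hstack([ones, np.delete(x, i, axis=1)])
        target = x[:, i]
        coef, _, _, _ = np.linalg.lstsq(others, target, rcond=None)
        resid = target - others @ coef
        sst = float(((target - target.mean()) ** 2).sum())
        if sst <= 0:  # constant column: no variance to inflate
            vifs[i] = 1.0
            continue
        r2 = 1.0 - float((resid ** 2).sum()) / sst
        vifs[i] = np.inf if r2 >= 1.0 - _EXACT_COLLINEARITY_TOL else 1.0 / (1.0 - r2)
    return vifs


def vif(feature_table: pd.DataFrame, variable: str) -> float:
    """Variance inflation factor of ``variable`` against the other columns."""
    cols = list(feature_table.columns)
    if variable not in cols:
        raise KeyError(variable)
    x = feature_table.to_numpy(dtype=float)
    n, p = x.shape
    if p < 2:
        raise UnderdeterminedDesignError("need at least 2 variables")
    if n <= p:
        raise UnderdeterminedDesignError(f"rows ({n}) must exceed variables ({p})")
    return float(_all_vifs(_zscore(x))[cols.index(variable)])


def eliminate(feature_table: pd.DataFrame,
              threshold: float = VIF_THRESHOLD) -> CollinearityReport:
    """Remove the worst-VIF variable per iteration until all VIFs <= threshold."""
    table = feature_table.copy()
    if table.shape[1] < 2:
        raise DegenerateEliminationError("need at least 2 variables to analyse")
    if table.shape[0] <= table.shape[1]:
        raise UnderdeterminedDesignError(
            f"rows ({table.shape[0]}) must exceed variables ({table.shape[1]})")
    report = CollinearityReport(threshold=threshold)
    while True:
        cols = list(table.columns)
        vifs = _all_vifs(_zscore(table.to_numpy(dtype=float)))
        worst = int(np.argmax(vifs))  # argmax: first (earlier canonical) max wins ties
        if vifs[worst] <= threshold:
            report.surviving = cols
            report.final_vifs = dict(zip(cols, map(float, vifs)))
            return report
        if table.shape[1] <= 2:
            raise DegenerateEliminationError(
                "elimination would leave fewer than 2 variables")
        report.iterations.append(EliminationStep(
            removed_variable=cols[worst], vif=float(vifs[worst]),
            all_vifs=dict(zip(cols, map(float, vifs)))))
        table = table.drop(columns=[cols[worst]])
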