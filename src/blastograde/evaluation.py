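"""Rater aggregation and the grading metric battery.

Covers everything needed to judge a grading system against the
embryologists' consensus: the mode-of-three-raters reference grade, the
3x3 confusion matrix with total / per-class success and the serious-error
rate (prediction off by two grades), one-vs-rest ROC curves with
trapezoidal AUC, and chance-corrected agreement — Fleiss' kappa for three
(or more) raters, Cohen's kappa for rater pairs — each with a large-sample
z-test against zero agreement.

Percentages are rounded to one decimal for display only; internal values
stay exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats
from sklearn.metrics import cohen_kappa_score, roc_curve, auc as _trapezoid_auc
from statsmodels.stats.inter_rater import aggregate_raters, fleiss_kappa

from .errors import BlastogradeError

GRADES = (1, 2, 3)


def mode_grade(grades) -> int:
    """Consensus of three rater grades: the majority, or the median (2)
    when all three differ."""
    g = [int(v) for v in grades]
    if len(g) != 3 or any(v not in GRADES for v in g):
        raise BlastogradeError(f"expected three grades in {{1,2,3}}, got {grades}")
    counts = {v: g.count(v) for v in set(g)}
    best = max(counts, key=counts.get)
    if counts[best] >= 2:
        return best
    return int(np.median(g))  # (1,2,3) -> 2, the only order-symmetric choice


@dataclass
class ConfusionMatrix:
    """3x3 counts: rows = reference grade, columns = predicted grade."""

    counts: np.ndarray = field(repr=False)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def total_success(self) -> float:
        """Overall accuracy, percent."""
        return 100.0 * float(np.trace(self.counts)) / self.n

    @property
    def per_class_success(self) -> dict[int, float]:
        """Accuracy per reference grade, percent (NaN for an absent class)."""
        out = {}
        for i, grade in enumerate(GRADES):
            row = self.counts[i].sum()
            out[grade] = 100.0 * self.counts[i, i] / row if row else float("nan")
        return out

    @property
    def serious_error_pct(self) -> float:
        """Percent of predictions off by two grades (1<->3 confusions)."""
        serious = self.counts[0, 2] + self.counts[2, 0]
        return 100.0 * float(serious) / self.n

    def summary(self) -> str:
        lines = ["Confusion matrix (rows: reference, cols: predicted)"]
        header = "        " + "".join(f"  pred {g}" for g in GRADES)
        lines.append(header)
        for i, g in enumerate(GRADES):
            lines.append(f"  ref {g} " + "".join(f"{int(c):8d}" for c in self.counts[i]))
        lines.append(f"total success: {self.total_success:.1f}%")
        for g, v in self.per_class_success.items():
            lines.append(f"success grade {g}: {v:.1f}%")
        lines.append(f"serious errors (|ref-pred| >= 2): {self.serious_error_pct:.1f}%")
        return "\n".join(lines)


def confusion(reference, predicted) -> ConfusionMatrix:
    """Cross-tabulate reference vs predicted grades."""
    ref = np.asarray(reference, dtype=int)
    pred = np.asarray(predicted, dtype=int)
    if ref.shape != pred.shape:
        raise BlastogradeError("reference and predicted lengths differ")
    if not (np.isin(ref, GRADES).all() and np.isin(pred, GRADES).all()):
        raise BlastogradeError("grades must be in {1, 2, 3}")
    counts = np.zeros((3, 3), dtype=np.int64)
    np.add.at(counts, (ref - 1, pred - 1), 1)
    return ConfusionMatrix(counts=counts)


@dataclass
class ROCCurve:
    grade: int
    fpr: np.ndarray = field(repr=False, default=None)
    tpr: np.ndarray = field(repr=False, default=None)
    thresholds: np.ndarray = field(repr=False, default=None)
    auc: float = float("nan")
    defined: bool = True


def roc_one_vs_rest(scores, reference) -> dict[int, ROCCurve]:
    """Per-grade one-vs-rest ROC from the 3-column network scores.

    A grade absent from (or filling all of) the reference has no
    positive/negative contrast; its curve is flagged undefined.
    """
    s = np.asarray(scores, dtype=float)
    ref = np.asarray(reference, dtype=int)
    if s.ndim != 2 or s.shape[1] != 3 or s.shape[0] != ref.shape[0]:
        raise BlastogradeError("scores must be (n, 3) aligned with reference")
    if not np.isfinite(s).all():
        raise BlastogradeError("scores must be finite")
    out: dict[int, ROCCurve] = {}
    for i, grade in enumerate(GRADES):
        positive = ref == grade
        if positive.all() or not positive.any():
            out[grade] = ROCCurve(grade=grade, defined=False)
            continue
        fpr, tpr, thr = roc_curve(positive.astype(int), s[:, i])
        out[grade] = ROCCurve(grade=grade, fpr=fpr, tpr=tpr, thresholds=thr,
                              auc=float(_trapezoid_auc(fpr, tpr)))
    return out


@dataclass
class AgreementReport:
    kappa: float
    kind: str                      # "fleiss_multi_rater" or "cohen_pairwise"
    n_items: int
    n_raters: int
    n_categories: int = 3
    p_value: float = float("nan")  # large-sample z test against kappa = 0

    def summary(self) -> str:
        return (f"{self.kind}: kappa={self.kappa:.3f} "
                f"(n={self.n_items}, raters={self.n_raters}, "
                f"p={self.p_value:.3g})")


def kappa_fleiss(ratings) -> AgreementReport:
    """Fleiss' multi-rater kappa over the 3 grade categories.

    ``ratings`` is (n_items, n_raters).  The z-test uses the Fleiss (1971)
    large-sample null variance.  When every rating is the same single
    category, expected agreement is 1 and kappa is reported as 1 with a
    warning.
    """
    r = np.asarray(ratings, dtype=int)
    if r.ndim != 2 or r.shape[1] < 2:
        raise BlastogradeError("ratings must be (n_items, n_raters>=2)")
    if not np.isin(r, GRADES).all():
        raise BlastogradeError("ratings must be in {1, 2, 3}")
    n_items, n_raters = r.shape
    table, _ = aggregate_raters(r, n_cat=None)
    # pad to the 3 grade categories if some grade never occurs
    if table.shape[1] < 3:
        full = np.zeros((n_items, 3), dtype=table.dtype)
        used = sorted(np.unique(r))
        for k, cat in enumerate(used):
            full[:, cat - 1] = table[:, k]
        table = full
    p_j = table.sum(axis=0) / (n_items * n_raters)
    if np.max(p_j) >= 1.0:
        warnings.warn("all ratings identical: expected agreement is 1, "
                      "kappa reported as 1")
        return AgreementReport(kappa=1.0, kind="fleiss_multi_rater",
                               n_items=n_items, n_raters=n_raters, p_value=0.0)
    kappa = float(fleiss_kappa(table, method="fleiss"))
    q_j = 1.0 - p_j
    spq = float(np.sum(p_j * q_j))
    var0 = (2.0 / (n_items * n_raters * (n_raters - 1))) * \
        (spq ** 2 - float(np.sum(p_j * q_j * (q_j - p_j)))) / (spq ** 2)
    z = kappa / np.sqrt(var0)
    p = 2.0 * sstats.norm.sf(abs(z))
    return AgreementReport(kappa=kappa, kind="fleiss_multi_rater",
                           n_items=n_items, n_raters=n_raters, p_value=float(p))


def kappa_cohen(r1, r2) -> AgreementReport:
    """Cohen's unweighted kappa between two raters over the 3 grades."""
    a = np.asarray(r1, dtype=int)
    b = np.asarray(r2, dtype=int)
    if a.shape != b.shape:
        raise BlastogradeError("rating vectors must have equal length")
    if not (np.isin(a, GRADES).all() and np.isin(b, GRADES).all()):
        raise BlastogradeError("ratings must be in {1, 2, 3}")
    n = a.size
    if np.array_equal(a, b):
        kappa = 1.0
    else:
        kappa = float(cohen_kappa_score(a, b, labels=list(GRADES)))
    # large-sample null variance (Fleiss, Levin & Paik)
    pi = np.array([np.mean(a == g) for g in GRADES])
    pj = np.array([np.mean(b == g) for g in GRADES])
    pe = float(np.sum(pi * pj))
    if pe >= 1.0:
        p = 0.0 if kappa == 1.0 else float("nan")
    else:
        var0 = (pe + pe ** 2 - float(np.sum(pi * pj * (pi + pj)))) / \
            (n * (1.0 - pe) ** 2)
        z = kappa / np.sqrt(var0) if var0 > 0 else np.inf
        p = float(2.0 * sstats.norm.sf(abs(z)))
    return AgreementReport(kappa=kappa, kind="cohen_pairwise",
                           n_items=int(n), n_raters=2, p_value=p)
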