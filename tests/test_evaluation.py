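"""Metric battery: mode grade, confusion matrix, ROC/AUC, kappa statistics."""

import numpy as np
import pytest

from blastograde import evaluation as ev
from blastograde.errors import BlastogradeError


# ---------------------------------------------------------------------------
# independent textbook oracles

def fleiss_kappa_oracle(ratings):
    """Direct evaluation of the multi-rater kappa definition."""
    r = np.asarray(ratings, int)
    n, m = r.shape
    table = np.stack([(r == g).sum(axis=1) for g in (1, 2, 3)], axis=1)
    p_j = table.sum(axis=0) / (n * m)
    p_i = ((table ** 2).sum(axis=1) - m) / (m * (m - 1))
    p_bar = p_i.mean()
    p_e = (p_j ** 2).sum()
    return (p_bar - p_e) / (1 - p_e)


def cohen_kappa_oracle(a, b):
    a, b = np.asarray(a, int), np.asarray(b, int)
    po = np.mean(a == b)
    pe = sum(np.mean(a == g) * np.mean(b == g) for g in (1, 2, 3))
    return (po - pe) / (1 - pe)


def auc_pairwise_oracle(scores, labels):
    """P(score_pos > score_neg) + 0.5 P(equal) over all pos/neg pairs."""
    pos = scores[labels]
    neg = scores[~labels]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


# ---------------------------------------------------------------------------

@pytest.mark.parametrize("grades,expected", [
    ((1, 1, 2), 1), ((3, 3, 3), 3), ((1, 2, 3), 2), ((2, 3, 2), 2),
    ((3, 1, 3), 3),
])
def test_mode_grade(grades, expected):
    assert ev.mode_grade(grades) == expected


def test_mode_grade_rejects_bad_input():
    with pytest.raises(BlastogradeError):
        ev.mode_grade((1, 2))
    with pytest.raises(BlastogradeError):
        ev.mode_grade((0, 1, 2))


def test_confusion_hand_example():
    cm = ev.confusion([1, 1, 2, 3], [1, 2, 2, 3])
    assert cm.total_success == pytest.approx(75.0)
    assert cm.serious_error_pct == 0.0
    assert cm.counts[0, 0] == 1 and cm.counts[0, 1] == 1
    assert "75.0%" in cm.summary()


def test_confusion_dataset_scale_arithmetic():
    """55 of 72 correct -> 76.4% total; 4 two-grade errors -> 5.6%."""
    ref = np.array([1] * 24 + [2] * 24 + [3] * 24)
    # 17 errors of which 4 are |ref-pred| == 2
    pred = ref.copy()
    pred[0:2] = 3                 # grade1 -> grade3: serious
    pred[24:26] = 1               # grade2 -> 1: ordinary
    pred[26:37] = 3               # grade2 -> 3: ordinary (11)
    pred[48:50] = 1               # grade3 -> 1: serious
    cm = ev.confusion(ref, pred)
    assert cm.n == 72
    assert np.trace(cm.counts) == 55
    assert round(cm.total_success, 1) == 76.4
    assert round(cm.serious_error_pct, 1) == 5.6


def test_per_class_successes_recombine_to_total():
    rng = np.random.default_rng(0)
    ref = rng.integers(1, 4, 200)
    pred = rng.integers(1, 4, 200)
    cm = ev.confusion(ref, pred)
    weights = cm.counts.sum(axis=1) / cm.n
    per_class = np.array([cm.per_class_success[g] for g in (1, 2, 3)])
    assert np.nansum(weights * per_class) == pytest.approx(cm.total_success)
    with pytest.raises(BlastogradeError):
        ev.confusion(ref[:-1], pred)


def test_roc_perfect_separation_and_absent_class():
    ref = np.array([1, 1, 2, 2, 3, 3])
    scores = np.eye(3)[ref - 1] * 5.0
    curves = ev.roc_one_vs_rest(scores, ref)
    for g in (1, 2, 3):
        assert curves[g].auc == pytest.approx(1.0)
    curves = ev.roc_one_vs_rest(scores[:4], ref[:4])
    assert not curves[3].defined


def test_auc_matches_pairwise_oracle_and_is_rank_invariant():
    rng = np.random.default_rng(1)
    ref = rng.integers(1, 4, 20)
    scores = rng.normal(size=(20, 3))
    curves = ev.roc_one_vs_rest(scores, ref)
    for i, g in enumerate((1, 2, 3)):
        expected = auc_pairwise_oracle(scores[:, i], ref == g)
        assert curves[g].auc == pytest.approx(expected, abs=1e-12)
    transformed = np.exp(scores)  # strictly monotone transform
    curves2 = ev.roc_one_vs_rest(transformed, ref)
    for g in (1, 2, 3):
        assert curves2[g].auc == pytest.approx(curves[g].auc, abs=1e-12)


def test_fleiss_kappa_perfect_agreement_is_one():
    rng = np.random.default_rng(2)
    col = rng.integers(1, 4, 50)
    ratings = np.stack([col] * 3, axis=1)
    report = ev.kappa_fleiss(ratings)
    assert report.kappa == pytest.approx(1.0)
    assert report.n_items == 50 and report.n_raters == 3


def test_fleiss_kappa_matches_textbook_oracle():
    rng = np.random.default_rng(3)
    for _ in range(5):
        ratings = rng.integers(1, 4, size=(40, 4))
        report = ev.kappa_fleiss(ratings)
        assert report.kappa == pytest.approx(fleiss_kappa_oracle(ratings),
                                             abs=1e-10)
        assert 0.0 <= report.p_value <= 1.0


def test_fleiss_kappa_single_category_warns_and_returns_one():
    ratings = np.full((20, 3), 2)
    with pytest.warns(UserWarning):
        report = ev.kappa_fleiss(ratings)
    assert report.kappa == 1.0


def test_cohen_kappa_cases_and_oracle():
    assert ev.kappa_cohen([1, 2, 3, 1], [1, 2, 3, 1]).kappa == 1.0
    # observed agreement 0.5 equals expected agreement -> kappa 0
    assert ev.kappa_cohen([1, 1, 2, 2], [1, 2, 1, 2]).kappa == pytest.approx(0.0)
    rng = np.random.default_rng(4)
    for _ in range(5):
        a = rng.integers(1, 4, 80)
        b = rng.integers(1, 4, 80)
        assert ev.kappa_cohen(a, b).kappa == pytest.approx(
            cohen_kappa_oracle(a, b), abs=1e-10)


def test_cohen_kappa_null_is_near_zero():
    for seed in range(5):
        rng = np.random.default_rng(seed)
        a = rng.integers(1, 4, 500)
        b = rng.permutation(a)
        report = ev.kappa_cohen(a, b)
        assert abs(report.kappa) < 0.05
        assert report.p_value > 0.01  # no spurious significance
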