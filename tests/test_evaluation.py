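"""ROC/AUC oracles, confusion metrics, cross-validation and DeLong comparison."""

import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from plspair import (
    compare_roc,
    confusion_metrics,
    cross_validate,
    mann_whitney_auc,
    roc_auc,
)
from plspair.io import NONRESPONDER, RESPONDER


def all_pairs_auc(scores, y):
    """Brute-force average over every responder/nonresponder pair."""
    pos = scores[y > 0]
    neg = scores[y < 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def scores_25v15(seed, ties=False):
    rng = np.random.default_rng(seed)
    y = np.repeat([1.0, -1.0], [25, 15])
    s = rng.normal(loc=(y > 0) * 1.0)
    if ties:
        s = np.round(s, 1)
    return s, y


def test_perfect_separation_gives_auc_one():
    y = np.repeat([1.0, -1.0], [3, 2])
    res = roc_auc(np.array([3.0, 2.0, 1.0, 0.0, -1.0]), y)
    assert res.auc == 1.0
    assert res.ci95 == (1.0, 1.0)


@pytest.mark.parametrize("seed,ties", [(0, False), (1, False), (2, True), (3, True)])
def test_auc_matches_all_pairs_oracle_and_sklearn(seed, ties):
    s, y = scores_25v15(seed, ties)
    res = roc_auc(s, y)
    assert res.auc == pytest.approx(all_pairs_auc(s, y), abs=1e-12)
    assert res.auc == pytest.approx(roc_auc_score(y > 0, s), abs=1e-12)
    assert res.ci95[0] <= res.auc <= res.ci95[1]
    assert np.all(np.diff(res.fpr) >= 0) and np.all(np.diff(res.tpr) >= 0)


def test_trapezoid_equals_mann_whitney_when_tie_free():
    for seed in range(5):
        s, y = scores_25v15(seed)
        res = roc_auc(s, y)
        trapezoid = np.trapezoid(res.tpr, res.fpr)
        assert trapezoid == pytest.approx(res.auc, abs=1e-12)


def test_auc_invariant_under_monotone_transform():
    s, y = scores_25v15(4)
    assert mann_whitney_auc(np.exp(s), y) == pytest.approx(
        mann_whitney_auc(s, y), abs=1e-12
    )


def test_auc_requires_both_classes():
    with pytest.raises(ValueError, match="both classes"):
        mann_whitney_auc(np.arange(5.0), np.ones(5))


def test_confusion_metrics_hand_ratios():
    assert confusion_metrics(25, 15, 0, 0) == (1.0, 1.0, 1.0)
    sens, spec, acc = confusion_metrics(3, 2, 2, 1)
    assert (sens, spec, acc) == (0.75, 0.5, 0.625)
    assert confusion_metrics(30, 20, 20, 10) == (0.75, 0.5, 0.625)  # scaled x10
    with pytest.raises(ValueError, match="sensitivity"):
        confusion_metrics(0, 5, 5, 0)
    with pytest.raises(ValueError, match="specificity"):
        confusion_metrics(5, 0, 0, 5)
    with pytest.raises(ValueError, match="non-negative"):
        confusion_metrics(-1, 1, 1, 1)


def _cohort_frame(n_pos, n_neg, d=2.0, seed=0):
    rng = np.random.default_rng(seed)
    y = np.repeat([1.0, -1.0], [n_pos, n_neg])
    X = pd.DataFrame(
        {
            "a": d / 2 * y + rng.normal(size=y.size),
            "b": -d / 2 * y + rng.normal(size=y.size),
        }
    )
    return X, y


def test_cv_fold_shape_at_six_vs_six():
    X, y = _cohort_frame(6, 6, d=3.0)
    report = cross_validate(X, y, k=5, seed=17)
    sizes = sorted(report.fold_metrics["n_test"])
    assert sizes == [2, 2, 2, 3, 3]
    # every sample held out exactly once
    assert np.all(report.fold_assignments >= 0)
    assert report.fold_metrics["n_test"].sum() == 12


def test_cv_deterministic_under_fixed_seed():
    X, y = _cohort_frame(10, 10)
    a = cross_validate(X, y, k=5, seed=3)
    b = cross_validate(X, y, k=5, seed=3)
    pd.testing.assert_frame_equal(a.fold_metrics, b.fold_metrics)
    assert np.array_equal(a.fold_assignments, b.fold_assignments)
    c = cross_validate(X, y, k=5, seed=4)
    assert not np.array_equal(a.fold_assignments, c.fold_assignments)


def test_cv_perfectly_separable_data_scores_one():
    X, y = _cohort_frame(10, 10, d=12.0, seed=1)
    report = cross_validate(X, y, k=5, seed=0)
    assert report.mean_accuracy == 1.0
    assert report.pooled_accuracy == 1.0
    assert report.mean_auc == 1.0


def test_cv_pooled_accuracy_follows_count_formula():
    X, y = _cohort_frame(12, 8, d=1.0, seed=2)
    report = cross_validate(X, y, k=5, seed=5)
    total = (report.fold_metrics["tp"] + report.fold_metrics["tn"]).sum()
    assert report.pooled_accuracy == pytest.approx(total / len(X))


def test_cv_degrades_gracefully_below_k_members():
    X, y = _cohort_frame(3, 9, d=3.0, seed=3)
    with pytest.warns(UserWarning, match="fewer than k"):
        report = cross_validate(X, y, k=5, seed=0)
    assert len(report.fold_metrics) == 5
    with pytest.raises(ValueError, match="at least 2"):
        cross_validate(X, y, k=1)


def test_compare_roc_identity_and_rank_invariance():
    s, y = scores_25v15(5)
    auc_a, auc_b, p = compare_roc(s, s, y)
    assert auc_a == auc_b and p == 1.0
    auc_a, auc_b, p = compare_roc(s, np.exp(s), y)
    assert auc_a == pytest.approx(auc_b, abs=1e-12)
    assert p == 1.0


def permutation_auc_diff_p(scores_a, scores_b, y, n_perm=10_000, seed=0):
    """Permutation test of the AUC difference by label reshuffling."""
    rng = np.random.default_rng(seed)
    observed = abs(mann_whitney_auc(scores_a, y) - mann_whitney_auc(scores_b, y))
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(y)
        d = abs(mann_whitney_auc(scores_a, perm) - mann_whitney_auc(scores_b, perm))
        hits += d >= observed - 1e-12
    return hits / n_perm


def test_delong_matches_permutation_oracle():
    rng = np.random.default_rng(11)
    y = np.repeat([1.0, -1.0], 20)
    base = (y > 0) * 1.2 + rng.normal(size=40)
    scores_a = base + 0.3 * rng.normal(size=40)
    scores_b = 0.6 * base + rng.normal(size=40)
    _, _, p_delong = compare_roc(scores_a, scores_b, y)
    p_perm = permutation_auc_diff_p(scores_a, scores_b, y, n_perm=4000, seed=1)
    mc_se = np.sqrt(p_perm * (1 - p_perm) / 4000)
    assert p_delong == pytest.approx(p_perm, abs=max(5 * mc_se, 0.05))


def test_delong_null_rejection_rate_calibrated():
    """Under permuted labels the 5% test rejects about 5% of the time."""
    rng = np.random.default_rng(21)
    n, reps = 40, 1000
    base = rng.normal(size=n)
    scores_a = base + 0.5 * rng.normal(size=n)
    scores_b = base + 0.5 * rng.normal(size=n)
    rejections = 0
    for _ in range(reps):
        y = rng.permutation(np.repeat([1.0, -1.0], n // 2))
        _, _, p = compare_roc(scores_a, scores_b, y)
        rejections += p < 0.05
    rate = rejections / reps
    se = np.sqrt(0.05 * 0.95 / reps)
    assert rate == pytest.approx(0.05, abs=4 * se)
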