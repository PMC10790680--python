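"""ROC/AUC machinery, confusion-matrix metrics, fivefold CV, ROC comparison.

AUC is the Mann-Whitney estimator (ties count 0.5): the probability that a
random responder scores above a random nonresponder. Its standard error
follows Hanley & McNeil and the 95% CI a logit-transformed normal
approximation clipped to [0, 1]. Paired ROC curves are compared with the
DeLong test. Cross-validation is stratified k-fold with a seeded shuffle;
each fold refits the PLS weights and threshold on the training portion and
evaluates sensitivity, specificity, accuracy and AUC on the held-out
samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve
from sklearn.model_selection import KFold, StratifiedKFold

from . import pls
from .io import NONRESPONDER, RESPONDER
from .pls import encode_labels


@dataclass(frozen=True)
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    se: float
    ci95: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "se": self.se,
            "ci95": list(self.ci95),
            "fpr": self.fpr.tolist(),
            "tpr": self.tpr.tolist(),
            "thresholds": self.thresholds.tolist(),
        }


def mann_whitney_auc(scores, labels) -> float:
    """AUC as the tie-aware Mann-Whitney probability estimate."""
    scores = np.asarray(scores, dtype=float)
    yy = encode_labels(labels)
    n_pos = int((yy > 0).sum())
    n_neg = int((yy < 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute an AUC")
    ranks = stats.rankdata(scores)
    return float(
        (ranks[yy > 0].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    )


def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley-McNeil standard error of an AUC estimate."""
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (
        auc * (1 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def _logit_ci(auc: float, se: float, level: float = 0.95) -> tuple[float, float]:
    if se == 0.0 or auc <= 0.0 or auc >= 1.0:
        return (auc, auc)
    z = stats.norm.ppf(0.5 + level / 2)
    logit = np.log(auc / (1 - auc))
    se_logit = se / (auc * (1 - auc))
    lo = 1 / (1 + np.exp(-(logit - z * se_logit)))
    hi = 1 / (1 + np.exp(-(logit + z * se_logit)))
    return (float(np.clip(lo, 0, 1)), float(np.clip(hi, 0, 1)))


def roc_auc(scores, labels) -> ROCResult:
    """ROC points plus Mann-Whitney AUC with Hanley-McNeil SE and logit CI."""
    scores = np.asarray(scores, dtype=float)
    yy = encode_labels(labels)
    n_pos = int((yy > 0).sum())
    n_neg = int((yy < 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute a ROC curve")
    fpr, tpr, thresholds = roc_curve(yy > 0, scores)
    auc = mann_whitney_auc(scores, yy)
    se = hanley_mcneil_se(auc, n_pos, n_neg)
    return ROCResult(fpr, tpr, thresholds, auc, se, _logit_ci(auc, se))


def confusion_metrics(tp: int, tn: int, fp: int, fn: int) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) from confusion counts.

    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
    accuracy = (TP+TN)/N.
    """
    counts = {"TP": tp, "TN": tn, "FP": fp, "FN": fn}
    for name, v in counts.items():
        if v < 0 or v != int(v):
            raise ValueError(f"{name} must be a non-negative integer")
    if tp + fn == 0:
        raise ValueError("sensitivity undefined: TP + FN is zero")
    if tn + fp == 0:
        raise ValueError("specificity undefined: TN + FP is zero")
    n = tp + tn + fp + fn
    return (tp / (tp + fn), tn / (tn + fp), (tp + tn) / n)


@dataclass(frozen=True)
class CVReport:
    fold_metrics: pd.DataFrame
    mean_accuracy: float
    mean_sensitivity: float
    mean_specificity: float
    mean_auc: float
    pooled_accuracy: float
    fold_assignments: np.ndarray
    seed: int

    def to_dict(self) -> dict:
        return {
            "folds": self.fold_metrics.where(
                self.fold_metrics.notna(), None
            ).to_dict(orient="records"),
            "mean_accuracy": self.mean_accuracy,
            "mean_sensitivity": self.mean_sensitivity,
            "mean_specificity": self.mean_specificity,
            "mean_auc": self.mean_auc,
            "pooled_accuracy": self.pooled_accuracy,
            "fold_assignments": self.fold_assignments.tolist(),
            "seed": self.seed,
        }


def _folds(yy: np.ndarray, k: int, seed: int):
    n_pos = int((yy > 0).sum())
    n_neg = int((yy < 0).sum())
    if min(n_pos, n_neg) >= k:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        return splitter.split(np.zeros_like(yy), yy > 0)
    warnings.warn(
        f"a class has fewer than k={k} members; falling back to unstratified folds",
        stacklevel=3,
    )
    return KFold(n_splits=k, shuffle=True, random_state=seed).split(yy)


def cross_validate(X, y, k: int = 5, seed: int = 0) -> CVReport:
    """Stratified k-fold CV of the single-component PLS classifier.

    Each fold fits weights, scaling and threshold on the training portion
    only and evaluates on the held-out samples. Folds in which a metric is
    undefined (a single-class fold for AUC, or no positives/negatives for
    sensitivity/specificity) are excluded from that metric's mean with a
    warning. ``pooled_accuracy`` is (sum TP + TN) / N over all held-out
    predictions.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.atleast_2d(np.asarray(X, dtype=float)))
        X.columns = [str(c) for c in X.columns]
    yy = encode_labels(y)
    if len(yy) != len(X):
        raise ValueError("X and y disagree on the number of samples")

    assignments = np.full(len(X), -1, dtype=int)
    rows = []
    total_correct = 0
    for fold, (train, test) in enumerate(_folds(yy, k, seed)):
        assignments[test] = fold
        model = pls.fit(X.iloc[train], yy[train])
        s = model.score(X.iloc[test])
        pred = s > model.threshold
        truth = yy[test] > 0
        tp = int((pred & truth).sum())
        tn = int((~pred & ~truth).sum())
        fp = int((pred & ~truth).sum())
        fn = int((~pred & truth).sum())
        total_correct += tp + tn
        sens = tp / (tp + fn) if (tp + fn) else np.nan
        spec = tn / (tn + fp) if (tn + fp) else np.nan
        if truth.any() and (~truth).any():
            auc = mann_whitney_auc(s, yy[test])
        else:
            warnings.warn(
                f"fold {fold} holds a single class; AUC excluded from the mean",
                stacklevel=2,
            )
            auc = np.nan
        rows.append(
            {
                "fold": fold,
                "n_test": len(test),
                "tp": tp,
                "tn": tn,
                "fp": fp,
                "fn": fn,
                "accuracy": (tp + tn) / len(test),
                "sensitivity": sens,
                "specificity": spec,
                "auc": auc,
            }
        )
    metrics = pd.DataFrame(rows)
    if metrics[["sensitivity", "specificity"]].isna().any().any():
        warnings.warn(
            "some folds lack a class; sensitivity/specificity means skip them",
            stacklevel=2,
        )
    return CVReport(
        fold_metrics=metrics,
        mean_accuracy=float(metrics["accuracy"].mean()),
        mean_sensitivity=float(metrics["sensitivity"].mean()),
        mean_specificity=float(metrics["specificity"].mean()),
        mean_auc=float(metrics["auc"].mean()),
        pooled_accuracy=total_correct / len(X),
        fold_assignments=assignments,
        seed=seed,
    )


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def compare_roc(scores_a, scores_b, labels) -> tuple[float, float, float]:
    """DeLong test for two correlated ROC curves on the same samples.

    Returns ``(auc_a, auc_b, p)`` with a two-sided p-value for the null of
    equal AUCs. Identical (or rank-identical) score vectors give p = 1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    yy = encode_labels(labels)
    if not (scores_a.shape == scores_b.shape == yy.shape):
        raise ValueError("paired scores and labels must align")
    pos = yy > 0
    m = int(pos.sum())
    n = int((~pos).sum())
    if m == 0 or n == 0:
        raise ValueError("both classes must be present to compare ROC curves")

    aucs = np.empty(2)
    v01 = np.empty((2, m))
    v10 = np.empty((2, n))
    for i, s in enumerate((scores_a, scores_b)):
        tz = _midrank(np.concatenate([s[pos], s[~pos]]))
        tx = _midrank(s[pos])
        ty = _midrank(s[~pos])
        aucs[i] = (tz[:m].sum() - m * (m + 1) / 2) / (m * n)
        v01[i] = (tz[:m] - tx) / n
        v10[i] = 1.0 - (tz[m:] - ty) / m

    s01 = np.cov(v01) if m > 1 else np.zeros((2, 2))
    s10 = np.cov(v10) if n > 1 else np.zeros((2, 2))
    var = s01 / m + s10 / n
    var_diff = float(var[0, 0] + var[1, 1] - 2 * var[0, 1])
    diff = float(aucs[0] - aucs[1])
    if var_diff <= 0:
        p = 1.0 if diff == 0 else 0.0
    else:
        z = diff / np.sqrt(var_diff)
        p = float(2 * stats.norm.sf(abs(z)))
    return float(aucs[0]), float(aucs[1]), p
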