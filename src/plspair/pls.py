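"""Single-component PLS response classifier.

The classifier is one partial-least-squares component: a unit-norm weight
vector W over a small gene panel maximizing the squared sample covariance
cov^2(Xw, y) between the linear score and the response, where predictors
are standardized and the response is coded +1 (responder) / -1
(nonresponder) and centered. The maximizer has the closed form
W = c / ||c|| with c the vector of covariances between each standardized
predictor and the centered response. A sample's score is
S = sum_i W_i * scaled(L_i); the decision threshold T is the score cutoff
maximizing Youden's J (sensitivity + specificity - 1), and a sample is
called a responder exactly when S > T.

The inherent sign ambiguity of a covariance direction is resolved by
flipping W, if needed, so that responders score higher than nonresponders
on the training data — making "S > T implies responder" self-consistent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .io import NONRESPONDER, RESPONDER


def encode_labels(labels) -> np.ndarray:
    """Map responder/nonresponder labels to +1/-1."""
    values = np.asarray(labels.values if isinstance(labels, pd.Series) else labels)
    if values.dtype.kind in "USO":
        unknown = set(np.unique(values)) - {RESPONDER, NONRESPONDER}
        if unknown:
            raise ValueError(f"unknown labels: {sorted(unknown)}")
        return np.where(values == RESPONDER, 1.0, -1.0)
    values = values.astype(float)
    if not set(np.unique(values)) <= {0.0, 1.0, -1.0}:
        raise ValueError("numeric labels must be 0/1 or -1/+1")
    return np.where(values > 0, 1.0, -1.0)


@dataclass(frozen=True)
class PLSModel:
    """Fitted panel, unit-norm weights, scaling and decision threshold."""

    panel: tuple[str, ...]
    weights: np.ndarray
    center: np.ndarray
    scale: np.ndarray
    threshold: float
    degenerate_threshold: bool = False
    reference_gene: str | None = None

    def scale_expression(self, X) -> np.ndarray:
        """Standardize panel expression with the training center/scale."""
        X = _panel_matrix(X, self.panel)
        return (X - self.center) / self.scale

    def score(self, X) -> np.ndarray:
        """Linear PLS score S = sum_i W_i * scaled(L_i) per sample."""
        return self.scale_expression(X) @ self.weights

    def predict(self, X) -> np.ndarray:
        """Responder exactly when S > T (strict)."""
        return np.where(self.score(X) > self.threshold, RESPONDER, NONRESPONDER)

    def to_dict(self) -> dict:
        return {
            "panel": list(self.panel),
            "weights": [float(w) for w in self.weights],
            "center": [float(c) for c in self.center],
            "scale": [float(s) for s in self.scale],
            "threshold": float(self.threshold),
            "degenerate_threshold": bool(self.degenerate_threshold),
            "reference_gene": self.reference_gene,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PLSModel":
        return cls(
            panel=tuple(d["panel"]),
            weights=np.asarray(d["weights"], dtype=float),
            center=np.asarray(d["center"], dtype=float),
            scale=np.asarray(d["scale"], dtype=float),
            threshold=float(d["threshold"]),
            degenerate_threshold=bool(d.get("degenerate_threshold", False)),
            reference_gene=d.get("reference_gene"),
        )


class ThresholdResult(NamedTuple):
    threshold: float
    youden_j: float
    degenerate: bool


def _panel_matrix(X, panel: tuple[str, ...] | None = None) -> np.ndarray:
    """Coerce samples x panel input (DataFrame, Series, dict, array) to 2-d."""
    if isinstance(X, pd.DataFrame):
        if panel is not None:
            missing = [g for g in panel if g not in X.columns]
            if missing:
                raise KeyError(f"panel genes missing from input: {missing}")
            X = X.loc[:, list(panel)]
        return X.to_numpy(float)
    if isinstance(X, pd.Series):
        return _panel_matrix(X.to_frame().T, panel)
    if isinstance(X, dict):
        return _panel_matrix(pd.DataFrame([X]), panel)
    arr = np.atleast_2d(np.asarray(X, dtype=float))
    if panel is not None and arr.shape[1] != len(panel):
        raise ValueError(
            f"expected {len(panel)} panel genes, got {arr.shape[1]} columns"
        )
    return arr


def fit_weights(X, y, panel: tuple[str, ...] | None = None) -> np.ndarray:
    """Closed-form unit-norm weights maximizing cov^2(Xw, y).

    ``X`` is samples x panel; predictors are standardized internally and
    ``y`` is coded +1/-1 and centered. The weight vector is the normalized
    covariance vector between standardized predictors and centered
    response, sign-flipped so responders score higher.
    """
    Xs, _, _ = _standardize(X, panel)
    yc = _centered_response(y, Xs.shape[0])
    n = Xs.shape[0]
    c = Xs.T @ yc / (n - 1)
    norm = float(np.linalg.norm(c))
    if norm == 0:
        raise ValueError("response is uncorrelated with every panel gene")
    w = c / norm
    scores = Xs @ w
    if scores[yc > 0].mean() < scores[yc < 0].mean():
        w = -w
    return w


def _standardize(
    X, panel: tuple[str, ...] | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    arr = _panel_matrix(X, panel)
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 samples to standardize")
    center = arr.mean(axis=0)
    scale = arr.std(axis=0, ddof=1)
    if np.any(scale == 0):
        names = (
            [panel[i] for i in np.nonzero(scale == 0)[0]]
            if panel is not None
            else list(np.nonzero(scale == 0)[0])
        )
        raise ValueError(f"zero-variance panel gene(s): {names}")
    return (arr - center) / scale, center, scale


def _centered_response(y, n_samples: int) -> np.ndarray:
    yy = encode_labels(y)
    if yy.shape[0] != n_samples:
        raise ValueError("X and y disagree on the number of samples")
    if (yy > 0).sum() < 2 or (yy < 0).sum() < 2:
        raise ValueError("need at least 2 samples in each class to fit")
    return yy - yy.mean()


def select_threshold(scores, labels) -> ThresholdResult:
    """Score cutoff maximizing Youden's J over midpoints of adjacent scores.

    Candidate cutoffs are the midpoints between adjacent distinct sorted
    scores; J ties are broken toward the smallest cutoff. If every score is
    identical there is no informative cutoff: that score is returned with
    the degenerate flag set.
    """
    scores = np.asarray(scores, dtype=float)
    yy = encode_labels(labels)
    if scores.shape != yy.shape:
        raise ValueError("scores and labels must align")
    if np.unique(yy).size < 2:
        raise ValueError("both classes must be present to choose a threshold")

    distinct = np.unique(scores)
    if distinct.size == 1:
        return ThresholdResult(float(distinct[0]), 0.0, True)
    cutoffs = (distinct[:-1] + distinct[1:]) / 2
    n_pos = int((yy > 0).sum())
    n_neg = int((yy < 0).sum())
    # predicted responder iff score > T; compare J in exact integer units
    # (tp*n_neg + tn*n_pos) so ties break reliably toward the smallest cutoff
    tp = np.array([(scores[yy > 0] > t).sum() for t in cutoffs])
    tn = np.array([(scores[yy < 0] <= t).sum() for t in cutoffs])
    j_units = tp * n_neg + tn * n_pos
    best = int(np.argmax(j_units))  # argmax takes the first cutoff on ties
    j = tp[best] / n_pos + tn[best] / n_neg - 1.0
    return ThresholdResult(float(cutoffs[best]), float(j), False)


def fit(
    X,
    labels,
    panel: tuple[str, ...] | None = None,
    reference_gene: str | None = None,
) -> PLSModel:
    """Fit weights, scaling and threshold on a training cohort.

    ``X`` is samples x panel (DataFrame columns name the panel when
    ``panel`` is omitted). The threshold is chosen on the training scores
    by Youden's J.
    """
    if panel is None and isinstance(X, pd.DataFrame):
        panel = tuple(X.columns)
    if panel is None:
        raise ValueError("panel gene ids are required for non-DataFrame input")
    Xs, center, scale = _standardize(X, panel)
    yc = _centered_response(labels, Xs.shape[0])
    n = Xs.shape[0]
    c = Xs.T @ yc / (n - 1)
    norm = float(np.linalg.norm(c))
    if norm == 0:
        raise ValueError("response is uncorrelated with every panel gene")
    w = c / norm
    scores = Xs @ w
    if scores[yc > 0].mean() < scores[yc < 0].mean():
        w, scores = -w, -scores
    thr = select_threshold(scores, labels)
    return PLSModel(
        panel=tuple(panel),
        weights=w,
        center=center,
        scale=scale,
        threshold=thr.threshold,
        degenerate_threshold=thr.degenerate,
        reference_gene=reference_gene,
    )


def score(model: PLSModel, sample_expression) -> np.ndarray:
    """Module-level alias for :meth:`PLSModel.score`."""
    return model.score(sample_expression)


def predict(model: PLSModel, X) -> np.ndarray:
    """Module-level alias for :meth:`PLSModel.predict`."""
    return model.predict(X)
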