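"""lncRNA-mRNA co-expression screening within each response group.

All lncRNA x mRNA Pearson correlations are computed separately among
responders and among nonresponders; a pair is retained when it is
significant (two-sided p from the t-transform with n-2 df) in *both*
groups. The mRNA side of the surviving pairs is then intersected with a
drug-target gene list to give the candidate biomarker pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import NONRESPONDER, RESPONDER

PAIR_COLUMNS = [
    "lnc_id",
    "mrna_id",
    "r_responder",
    "p_responder",
    "r_nonresponder",
    "p_nonresponder",
    "mean_abs_r",
]


@dataclass(frozen=True)
class CoexpressionPair:
    """A lncRNA/mRNA pair with per-group correlation evidence."""

    lnc_id: str
    mrna_id: str
    r_responder: float
    p_responder: float
    r_nonresponder: float
    p_nonresponder: float

    @property
    def mean_abs_r(self) -> float:
        return (abs(self.r_responder) + abs(self.r_nonresponder)) / 2


def pearson_with_p(x, y) -> tuple[float, float]:
    """Sample Pearson r with two-sided p from the t-transform (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs contain non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a zero-variance vector")
    r = float(stats.pearsonr(x, y).statistic)
    return r, _r_to_p(np.array([r]), n).item()


def _r_to_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Pearson r via t = r*sqrt((n-2)/(1-r^2))."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.where(np.abs(r) >= 1.0, 0.0, p)


def _group_correlations(
    lnc: pd.DataFrame, mrna: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """All lncRNA x mRNA correlations within one sample group (vectorized)."""
    n = lnc.shape[1]
    a = lnc.to_numpy(float)
    b = mrna.to_numpy(float)
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    sa = np.sqrt((a**2).sum(axis=1))
    sb = np.sqrt((b**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (a @ b.T) / np.outer(sa, sb)
    return r, _r_to_p(r, n)


@dataclass(frozen=True)
class ScreenResult:
    responder_pairs: pd.DataFrame
    nonresponder_pairs: pd.DataFrame
    intersection: pd.DataFrame


def screen_pairs(
    lnc_matrix: pd.DataFrame,
    mrna_matrix: pd.DataFrame,
    labels: pd.Series,
    p_threshold: float = 0.05,
) -> ScreenResult:
    """Pairs significantly correlated within responders, nonresponders, and both.

    Matrices are genes x samples, typically restricted to DE-surviving
    genes. Returns per-group significant pair tables (lnc_id, mrna_id, r, p)
    and the both-groups intersection with the full evidence columns; all
    tables sorted by (lnc_id, mrna_id) so output is order-invariant.
    """
    labels = labels.reindex(lnc_matrix.columns)
    if not lnc_matrix.columns.equals(mrna_matrix.columns):
        raise ValueError("lncRNA and mRNA matrices must share the same samples")
    out = {}
    stats_by_group = {}
    for group in (RESPONDER, NONRESPONDER):
        cols = (labels == group).values
        if cols.sum() < 3:
            raise ValueError(f"need at least 3 {group} samples for correlation")
        r, p = _group_correlations(
            lnc_matrix.loc[:, cols], mrna_matrix.loc[:, cols]
        )
        stats_by_group[group] = (r, p)
        li, mi = np.nonzero(p < p_threshold)
        out[group] = (
            pd.DataFrame(
                {
                    "lnc_id": lnc_matrix.index[li],
                    "mrna_id": mrna_matrix.index[mi],
                    "r": r[li, mi],
                    "p": p[li, mi],
                }
            )
            .sort_values(["lnc_id", "mrna_id"])
            .reset_index(drop=True)
        )

    r_r, p_r = stats_by_group[RESPONDER]
    r_n, p_n = stats_by_group[NONRESPONDER]
    li, mi = np.nonzero((p_r < p_threshold) & (p_n < p_threshold))
    intersection = (
        pd.DataFrame(
            {
                "lnc_id": lnc_matrix.index[li],
                "mrna_id": mrna_matrix.index[mi],
                "r_responder": r_r[li, mi],
                "p_responder": p_r[li, mi],
                "r_nonresponder": r_n[li, mi],
                "p_nonresponder": p_n[li, mi],
                "mean_abs_r": (np.abs(r_r[li, mi]) + np.abs(r_n[li, mi])) / 2,
            }
        )
        .sort_values(["lnc_id", "mrna_id"])
        .reset_index(drop=True)
    )
    return ScreenResult(out[RESPONDER], out[NONRESPONDER], intersection)


def intersect_targets(
    pairs: pd.DataFrame, target_list: list[str]
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Retain pairs whose mRNA is a drug target; report Venn counts.

    Matching is exact and case-sensitive after whitespace stripping.
    """
    targets = {t.strip() for t in target_list}
    keep = pairs["mrna_id"].astype(str).str.strip().isin(targets)
    candidates = pairs.loc[keep].reset_index(drop=True)
    venn = {
        "pairs_total": int(len(pairs)),
        "targets_total": len(targets),
        "overlap": int(len(candidates)),
    }
    return candidates, venn
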