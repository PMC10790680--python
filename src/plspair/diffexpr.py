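"""Differential expression screening between responders and nonresponders.

Two-sided unpaired Student t-test (pooled variance) per gene on log2-scale
expression, with log2 fold-change defined as responder mean minus
nonresponder mean. Filtering keeps genes with raw p below a threshold and
|log2FC| at or above a threshold; Benjamini-Hochberg adjustment is
available behind a flag but off by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import NONRESPONDER, RESPONDER


@dataclass(frozen=True)
class DEResult:
    gene_id: str
    gene_class: str
    log2_fold_change: float
    t_statistic: float
    p_value: float

    @property
    def direction(self) -> str:
        return "up" if self.log2_fold_change > 0 else "down"


def _split_classes(
    matrix: pd.DataFrame, labels: pd.Series
) -> tuple[np.ndarray, np.ndarray]:
    labels = labels.reindex(matrix.columns)
    if labels.isna().any():
        missing = list(matrix.columns[labels.isna()])
        raise ValueError(f"samples without labels: {missing}")
    resp = matrix.loc[:, (labels == RESPONDER).values].to_numpy(float)
    non = matrix.loc[:, (labels == NONRESPONDER).values].to_numpy(float)
    if resp.shape[1] < 2 or non.shape[1] < 2:
        raise ValueError("need at least 2 samples per class for the t-test")
    return resp, non


def de_test(
    matrix: pd.DataFrame, labels: pd.Series, gene_class: str = "mRNA"
) -> list[DEResult]:
    """Per-gene pooled-variance t-test of responders vs nonresponders.

    ``matrix`` is genes x samples on the log2 scale; ``labels`` maps sample
    id to responder/nonresponder. A gene with zero variance in both groups
    and equal means gets t = 0, p = 1 by convention.
    """
    resp, non = _split_classes(matrix, labels)
    if not (np.isfinite(resp).all() and np.isfinite(non).all()):
        raise ValueError("expression matrix contains non-finite values")

    lfc = resp.mean(axis=1) - non.mean(axis=1)
    with warnings.catch_warnings():
        # zero-pooled-variance genes are resolved by convention below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(resp, non, axis=1, equal_var=True)

    # degenerate genes: identical values everywhere -> no evidence, p = 1
    degenerate = ~np.isfinite(t)
    zero_diff = np.isclose(lfc, 0.0)
    t = np.where(degenerate & zero_diff, 0.0, t)
    p = np.where(degenerate & zero_diff, 1.0, p)
    # zero pooled variance but unequal means: infinitely strong evidence
    signed_inf = np.where(lfc > 0, np.inf, -np.inf)
    t = np.where(degenerate & ~zero_diff, signed_inf, t)
    p = np.where(degenerate & ~zero_diff, 0.0, p)

    return [
        DEResult(gene, gene_class, float(l), float(ti), float(pi))
        for gene, l, ti, pi in zip(matrix.index, lfc, t, p)
    ]


def filter_de(
    results: list[DEResult],
    p_threshold: float = 0.05,
    abs_log2fc_threshold: float = 0.5,
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Keep genes with p < p_threshold and |log2FC| >= abs_log2fc_threshold.

    Returns the surviving genes as a DataFrame (gene_id, gene_class,
    log2_fold_change, t_statistic, p_value, direction) with up/down counts
    in ``df.attrs``. With ``bh_adjust`` the p filter applies to
    Benjamini-Hochberg adjusted values instead of raw ones.
    """
    if p_threshold < 0 or abs_log2fc_threshold < 0:
        raise ValueError("thresholds must be non-negative")
    df = de_table(results)
    pvals = df["p_value"].to_numpy()
    if bh_adjust and len(df):
        pvals = stats.false_discovery_control(pvals, method="bh")
    keep = (pvals < p_threshold) & (
        df["log2_fold_change"].abs() >= abs_log2fc_threshold
    )
    out = df.loc[keep].reset_index(drop=True)
    out.attrs["n_up"] = int((out["direction"] == "up").sum())
    out.attrs["n_down"] = int((out["direction"] == "down").sum())
    return out


def de_table(results: list[DEResult]) -> pd.DataFrame:
    """Flatten DEResult records into a tidy DataFrame."""
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "gene_class": r.gene_class,
                "log2_fold_change": r.log2_fold_change,
                "t_statistic": r.t_statistic,
                "p_value": r.p_value,
                "direction": r.direction,
            }
            for r in results
        ],
        columns=[
            "gene_id",
            "gene_class",
            "log2_fold_change",
            "t_statistic",
            "p_value",
            "direction",
        ],
    )
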