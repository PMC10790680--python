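"""Tabular I/O helpers: expression matrices, labels, edge lists, gene lists, models.

All tabular formats are TSV with a header row. Expression matrices are
genes x samples (first column ``gene_id``); labels map ``sample_id`` to
``responder``/``nonresponder``; edge lists carry ``node1``, ``node2``,
``combined_score``. Fitted models round-trip through JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

RESPONDER = "responder"
NONRESPONDER = "nonresponder"
LABEL_VALUES = (RESPONDER, NONRESPONDER)


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples expression TSV (first column gene ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str).str.strip()
    return df.astype(float)


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id")


def read_labels(path: str | Path) -> pd.Series:
    """Read a sample_id/response TSV into a Series indexed by sample id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "response"} <= set(df.columns):
        raise ValueError("labels file must have columns sample_id and response")
    labels = pd.Series(
        df["response"].str.strip().values,
        index=df["sample_id"].str.strip(),
        name="response",
    )
    bad = sorted(set(labels.unique()) - set(LABEL_VALUES))
    if bad:
        raise ValueError(f"unknown response labels: {bad}; expected {LABEL_VALUES}")
    return labels


def write_labels(labels: pd.Series, path: str | Path) -> None:
    out = pd.DataFrame({"sample_id": labels.index, "response": labels.values})
    out.to_csv(path, sep="\t", index=False)


def read_edges(path: str | Path) -> pd.DataFrame:
    """Read a weighted edge TSV (node1, node2, combined_score); header optional."""
    first = pd.read_csv(path, sep="\t", nrows=1, header=None)
    has_header = not _looks_numeric(first.iloc[0, -1])
    df = pd.read_csv(path, sep="\t", header=0 if has_header else None)
    df.columns = ["node1", "node2", "combined_score"]
    df["node1"] = df["node1"].astype(str).str.strip()
    df["node2"] = df["node2"].astype(str).str.strip()
    df["combined_score"] = df["combined_score"].astype(float)
    return df


def _looks_numeric(value: object) -> bool:
    try:
        float(value)  # type: ignore[arg-type]
        return True
    except (TypeError, ValueError):
        return False


def write_edges(edges: pd.DataFrame, path: str | Path) -> None:
    edges.to_csv(path, sep="\t", index=False,
                 columns=["node1", "node2", "combined_score"])


def read_gene_list(path: str | Path) -> list[str]:
    """Read a plain-text gene list, one symbol per line, whitespace-stripped."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes: list[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
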