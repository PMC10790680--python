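"""End-to-end orchestration: DE -> pair screening -> network ranking -> PLS.

``discover`` runs the biomarker-discovery arm (differential expression in
both gene classes, within-group co-expression screening, drug-target
intersection, median-filtered network topology, top-pair selection) and
``predict_response`` the classification arm (one PLS model per requested
reference-gene normalization, fivefold CV, DeLong comparison of the paired
model against each single-gene score). File-level wrappers
(``run_discovery``, ``run_prediction``) read and write the TSV/JSON
artifacts so a run can resume from any stage's files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import coexpression, diffexpr, evaluation, io, network, pls

logger = logging.getLogger("plspair")


@dataclass
class RunConfig:
    """Paths, thresholds and seeds for a file-driven pipeline run."""

    expr_lnc: str
    expr_mrna: str
    labels: str
    targets: str
    edges: str
    out_dir: str = "plspair_out"
    p_de: float = 0.05
    abs_log2fc: float = 0.5
    p_pair: float = 0.05
    k_folds: int = 5
    seed: int = 0
    reference_genes: tuple[str, ...] = ("RN18S", "GAPDH")
    panel: tuple[str, str] | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "reference_genes" in raw:
            raw["reference_genes"] = tuple(raw["reference_genes"])
        if raw.get("panel"):
            raw["panel"] = tuple(raw["panel"])
        return cls(**raw)

    def validate(self) -> None:
        for name in ("expr_lnc", "expr_mrna", "labels", "targets", "edges"):
            path = getattr(self, name)
            if not Path(path).is_file():
                raise FileNotFoundError(f"{name} file not found: {path}")
        for name in ("p_de", "p_pair"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.abs_log2fc < 0:
            raise ValueError("abs_log2fc must be non-negative")
        if self.k_folds < 2:
            raise ValueError("k_folds must be at least 2")


@dataclass
class DiscoveryReport:
    de_lnc: pd.DataFrame
    de_mrna: pd.DataFrame
    screen: coexpression.ScreenResult
    candidates: pd.DataFrame
    venn: dict[str, int]
    topology: pd.DataFrame
    ranked: pd.DataFrame

    @property
    def top_pair(self) -> tuple[str, str]:
        row = self.ranked.iloc[0]
        return (str(row["lnc_id"]), str(row["mrna_id"]))

    def summary(self) -> dict:
        return {
            "n_de_lnc": int(len(self.de_lnc)),
            "n_de_mrna": int(len(self.de_mrna)),
            "n_pairs_responder": int(len(self.screen.responder_pairs)),
            "n_pairs_nonresponder": int(len(self.screen.nonresponder_pairs)),
            "n_pairs_both": int(len(self.screen.intersection)),
            "venn": self.venn,
            "n_candidates": int(len(self.candidates)),
            "top_pair": list(self.top_pair),
        }


def discover(
    lnc_matrix: pd.DataFrame,
    mrna_matrix: pd.DataFrame,
    labels: pd.Series,
    target_list: list[str],
    edges: pd.DataFrame,
    p_de: float = 0.05,
    abs_log2fc: float = 0.5,
    p_pair: float = 0.05,
) -> DiscoveryReport:
    """Run the discovery arm on in-memory inputs and rank candidate pairs."""
    de_lnc = diffexpr.filter_de(
        diffexpr.de_test(lnc_matrix, labels, gene_class="lncRNA"), p_de, abs_log2fc
    )
    logger.info("DE lncRNAs: %d of %d survive", len(de_lnc), len(lnc_matrix))
    de_mrna = diffexpr.filter_de(
        diffexpr.de_test(mrna_matrix, labels, gene_class="mRNA"), p_de, abs_log2fc
    )
    logger.info("DE mRNAs: %d of %d survive", len(de_mrna), len(mrna_matrix))
    if len(de_lnc) == 0 or len(de_mrna) == 0:
        raise ValueError("no differentially expressed genes in one class")

    screen = coexpression.screen_pairs(
        lnc_matrix.loc[de_lnc["gene_id"]],
        mrna_matrix.loc[de_mrna["gene_id"]],
        labels,
        p_threshold=p_pair,
    )
    logger.info(
        "pairs: %d responder / %d nonresponder / %d both",
        len(screen.responder_pairs),
        len(screen.nonresponder_pairs),
        len(screen.intersection),
    )
    candidates, venn = coexpression.intersect_targets(
        screen.intersection, target_list
    )
    logger.info("target intersection: %d candidate pairs", len(candidates))
    if len(candidates) == 0:
        raise ValueError("no candidate pairs after target intersection")

    graph = network.filter_edges_by_median(edges)
    topology = network.compute_topology(graph)
    ranked = network.select_top_pair(candidates, topology)
    logger.info("top pair: %s/%s", *ranked.iloc[0][["lnc_id", "mrna_id"]])
    return DiscoveryReport(de_lnc, de_mrna, screen, candidates, venn, topology, ranked)


def _panel_frame(
    lnc_matrix: pd.DataFrame,
    mrna_matrix: pd.DataFrame,
    pair: tuple[str, str],
    reference_gene: str | None,
) -> pd.DataFrame:
    """Samples x panel expression, optionally normalized to a reference gene.

    Normalization subtracts the reference row on the log2 scale (the
    negative of a qPCR delta-Ct).
    """
    lnc_id, mrna_id = pair
    if lnc_id not in lnc_matrix.index:
        raise KeyError(f"panel lncRNA {lnc_id!r} missing from expression")
    if mrna_id not in mrna_matrix.index:
        raise KeyError(f"panel mRNA {mrna_id!r} missing from expression")
    X = pd.DataFrame(
        {lnc_id: lnc_matrix.loc[lnc_id], mrna_id: mrna_matrix.loc[mrna_id]}
    )
    if reference_gene is not None:
        pool = mrna_matrix if reference_gene in mrna_matrix.index else lnc_matrix
        if reference_gene not in pool.index:
            raise KeyError(f"reference gene {reference_gene!r} missing")
        X = X.sub(pool.loc[reference_gene], axis=0)
    return X


def predict_response(
    lnc_matrix: pd.DataFrame,
    mrna_matrix: pd.DataFrame,
    labels: pd.Series,
    pair: tuple[str, str],
    reference_genes: tuple[str, ...] | tuple[None, ...] = (None,),
    k_folds: int = 5,
    seed: int = 0,
) -> dict:
    """Fit the paired-gene PLS classifier under each normalization.

    For every requested reference gene (``None`` = no normalization) this
    fits a PLSModel on the full cohort, runs stratified k-fold CV, and
    compares the paired-gene ROC with each single-gene ROC (standardized
    single-gene scores) by the DeLong test.
    """
    results: dict = {"pair": list(pair), "models": {}}
    for ref in reference_genes:
        X = _panel_frame(lnc_matrix, mrna_matrix, pair, ref)
        model = pls.fit(X, labels, reference_gene=ref)
        cv = evaluation.cross_validate(X, labels, k=k_folds, seed=seed)
        pair_scores = model.score(X)
        roc = evaluation.roc_auc(pair_scores, labels)
        comparisons = {}
        for gene in pair:
            single = (X[gene] - X[gene].mean()) / X[gene].std(ddof=1)
            if evaluation.mann_whitney_auc(single, labels) < 0.5:
                single = -single
            auc_pair, auc_single, p = evaluation.compare_roc(
                pair_scores, single, labels
            )
            comparisons[gene] = {
                "auc_pair": auc_pair,
                "auc_single": auc_single,
                "p_value": p,
            }
        key = ref if ref is not None else "none"
        results["models"][key] = {
            "model": model.to_dict(),
            "roc": {"auc": roc.auc, "se": roc.se, "ci95": list(roc.ci95)},
            "cv": cv.to_dict(),
            "comparisons": comparisons,
        }
        logger.info(
            "reference %s: AUC %.3f, CV mean accuracy %.3f",
            key,
            roc.auc,
            cv.mean_accuracy,
        )
    return results


def _load_inputs(config: RunConfig):
    lnc = io.read_expression(config.expr_lnc)
    mrna = io.read_expression(config.expr_mrna)
    labels = io.read_labels(config.labels)
    targets = io.read_gene_list(config.targets)
    edges = io.read_edges(config.edges)
    return lnc, mrna, labels, targets, edges


def run_discovery(config: RunConfig) -> DiscoveryReport:
    """File-driven discovery arm; writes DE, pair, topology and ranking TSVs."""
    config.validate()
    lnc, mrna, labels, targets, edges = _load_inputs(config)
    report = discover(
        lnc, mrna, labels, targets, edges,
        p_de=config.p_de, abs_log2fc=config.abs_log2fc, p_pair=config.p_pair,
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.de_lnc.to_csv(out / "de_lncrna.tsv", sep="\t", index=False)
    report.de_mrna.to_csv(out / "de_mrna.tsv", sep="\t", index=False)
    report.screen.intersection.to_csv(out / "pairs_both_groups.tsv", sep="\t", index=False)
    report.topology.to_csv(out / "topology.tsv", sep="\t", index=False)
    report.ranked.to_csv(out / "ranked_candidates.tsv", sep="\t", index=False)
    io.write_json(report.summary(), out / "discovery_summary.json")
    return report


def run_prediction(config: RunConfig, pair: tuple[str, str]) -> dict:
    """File-driven prediction arm; writes model JSONs and the CV report."""
    config.validate()
    lnc = io.read_expression(config.expr_lnc)
    mrna = io.read_expression(config.expr_mrna)
    labels = io.read_labels(config.labels)
    refs = tuple(
        r for r in config.reference_genes
        if r in mrna.index or r in lnc.index
    ) or (None,)
    results = predict_response(
        lnc, mrna, labels, pair,
        reference_genes=refs, k_folds=config.k_folds, seed=config.seed,
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for key, entry in results["models"].items():
        io.write_json(entry["model"], out / f"model_{key}.json")
    io.write_json(results, out / "prediction_report.json")
    return results


def run_all(config: RunConfig) -> dict:
    """Discovery then prediction on the discovered top pair."""
    report = run_discovery(config)
    pair = config.panel or report.top_pair
    results = run_prediction(config, pair)
    return {"discovery": report.summary(), "prediction": results}
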