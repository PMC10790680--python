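"""Synthetic two-class expression cohorts with a planted lncRNA/mRNA signal pair.

The generator emulates the statistical structure the discovery pipeline
assumes: a responder/nonresponder cohort whose planted lncRNA is shifted up
and planted mRNA shifted down in responders, with the two correlated within
each class; independent background genes, a fraction of which carry random
class effects; a preferential-attachment interaction network in which the
planted genes are hubs; a drug-target list containing the planted mRNA; and
qPCR tables normalized to an internal reference gene.

Expression is modeled as Gaussian log2 intensity (microarray-like); qPCR
Ct values are derived from it by a monotone map, so both assay types share
one latent abundance scale. A single integer seed governs every generator:
each stage draws from its own deterministic substream of that seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io import NONRESPONDER, RESPONDER

REFERENCE_GENES = ("RN18S", "GAPDH")

# substream indices, one per generator stage
_STREAM_COHORT = 0
_STREAM_NETWORK = 1
_STREAM_TARGETS = 2
_STREAM_QPCR = 3


class InvalidConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror a small two-class discovery cohort: 6 responders vs 6
    nonresponders, a planted pair with standardized effect |d| = 1.5
    (lncRNA up, mRNA down in responders), within-class Pearson correlation
    0.8 between the pair, unit residual SD on the log2 scale, 200
    background genes of each class (10% of them with random class effects),
    and a 100-node preferential-attachment network.
    """

    n_responders: int = 6
    n_nonresponders: int = 6
    n_lnc_background: int = 200
    n_mrna_background: int = 200
    effect_size_d: float = 1.5
    within_class_rho: float = 0.8
    noise_sd: float = 1.0
    n_network_nodes: int = 100
    network_attachment: int = 2
    background_de_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_responders < 2 or self.n_nonresponders < 2:
            raise InvalidConfigError("need at least 2 samples per class")
        if self.n_lnc_background < 0 or self.n_mrna_background < 0:
            raise InvalidConfigError("background gene counts must be non-negative")
        if not abs(self.within_class_rho) < 1:
            raise InvalidConfigError("|within_class_rho| must be < 1")
        if self.noise_sd <= 0:
            raise InvalidConfigError("noise_sd must be positive")
        if self.n_network_nodes < 2:
            raise InvalidConfigError("network needs at least 2 nodes")
        if self.network_attachment < 1:
            raise InvalidConfigError("network_attachment must be >= 1")
        if not 0 <= self.background_de_fraction <= 1:
            raise InvalidConfigError("background_de_fraction must be in [0, 1]")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth of the planted signal, sufficient to score recovery."""

    signal_lnc_id: str
    signal_mrna_id: str
    lnc_effect_size: float
    mrna_effect_size: float
    within_class_rho: float
    background_lnc_ids: tuple[str, ...] = ()
    background_mrna_ids: tuple[str, ...] = ()
    de_background_ids: tuple[str, ...] = ()


@dataclass(frozen=True)
class QPCRTable:
    """Per-sample Ct values and 2^(-dCt) relative expression."""

    ct: pd.DataFrame
    relative_expression: pd.DataFrame
    reference_gene: str


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def generate_cohort(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, TruthRecord]:
    """Simulate lncRNA and mRNA log2-expression matrices plus labels and truth.

    Returns ``(lnc_matrix, mrna_matrix, labels, truth)``; matrices are
    genes x samples DataFrames. The planted lncRNA mean is shifted by
    +d*noise_sd in responders and the planted mRNA by -d*noise_sd; within
    each class the pair is bivariate normal with correlation
    ``within_class_rho``. Background genes are independent Gaussians, a
    ``background_de_fraction`` of which receive a random class effect
    (magnitude 0.8-1.6 SD, random sign). Two near-constant reference genes
    (RN18S, GAPDH) are appended to the mRNA matrix for qPCR normalization.
    """
    rng = _rng(config, _STREAM_COHORT)
    n_r, n_n = config.n_responders, config.n_nonresponders
    n_total = n_r + n_n
    sd = config.noise_sd
    d = config.effect_size_d
    rho = config.within_class_rho

    samples = [f"R{i + 1:03d}" for i in range(n_r)] + [
        f"N{i + 1:03d}" for i in range(n_n)
    ]
    labels = pd.Series(
        [RESPONDER] * n_r + [NONRESPONDER] * n_n, index=samples, name="response"
    )

    lnc_ids = [f"LNC{i + 1:04d}" for i in range(config.n_lnc_background + 1)]
    mrna_ids = [f"GENE{i + 1:04d}" for i in range(config.n_mrna_background + 1)]
    signal_lnc = lnc_ids[int(rng.integers(len(lnc_ids)))]
    signal_mrna = mrna_ids[int(rng.integers(len(mrna_ids)))]
    bg_lnc = tuple(g for g in lnc_ids if g != signal_lnc)
    bg_mrna = tuple(g for g in mrna_ids if g != signal_mrna)

    base = {g: rng.normal(8.0, 1.5) for g in lnc_ids + mrna_ids}

    # planted pair: bivariate normal within each class
    cov = sd**2 * np.array([[1.0, rho], [rho, 1.0]])
    pair = np.empty((2, n_total))
    mu_resp = np.array([base[signal_lnc] + d * sd, base[signal_mrna] - d * sd])
    mu_non = np.array([base[signal_lnc], base[signal_mrna]])
    pair[:, :n_r] = rng.multivariate_normal(mu_resp, cov, size=n_r).T
    pair[:, n_r:] = rng.multivariate_normal(mu_non, cov, size=n_n).T

    def _background(ids: tuple[str, ...]) -> tuple[np.ndarray, list[str]]:
        values = np.empty((len(ids), n_total))
        de_ids: list[str] = []
        for i, g in enumerate(ids):
            mu = np.full(n_total, base[g])
            if rng.random() < config.background_de_fraction:
                shift = rng.uniform(0.8, 1.6) * sd * rng.choice([-1.0, 1.0])
                mu[:n_r] += shift
                de_ids.append(g)
            values[i] = rng.normal(mu, sd)
        return values, de_ids

    bg_lnc_values, de_lnc = _background(bg_lnc)
    bg_mrna_values, de_mrna = _background(bg_mrna)

    lnc = pd.DataFrame(bg_lnc_values, index=list(bg_lnc), columns=samples)
    lnc.loc[signal_lnc] = pair[0]
    lnc = lnc.loc[lnc_ids]

    mrna = pd.DataFrame(bg_mrna_values, index=list(bg_mrna), columns=samples)
    mrna.loc[signal_mrna] = pair[1]
    mrna = mrna.loc[mrna_ids]
    for ref, level in zip(REFERENCE_GENES, (14.0, 12.0)):
        mrna.loc[ref] = rng.normal(level, 0.05 * sd, size=n_total)

    truth = TruthRecord(
        signal_lnc_id=signal_lnc,
        signal_mrna_id=signal_mrna,
        lnc_effect_size=d,
        mrna_effect_size=-d,
        within_class_rho=rho,
        background_lnc_ids=bg_lnc,
        background_mrna_ids=bg_mrna,
        de_background_ids=tuple(de_lnc + de_mrna),
    )
    return lnc, mrna, labels, truth


def generate_network(truth: TruthRecord, config: SimConfig) -> pd.DataFrame:
    """Simulate a STRING-like weighted edge list with the planted pair as hubs.

    Grows a preferential-attachment graph on ``n_network_nodes`` nodes,
    relabels the two highest-degree nodes as the planted lncRNA and mRNA
    (so they are hubs), maps the remaining nodes onto background gene ids,
    guarantees a direct edge between the planted pair, and assigns each
    edge an integer combined score drawn uniformly from [1, 1000].
    """
    rng = _rng(config, _STREAM_NETWORK)
    n = config.n_network_nodes
    pool = list(truth.background_lnc_ids) + list(truth.background_mrna_ids)
    if n - 2 > len(pool):
        raise InvalidConfigError(
            f"n_network_nodes={n} exceeds the {len(pool) + 2} available gene ids"
        )

    if n == 2:
        graph = nx.Graph([(0, 1)])
    else:
        m = min(config.network_attachment, n - 1)
        graph = nx.barabasi_albert_graph(n, m, seed=int(rng.integers(2**31)))

    # top-2 degree nodes become the planted genes (ties broken by node id)
    by_degree = sorted(graph.degree, key=lambda kv: (-kv[1], kv[0]))
    hubs = [by_degree[0][0], by_degree[1][0]]
    others = [v for v in graph.nodes if v not in hubs]
    background = rng.choice(pool, size=len(others), replace=False)
    mapping = {hubs[0]: truth.signal_lnc_id, hubs[1]: truth.signal_mrna_id}
    mapping.update(dict(zip(others, background)))
    graph = nx.relabel_nodes(graph, mapping)
    graph.add_edge(truth.signal_lnc_id, truth.signal_mrna_id)

    rows = [
        (*sorted((u, v)), int(rng.integers(1, 1001)))
        for u, v in sorted(map(tuple, map(sorted, graph.edges)))
    ]
    return pd.DataFrame(rows, columns=["node1", "node2", "combined_score"])


def generate_target_list(
    truth: TruthRecord, config: SimConfig, n_decoys: int = 56
) -> list[str]:
    """Simulate a drug-target gene list: the planted mRNA plus decoys.

    The default 56 decoys give a 57-gene list, the size of a typical
    curated drug-target set for this disease.
    """
    rng = _rng(config, _STREAM_TARGETS)
    if n_decoys < 0:
        raise InvalidConfigError("n_decoys must be non-negative")
    if n_decoys > len(truth.background_mrna_ids):
        raise InvalidConfigError(
            f"{n_decoys} decoys requested but only "
            f"{len(truth.background_mrna_ids)} background mRNAs available"
        )
    decoys = rng.choice(truth.background_mrna_ids, size=n_decoys, replace=False)
    targets = [truth.signal_mrna_id, *decoys]
    rng.shuffle(targets)
    return list(targets)


def generate_qpcr(
    expression: pd.DataFrame,
    reference_gene: str,
    config: SimConfig | None = None,
    tech_noise_sd: float = 0.2,
    ct_intercept: float = 32.0,
) -> QPCRTable:
    """Derive a qPCR table from log2 expression, normalized to a reference gene.

    Ct = ct_intercept - log2_expression + Gaussian technical noise, so
    doubling a transcript's abundance lowers its Ct by exactly 1. Relative
    expression is 2^(-dCt) with dCt = Ct(gene) - Ct(reference).
    """
    if reference_gene not in expression.index:
        raise KeyError(f"reference gene {reference_gene!r} not in expression matrix")
    rng = _rng(config, _STREAM_QPCR) if config is not None else np.random.default_rng(0)
    noise = (
        rng.normal(0.0, tech_noise_sd, size=expression.shape)
        if tech_noise_sd > 0
        else 0.0
    )
    ct = ct_intercept - expression + noise
    delta_ct = ct - ct.loc[reference_gene]
    return QPCRTable(
        ct=ct, relative_expression=2.0**(-delta_ct), reference_gene=reference_gene
    )
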