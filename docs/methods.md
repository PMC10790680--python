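# Methods

## The classification model

The classifier is a single partial-least-squares component over a small
gene panel P = {P₁, …, P_k} (in the intended use, one lncRNA and one
mRNA). Predictors are standardized per gene (training mean and SD, ddof 1)
and the response is coded +1 for responders, −1 for nonresponders, then
centered. The weight vector solves

  W = argmax_{‖w‖₂=1} cov²(Xw, Y),

whose maximizer is available in closed form: cov(Xw, Y) = wᵀc is linear in
w, with c the vector of sample covariances between each standardized
predictor and the centered response, so the unit-norm maximizer of its
square is W = ±c/‖c‖. The sign ambiguity is resolved by flipping W, if
needed, so that responders have the higher mean training score; with that
convention "score > threshold ⇒ responder" is self-consistent. (With qPCR
data the orientation of the input — ΔCt vs 2^−ΔCt — flips every weight
sign; published weight signs are only interpretable relative to that
orientation, so the package fixes its own convention rather than a sign
pattern.) No deflation or further components are computed: the score
S = Σᵢ W_i·scaled(L_i) is a single linear combination by construction.

Any centered two-value coding of Y yields the same direction (c is then a
positive multiple), which is covered by a unit test.

**Threshold.** T maximizes Youden's J = sensitivity + specificity − 1 over
the midpoints between adjacent distinct sorted training scores, with the
prediction rule "responder iff S > T" (strict). J values are compared in
exact integer units (TP·n_neg + TN·n_pos) so ties break deterministically
toward the smallest cutoff regardless of floating-point rounding. If all
scores are identical, no cutoff is informative: that score is returned
with a degenerate flag.

**Evaluation.** AUC is the tie-aware Mann–Whitney estimator (probability a
random responder outscores a random nonresponder, ties counting ½),
computed from midranks; on tie-free data it equals the trapezoidal area
under the empirical ROC exactly. Its standard error uses the
Hanley–McNeil formula and the 95% CI a logit-normal approximation clipped
to [0, 1] (collapsing to a point when SE = 0 or AUC ∈ {0, 1}) — the
standard defaults when an AUC is reported with SE and CI but no named
method. Correlated ROC curves on the same
samples are compared with the DeLong test (midrank structural components;
two-sided normal p); a permutation oracle cross-checks it in the tests.
Cross-validation is stratified k-fold (default k = 5) with a seeded
shuffle; each fold refits weights, scaling and threshold on its training
portion only. If a class has fewer than k members the splitter degrades to
unstratified seeded k-fold with a warning; folds where a metric is
undefined (single-class fold for AUC, no positives for sensitivity) are
excluded from that metric's mean, again with a warning. Besides per-fold
means the report carries a pooled accuracy (ΣTP + TN)/N over all held-out
predictions.

## The discovery arm

- **Differential expression**: per-gene two-sided unpaired Student t-test
  with pooled variance (not Welch), log2FC = responder mean − nonresponder
  mean on log2-scale input. A gene constant across all samples gets
  t = 0, p = 1 by convention; zero pooled variance with unequal means gets
  p = 0. Default filter: raw p < .05 and |log2FC| ≥ 0.5. The fold-change
  cutoff is a free analysis choice (the screening literature states none
  canonically); 0.5 keeps genes whose estimated shift is at least half a
  log2 unit while not discarding moderate true effects at small n — at
  n = 20/20 the log2FC estimate of a d = 1.5 gene has SE ≈ 0.32, so a
  cutoff of 1 would drop a clearly real signal gene several percent of the
  time. No multiple-testing correction by default (raw p matches the
  screening design); Benjamini–Hochberg is available behind a flag.
- **Co-expression**: Pearson r within each response group, two-sided p via
  the t-transform t = r√((n−2)/(1−r²)); a pair is retained when p < .05
  in both groups. Correlations are computed only among DE-surviving genes,
  which bounds the pair universe and matches the screen-then-correlate
  order of the intended workflow. Target-list matching is exact and
  case-sensitive after whitespace stripping.
- **Network**: edges with combined score strictly greater than the median
  of all input scores are kept (all-equal scores therefore keep nothing);
  duplicate edges collapse to the maximum score and self-loops are
  dropped. Shortest paths are unweighted after filtering — the scores act
  only as an evidence filter, not as distances. Node importance combines
  unweighted degree, betweenness normalized by (n−1)(n−2)/2, and
  *harmonic* closeness (mean of 1/d(i,j), 1/∞ = 0), the
  disconnected-safe reading of "how quickly information from a node
  reaches the rest of the network". The composite is the sum of the three
  descending ranks with average-rank ties; smaller is more central.
- **Pair ranking**: candidates sort by mean absolute within-group
  correlation (primary), then combined rank-sum of the two members
  (members absent from the filtered network are charged a
  worse-than-worst rank), then lexicographic pair id. Correlation is
  primary because topological centrality in a public interaction network
  is evidence about the genes, not about the pair's predictive value.

## The synthetic-cohort generator

The generator emulates the statistical structure the pipeline assumes,
not any particular dataset. Expression is Gaussian log2 intensity
(microarray-like): per-gene baselines ~ N(8, 1.5), residual SD
`noise_sd` = 1 log2 unit. The planted pair is bivariate normal within
each class with correlation `within_class_rho` (default 0.8) and opposite
class shifts of ±`effect_size_d`·noise_sd (default ±1.5; lncRNA up, mRNA
down in responders). Background genes (default 200 per class) are
independent; 10% of them receive a random class effect of 0.8–1.6 SD with
random sign, so the DE filter yields a nontrivial but manageable candidate
set. The cohort default is 6 responders / 6 nonresponders — the shape of
a small discovery cohort; recovery experiments in the tests use 20/20,
where the within-group correlation screen has reasonable power (at 6 per
group a |r| ≈ 0.81 is needed for p < .05, so even a true rho = 0.8 pair
passes only about half the time — an honest property of tiny cohorts, not
a defect).

The interaction network is a Barabási–Albert preferential-attachment graph
(default 100 nodes, attachment m = 2) whose two highest-degree nodes are
relabeled as the planted genes (with a guaranteed direct edge between
them); integer edge scores are uniform on [1, 1000], giving a meaningful
median filter. The drug-target list contains the planted mRNA plus 56
decoy mRNAs (57 total, a typical curated target-set size). qPCR tables
derive from the same latent abundances via Ct = 32 − log2 expression +
N(0, 0.2²) technical noise, and relative expression 2^−ΔCt against a
near-constant reference gene (RN18S or GAPDH rows are always appended to
the mRNA matrix). One integer seed governs all generators through fixed
per-stage substreams, so outputs are bit-reproducible.

What the generator does **not** emulate: batch effects, probe-level array
structure, non-Gaussian expression (counts, heavy tails), clinical
covariates, or correlated background co-expression modules. Passing
recovery tests therefore shows the pipeline is correct and well calibrated
under its own model assumptions — it does not certify performance on real
cohorts, where normalization and confounding dominate.

## Problem sizes and numerical choices

Monte-Carlo test sizes were chosen to make the checked rates statistically
meaningful at desk scale: 100 end-to-end replicates for planted-pair
recovery (n = 20/20, d = ±1.5, rho = 0.8), 200 replicates for the
paired-vs-single-gene superiority property (n = 50/50, d = 1.0 per gene,
rho = 0), 1000 replicates/genes for null calibration, and oracle suites of
100 datasets (10⁵-vector grid sweep for the PLS direction, all-pairs AUC,
exhaustive threshold search) plus 200 random graphs of ≤ 7 nodes for
exhaustive centrality enumeration. The whole suite and the acceptance
script each run in well under a minute.

Degenerate-input conventions are stated where they live: constant genes in
the t-test (p = 1), zero-variance vectors in correlation (error), zero
variance in a panel gene (error naming the gene), single-class inputs
(error), identical scores at thresholding (degenerate flag), zero
denominators in confusion metrics (error naming the metric), and
var = 0 in the DeLong statistic (p = 1 when the AUCs are equal, else 0).

## Known limitations

- The single-component closed form is exact for this objective, but panels
  much larger than a handful of genes would typically want multi-component
  or sparse PLS, which are out of scope.
- Stratified 5-fold CV on a 12-sample cohort yields 2–3-sample test folds;
  per-fold AUCs are then extremely coarse, which is why means over folds
  (and the pooled accuracy) are reported.
- The DeLong test is asymptotic; at very small n its p-values are
  approximate (the permutation cross-check in the tests bounds the error
  at n = 40).
- Network centrality is computed on the median-filtered graph only; no
  weighted-path or signed-interaction variants are implemented.
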