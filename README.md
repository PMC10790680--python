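# plspair

Paired-gene biomarker discovery and single-component partial-least-squares
(PLS) response classification for two-class expression cohorts.

Many drug-response questions in transcriptomics come down to: *which small
set of genes, measured in peripheral blood before treatment, predicts
whether a patient will respond?* Single genes are often too noisy; a
**pair** of genes — here a lncRNA and an mRNA that are co-expressed within
each response group but shifted in opposite directions between groups —
can carry substantially more signal. `plspair` implements, as a tested and
reusable pipeline, the full route from expression matrices to a validated
paired-gene classifier:

1. **Differential expression** — per-gene two-sided unpaired Student
   t-test (pooled variance) of responders vs nonresponders on log2-scale
   expression, filtered by raw p-value and |log2 fold-change|.
2. **Co-expression screening** — all lncRNA × mRNA Pearson correlations
   computed *within* responders and *within* nonresponders; a pair
   survives only if significant (p < .05, t-transform with n−2 df) in both
   groups.
3. **Drug-target intersection** — the mRNA side of surviving pairs is
   intersected with a curated drug-target gene list.
4. **Network topological ranking** — a STRING-style weighted interaction
   network is filtered to edges scoring strictly above the median; nodes
   are ranked by degree, normalized betweenness and harmonic closeness
   (rank-sum composite); candidate pairs are ordered by mean absolute
   within-group correlation with topology as tie-break.
5. **PLS classification** — a single-component PLS classifier on the
   selected pair: the unit-norm weight vector

   **W** = argmax‖w‖=1 cov²(X w, Y),

   which has the closed form **W** = c/‖c‖ with c the vector of sample
   covariances between each standardized predictor and the centered ±1
   response. A sample's score is S = Σᵢ W_i · scaled(L_i); the decision
   threshold T maximizes Youden's J (sensitivity + specificity − 1) and a
   sample is called a responder exactly when S > T.
6. **Evaluation** — Mann–Whitney AUC with Hanley–McNeil SE and logit 95%
   CI, stratified fivefold cross-validation (per-fold refit of weights and
   threshold), and DeLong comparison of the paired-gene ROC against each
   single-gene ROC.

Because cohorts of this kind are rarely public, the package ships a
first-class **synthetic-cohort generator** that emulates the assumed data
structure — a planted lncRNA/mRNA pair (lncRNA up, mRNA down in
responders, correlated within class), background genes, a
preferential-attachment network with the planted genes as hubs, a target
list containing the planted mRNA, and ΔCt-based qPCR tables — so the whole
pipeline is testable end to end.

## Worked example

Simulate a 20-responder / 20-nonresponder cohort and run the whole
pipeline (the `plspair` console script and `python -m plspair` are
equivalent):

```bash
cat > sim.yaml <<EOF
n_responders: 20
n_nonresponders: 20
EOF
plspair simulate --config sim.yaml --out-dir data --seed 11

cat > run.yaml <<EOF
expr_lnc: data/expression_lncrna.tsv
expr_mrna: data/expression_mrna.tsv
labels: data/labels.tsv
targets: data/targets.txt
edges: data/edges.tsv
out_dir: out
EOF
plspair -v run-all --config run.yaml --seed 11
```

Stage log and summary (abbreviated):

```
INFO plspair: target intersection: 2 candidate pairs
INFO plspair: top pair: LNC0027/GENE0026
INFO plspair: reference RN18S: AUC 1.000, CV mean accuracy 1.000
n_de_lnc: 26
n_de_mrna: 39
n_pairs_both: 2
top_pair: [LNC0027, GENE0026]
```

The discovery arm found 26 DE lncRNAs and 39 DE mRNAs, two pairs
significant in both groups, and ranked the planted pair `LNC0027/GENE0026`
first. The prediction report (`out/prediction_report.json`) contains one
model per reference-gene normalization; with RN18S:

```
weights [0.7942, -0.6077]   threshold 0.0029
paired-gene AUC 1.000       CV mean accuracy 1.000
vs LNC0027 alone:  AUC 0.875, DeLong p = 0.024
vs GENE0026 alone: AUC 0.770, DeLong p = 0.002
```

The weights satisfy 0.7942² + 0.6077² = 1 (the unit-norm invariant), their
opposite signs recover the planted directions (lncRNA up, mRNA down in
responders), and the paired score separates the classes better than either
gene alone — the DeLong p-values quantify that gain.

Every stage is also available as its own subcommand (`de`, `pairs`,
`network`, `train`, `cv`, `evaluate`, `compare`), reading and writing
plain TSV/JSON so a run can resume from any stage's files, or
programmatically:

```python
import plspair as pp

config = pp.SimConfig(n_responders=20, n_nonresponders=20, seed=11)
lnc, mrna, labels, truth = pp.generate_cohort(config)
report = pp.discover(lnc, mrna, labels,
                     pp.generate_target_list(truth, config),
                     pp.generate_network(truth, config))
results = pp.predict_response(lnc, mrna, labels, report.top_pair,
                              reference_genes=("RN18S", "GAPDH"), seed=11)
```

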