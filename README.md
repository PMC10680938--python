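# pathformer

Disease classification and reproducible biomarker ranking from patient gene
signaling networks, with a transformer-style graph encoder.

Omics cohorts are naturally graph-structured: each patient carries
expression values on the nodes of a shared gene–gene interaction network
(KEGG / BioGRID style).  Conventional message-passing GNNs do poorly here —
signaling networks are large and dense (mean degree > 25), which
over-squashes local aggregation, and their class signal is not confined to
low-frequency graph-spectral components, which defeats architectures that
act as low-pass filters.  This package implements an architecture built for
that regime, for computational biologists who want both a competitive
classifier and a stable, knowledge-consistent gene ranking they can hand to
enrichment analysis.

## The model

Genes are globally ordered (lexicographic order function `h` on the cohort
gene universe `S`).  Three components sit on top of that order:

- **KD-Sortpool** — a trainable importance vector `λ = softplus(θ)` over
  `S` gives each sample's genes selection probabilities
  `ε(v) = λ_h(v) / Σ_{u∈Vn} λ_h(u)`; the hard top-K by `ε` is the analysed
  subset.  Selection is deliberately independent of expression values and is
  regularized toward prior gene–disease-association (GDA) knowledge via the
  gene-subset-consistency loss `Σ_{v∈Sn} ε(v)(1−e(v))`, so rankings
  reproduce across cohorts of the same disease.
- **SNPMF pathway encoding** — per gene a sparse binary vector of length
  `B·|S|` marking which universe genes lie at shortest-path distance
  `d ≤ B`, block per distance; it acts as pathway context and positional
  encoding at once.
- **PAM encoder layers** — attention whose queries/keys are computed from
  `concat(Z, P)` (two GIN layers on the subset subgraph, or MLPs), values
  from `Z` alone, followed by a feed-forward block with residual; a
  gene-order-indexed readout `z = Σ_k W_{h(v_k)} O_k` and an MLP head emit
  class probabilities.  Training minimises `CE + λ_gsc·GSC` with Adam,
  halving the learning rate every 30 epochs, early stopping on validation
  accuracy.

Interpretation utilities rank biomarkers by mean `ε`, average attention
into a population gene–gene co-effect matrix, and report subset overlap and
top-K nestedness.  A graph-spectral probe (`lowpass_profile`) tests whether
a dataset's signal survives low-frequency-only reconstruction — the
"low-pass nature" diagnostic.  A seeded synthetic-cohort generator with
planted discriminative genes makes the whole pipeline testable without
external data.

The trainable stack runs on a compact numpy reverse-mode autodiff core
(float64, fully seeded); no deep-learning framework is required.

## Worked example

Simulate a cohort (120 genes, 10 planted biomarkers with a 1.5-SD class
shift and high GDA scores, 2×30 samples), cross-validate, train, and rank:

```bash
pathformer simulate --out data --n-genes 120 --n-samples-per-class 30 \
    --mean-degree 12 --n-planted 10 --effect-size 1.5 --seed 7
pathformer cv --config cfg.yaml --out cv_out
# accuracy 0.9500 +/- 0.0408
pathformer train --config cfg.yaml --out run
# best validation accuracy: 1.0000
pathformer interpret rank --config cfg.yaml \
    --checkpoint run/checkpoint.npz --out ranking.tsv
head -6 ranking.tsv
# gene    epsilon_score   rank    gda_score
# G0056   0.008372486775  1       0.9169782136
# G0058   0.008371315847  2       0.913380783
# G0086   0.008370430643  3       0.9102245118
# G0080   0.008369812795  4       0.9082445147
# G0068   0.008368905982  5       0.9064775243
```

with `cfg.yaml`:

```yaml
data:
  expression: data/cohort_expression.tsv
  edges: data/cohort_edges.txt
  gda: data/cohort_gda.tsv
  labels: data/cohort_labels.tsv
model:
  k: 15
training:
  k: 15
  lambda_gsc: 1.0
  max_epochs: 30
  patience: 8
  batch_size: 16
  folds: 5
```

The 5-fold cross-validated accuracy is 0.95 ± 0.04 and all 10 planted genes
appear in the top-15 of the exported ranking — the classifier finds the
class signal and the knowledge-regularized selection recovers the planted
biomarkers, with their elevated GDA scores visible in the last column.

Input formats: expression is a genes × samples TSV of TPM values, edges a
two-column symbol pair list (`#` comments allowed, direction and duplicates
ignored), GDA a `gene<TAB>score` table with scores in [0,1], labels a
`sample_id<TAB>class_name` table.

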