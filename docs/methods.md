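# Methods

## Problem setting

The package classifies disease state from patient transcriptomes structured
as *gene signaling networks*: every sample in a cohort shares one undirected
interaction network (KEGG/BioGRID-style edge lists), carries TPM expression
values on its measured genes, and has a class label (e.g. AD vs control, or
a cancer type).  Two properties of this data shape the architecture:

1. **Shared connections.**  A gene appears at most once per sample network
   and an interaction between two genes holds in every sample where both are
   measured.  Every sample network is therefore the subgraph of one global
   network induced by the sample's present genes, and any encoding keyed to
   the global gene order transfers across samples.
2. **Dense, large graphs without the low-pass property.**  Curated signaling
   networks have mean degrees in the tens and thousands of nodes, and the
   class signal is not confined to low-frequency graph-spectral components
   of the expression signal (see the spectral diagnostic below).  Local
   message passing both over-squashes and low-pass filters; the encoder
   therefore uses global attention over a selected gene subset.

## Model

**Canonical gene order.**  The universe S is the union of all genes across
samples and edges, ordered by byte-wise lexicographic sort of uppercased
symbols; h(v) is a gene's rank.  All positional structures (pathway vector
blocks, readout weights, the importance vector) are indexed by h.

**KD-Sortpool.**  A trainable vector theta over S defines importances
lambda = softplus(theta) > 0; for sample n with present genes Vn the
selection probability is eps(v) = lambda_h(v) / sum_{u in Vn} lambda_h(u).
The subset Sn is the hard top-K of eps with ties broken by h.  Selection is
independent of expression by construction: group-level expression contrasts
can disagree in sign between cohorts of the same disease, so importance is
learned only through the knowledge prior (below), making subsets
reproducible across datasets.  softplus reparameterization (initialised at
softplus(theta)=1 for every gene) keeps the probabilities well-defined
without constraining the optimizer.  Because a fixed lambda induces one
global ranking, top-K subsets for increasing K are nested prefixes — the
nestedness report quantifies deviations only when models are retrained per
K.

**Gene-disease-association prior.**  e(v) in [0,1] is a DisGeNET-style GDA
score; unlisted genes score 0.  e(v) is frozen during training.  The GSC
(gene-subset consistency) loss mean_n sum_{v in Sn} eps(v)(1 - e(v)), always
in [0,1], pulls selection toward genes with prior disease evidence; the
expected subset association A(Sn) = sum eps(v) e(v) is its complement
restricted to the subset.

**SNPMF pathway encoding.**  Each gene v gets a binary vector p(v) of
length B·|S|: entry (d-1)·|S| + h(u) is 1 iff the shortest-path distance
from v to u in the sample network is exactly d (1 <= d <= B).  Genes are
marked once, at their shortest distance, which keeps popcount <= |S|-1 and
makes the B blocks interpretable as distance shells.  Two textual
ambiguities are exposed as flags and resolved as follows by default:
`strict_lt` (d < B instead of d <= B; off, because a strict bound would
leave the last block permanently empty), and `snpmf_on_subset` (compute
p(v) on the subset-induced subgraph rather than the full sample network;
off, because selection should not amputate pathway context).  Vectors are
stored sparse (CSR) and cached per gene; B defaults to 2, which on
mean-degree-25 networks already covers most of the graph per gene while
keeping the encoding length 2|S| manageable.

**Encoder layer (PAM + FFN).**  Layer input Z (K×d, d = 32 by default) and
the pathway matrix P (K×B|S|, identical at every layer) are concatenated to
drive queries and keys; values are a linear map of Z alone:

    Q = QNet(concat(Z, P)),  Kmat = KNet(concat(Z, P)),  V = Linear(Z)
    Att = Q Kmat^T / sqrt(d_qk),  V_hat = row_softmax(Att) V
    O = FFN(V_hat),   FFN = Dropout → FC(d→64) → ReLU → Dropout → FC(64→d)

with a residual connection from the tensor entering the first FC to the
block output.  QNet/KNet are either two GIN graph-convolution layers on the
subgraph induced by Sn (default, hidden/output width 32; the concatenated
input is first compressed by a linear map because message passing on
B|S|-wide features is wasteful) or 2-layer MLPs (hidden 64).  The printed
form of the attention normalisation ("softmax(exp(Att))") is treated as
notation for the standard row softmax, since softmax already exponentiates;
a `double_exp` flag reproduces the literal double exponential.  Similarly
the attention scale is sqrt(d) by default (`attn_scale="d"` divides by d
instead).  A single attention head is the default; `n_heads` splits the
feature axis when set.  There is no residual or LayerNorm around the
attention itself — the only residual is the one inside the FFN.

**First-layer features and scaling.**  Row k of the input is
concat(x(v_k), p(v_k)) — the transformed expression scalar plus the pathway
vector acting as a positional encoding — projected to width d.  Two
numerical choices matter here.  (i) p(v) rows are scaled to unit L2 norm
inside the model: raw binary vectors have norm sqrt(popcount), which on
dense networks is ~15–25 and varies per gene.  (ii) The projection's
expression row is initialised with fan-in-1 Xavier scale rather than the
block's joint fan-in.  Without these, the across-sample signal (which lives
entirely in the single expression coordinate) is orders of magnitude
smaller than the constant positional component and the classifier head
receives an essentially sample-independent input; with them, training
converges in tens of epochs.

**Readout.**  z = sum_k W_{h(v_k)} O_k with one trainable d_out×d matrix
per universe gene, stored as a single |S|×d_out×d tensor (Xavier
initialised at construction; memory is the user's K/|S| trade-off), then a
2-layer MLP head and softmax give class probabilities.  Indexing W by h(v)
rather than by subset position makes the readout invariant to subset order
and consistent across samples with different Vn.

**Expression transform.**  `expr_transform` is `none`, `log2p1`, or
`zscore` (default): log2(1+TPM) then per-gene standardisation with
statistics fit on training samples only.  Zero-variance genes are kept
(std clamped to 1); no silent gene filtering occurs anywhere.

## Training

Loss = CE + lambda_gsc · GSC.  Note the field's notation collision: the
importance vector and the loss weight are both conventionally written
lambda; here they are `lambda_imp` and `lambda_gsc`.  By default theta
receives gradients only through the GSC term (hard top-K is
non-differentiable); the optional `scale_values_by_eps` flag multiplies
first-layer features by K·eps(v) to add a Sortpool-style straight-through
signal, off by default.  Optimisation is Adam at lr 0.001 halved every 30
epochs; early stopping monitors validation accuracy (stratified 90/10 split
inside each training set, transform fit on the 90%) with strict-improvement
patience of 5 epochs by default and restores the best-validation
checkpoint.  Cross-validation is stratified K-fold (5 by default); macro-F1
accompanies accuracy because multi-class cohorts are class-imbalanced in
general.  With fixed seeds the whole harness is reproducible run-to-run on
one platform (float64 throughout).

The trainable stack runs on a small tape-based reverse-mode autodiff core
over numpy float64 arrays (`pathformer._autodiff`), sized for the dense
(batch, K, d) computations this model needs; every operation's gradient is
finite-difference tested.

## Synthetic cohorts

`synthetic.generate_cohort` emulates the cohort structure end-to-end: one
Erdos-Renyi network (topology `ba` available) shared by all samples,
TPM-like expression exp(mu + N(0, sd²)) so values are positive and the
log-scale model is exactly Gaussian, a planted gene subset carrying a
class-proportional mean shift of `effect_size`·sd on the log scale, and GDA
scores gda_planted (default 0.9) on planted vs gda_background (0.05)
elsewhere, jittered ±0.02.  All genes are present in every sample by
default; `dropout_genes` hides genes per sample to exercise the Vn ⊂ S code
path.  What the generator does *not* emulate: real KEGG topology (hubs,
modules), correlated co-expression, batch effects, or disease-specific
effect-size distributions — passing the recovery study therefore shows the
estimator and selection machinery work under the stated signal model, not
that comparable accuracy is reachable on real cohorts.

## Reference studies (scripts/acceptance.py)

Study conditions: 300 genes, mean degree 25, 2 classes × 100 samples, 20
planted genes, effect size 1.5, GDA 0.9/0.05, K = 40.  Training for these
studies uses lambda_gsc = 1 (the regime where the prior is informative and
intended to steer selection), a 60-epoch cap and patience 8 — problem sizes
and caps chosen so each study completes in minutes on one CPU.

- **Recovery**: 5-fold CV accuracy and macro-F1, plus the fraction of
  planted genes in the top-40 biomarker ranking of a model trained on the
  full cohort, with a hypergeometric enrichment p-value.
- **Null control**: the same pipeline on the label-permuted cohort; CV
  accuracy must fall in the chance band.
- **GSC effect**: mean GDA score of the selected top-40 after training with
  lambda_gsc = 0 vs 1; the difference isolates the regularizer.
- **Spectral contrast**: two node-signal cohorts on one 60-node graph
  (600 samples per class), with the class shift placed on the three lowest
  vs the three highest eigenmodes of L_sym = I − Dt^{-1/2}(A+I)Dt^{-1/2}
  (Dt = D+I; eigenvalues in [0,2]).  The 2-layer MLP probe on
  frequency-limited reconstructions saturates by fraction 0.1 in the
  low-frequency case and stays at chance until nearly the full spectrum in
  the high-frequency case.  Sample size and probe shrinkage (alpha = 1)
  were set so finite-sample spurious accuracy stays well below the
  qualitative contrast.

## Degenerate inputs and tie-breaks

Empty gene sets, empty samples, single-class training sets, classes smaller
than the fold count, out-of-range GDA scores and non-finite ranking scores
raise immediately with the violated bound named.  All order-dependent
operations (gene ranking, top-K selection, class indexing) break ties by
the canonical order h or sorted class names, so no result depends on file
row order, dict order or platform.

## Known limitations

- Attention, and hence memory, is O(K²) per sample; K in the thousands
  (e.g. selecting a whole 3000-gene network) needs blocking that is not
  implemented.
- The readout tensor is materialised for all |S| genes; for very large
  universes with small K a dict-backed lazy store would be lighter.
- GIN query/key networks run on the subset-induced subgraph; if K is small
  relative to the network the induced subgraph can be edgeless, in which
  case GIN reduces to an MLP of its own input.
- The co-effect matrix averages attention over contributing (sample, layer)
  pairs; with highly variable per-sample subsets, coverage counts must be
  consulted before interpreting rarely co-selected pairs.
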