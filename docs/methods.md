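# Methods

## Model

Each gene in an undirected PPI graph carries a 64-dimensional feature
vector (4 omics blocks × 16 cancer types, assumed normalized by the data
producer). Two branches transform the whole graph in parallel from the raw
features:

**GCN branch.** Three spectral convolution layers with the renormalized
propagation rule `σ(D̃^(-1/2)(A+I)D̃^(-1/2) H W)`, widths
`d_in → 300 → 100 → 16`. Self-loops from `A + I` guarantee every degree is
at least 1, so the normalization is always defined, including for isolated
nodes. Hidden activations are ReLU; the final 16-dimensional embedding
layer is linear. No bias terms — the propagation rule has none.

**GAT branch.** One hidden attention layer (5 heads, 100 units per head,
outputs concatenated to 500, ELU) followed by one output head (16 units,
linear). Attention logits use LeakyReLU with negative slope 0.2; each
node's neighbourhood includes the node itself, so softmax normalization is
always over a non-empty set. The attention vector `a` of length 2F′ is
stored as its two halves (one applied to the central node, one to the
neighbour), which is algebraically identical to the concatenated form and
evaluates in O(E) per head. Multi-head outputs are concatenated in the
hidden layer and averaged in the output layer — the canonical convention
for a 5-head hidden / 1-head output configuration; the averaged form is
the one the output-layer equation prescribes, and with a single output
head the two coincide.

**Head.** The two 16-dimensional embeddings are concatenated (GCN block
first) and classified by an MLP `32 → 16 → 1` (ReLU hidden, logistic
output, biases included). Single-branch ablation variants (`branch="gcn"`
or `"gat"`) feed one 16-dimensional embedding directly to the MLP.

The choice of linear embedding outputs and ReLU/ELU hidden activations is
ours; only the LeakyReLU inside the attention logit is pinned by the layer
definition, and the defaults of the two layer families are used elsewhere.

## Training

The loss is a class-weighted binary cross-entropy over the labeled nodes of
the current split, with positive-class weight
`c = round_half_up(n_neg / n_pos)` computed from the labeled set (for the
benchmark counts 796/2187 this gives c = 3). The forward pass always runs
over the full graph; unlabeled genes receive probabilities but contribute
no gradient. Internally the loss is evaluated in the logits via
`softplus`, which is exactly the clipped-probability form but immune to
saturation.

Optimization is Adam (lr 1e-3, L2 weight decay 5e-4 folded into the
gradient), dropout 0.5 applied to the input of every learned layer during
training only, at most 2000 epochs. Early stopping monitors the loss on a
validation set (10% of the train portion, stratified) and stops after 100
epochs without improvement (`patience`), restoring the best-validation
parameters. A non-finite training loss raises an error naming the epoch.

Cross-validation defaults to ten seeded repeats of a stratified 75/25
train/test split of the labeled nodes (Monte-Carlo CV); a classic
stratified 10-fold partition is available via `cv_scheme="kfold"`. Both
interpretations of "ten-fold CV with a 75/25 split" are defensible; the
repeated-split reading reproduces both stated fractions simultaneously, so
it is the default. Gene rankings use the fold-averaged probabilities
rather than a single refit model, trading a small bias for variance
reduction. Weight initialization is Glorot-uniform; one run seed
deterministically derives the split seeds, per-fold initialization seeds
and dropout streams, so identical inputs give bit-identical results on one
platform.

All tensor computations run on a small reverse-mode autodiff core over
NumPy (`monet.autodiff`): dense/sparse matmul, broadcasting arithmetic,
the activations above, and gather/scatter/segment-softmax primitives that
express per-edge attention without materializing an N×N matrix. Every
primitive is verified against central finite differences in the tests.

## Metrics

Accuracy, F1 and the Matthews correlation coefficient are computed from
the confusion counts at threshold 0.5 (a logistic output is symmetric, and
no other threshold is distinguished); degenerate denominators yield 0 by
the usual convention. AUROC uses the rank/trapezoid convention (equal to
the normalized Mann–Whitney U, tested against an exhaustive pairwise
oracle); AUPR is the step-wise non-interpolated area (average precision).
ROC's false positive rate is FP/(FP+TN) — the textbook definition; a
variant form FP/(TP+FP) that circulates as a misprint is the false
discovery rate and cannot produce a ROC curve, so it is not implemented.

## Consensus calling

Per network, genes are ranked by fold-averaged probability (stable sort,
lexicographic tie-break). The top K = 300 of each ranking are candidate
genes; genes present in at least m = 2 top-K lists are consensus
candidates, annotated as *known* (in the positive catalog) or *novel*.
Known positives are deliberately not removed before the cut — the
candidate set is expected to contain them, and the known fraction is a
useful calibration signal. Ties exactly at the K boundary are resolved by
the deterministic ranking order (fixed output size) and logged.

## Synthetic scenarios

The generator emulates the two signal channels the model consumes and
nothing else:

- **Topology**: a planted-community graph — driver–driver pairs connect
  with probability `p_in`, all other pairs with `p_out`. Further networks
  in the ensemble resample a fraction (default 0.2) of the base edges,
  giving correlated but distinct graphs with a shared gene universe.
- **Features**: i.i.d. standard-normal 64-column grid; driver rows are
  mean-shifted by a per-omics-block effect size in SD units (default 1.5
  on MF and GE, 0 elsewhere).
- **Labels**: positives sampled from the planted drivers (default half of
  them), negatives from the background at a 3:1 neg:pos ratio, mirroring
  the benchmark imbalance that motivates c = 3.

The reference scenario is 600 genes, 60 drivers, `p_in=0.05`,
`p_out=0.005`, six networks. It deliberately omits properties of real PPI
data — scale-free degree distributions, correlated omics blocks,
cancer-type-specific effects, label noise — so passing tests demonstrate
that the implementation recovers signal it is designed for and stays at
chance without it, not that the method's biological performance
transfers.

## Problem sizes in the test and acceptance runs

Scenario-scale runs use 2–3 CV repeats, at most 200 epochs and patience
25 — on these graph sizes validation loss plateaus well before 100 epochs,
so the larger default budget adds nothing. Signal recovery is measured
over 3 seeds on all six networks; the ensemble comparison (concatenated vs
single-branch) over 5 seeds on the base network; the null control over 3
seeds plus one full six-network consensus pass. The separable-clique
fixture runs under the full default protocol (10 repeats, 2000-epoch cap).
Generator parameters are never reduced.

## Known limitations

- Neighborhood aggregation carries a degree bias: a low-degree gene whose
  few neighbours are drivers inherits a driver-like embedding (its hub
  neighbour contributes weight ~1/√(2(d+1)) against a 1/2 self-weight),
  while a well-connected true driver has its own features down-weighted.
  On planted-community scenarios this caps top-K ranking precision at
  roughly 0.83 per network even when held-out AUROC is ≥ 0.99, and the
  surviving false candidates recur across correlated networks, so
  min-support consensus filters them only partially. Both graph branches
  and their concatenation show the effect; it is a property of the model
  family, not of the training budget.
- CPU-only, dense-ish linear algebra: suitable for graphs up to a few
  thousand nodes; real PPI networks (~15k genes, ~300k edges) train slowly
  though correctly.
- Edge confidence scores are used only for filtering (strict ">"
  threshold), never as weights in propagation.
- No gene-symbol alias resolution; identifiers are matched case-sensitively.
- Genes missing from the feature table are zero-imputed (neutral under
  z-scoring) with a logged warning; how missing omics should really be
  handled is data-dependent and out of scope.
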