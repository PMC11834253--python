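# monet-driver

Semi-supervised identification of cancer driver genes from protein–protein
interaction (PPI) networks and pan-cancer multi-omics features.

## The problem and the method

Driver genes carry mutations that give tumor cells a selective growth
advantage, but labeled examples are scarce: a few hundred confirmed drivers
(positives) and a curated set of non-drivers (negatives) against ~10,000
unlabeled genes. This package classifies every gene in a PPI graph by
combining two complementary graph representations of the same data:

- a **graph convolutional network (GCN)** propagating node features through
  the symmetrically normalized adjacency
  `H^(l+1) = σ(D̃^(-1/2) Ã D̃^(-1/2) H^(l) W^(l))` with `Ã = A + I`,
  capturing global graph structure;
- a **graph attention network (GAT)** with multi-head softmax attention:
  per-edge logits `e_ij = LeakyReLU(aᵀ[W h_i ‖ W h_j])`, neighbourhood
  weights `α_ij = softmax_j(e_ij)`, aggregated over K heads, capturing the
  varying importance of local neighbours.

Each branch produces a 16-dimensional embedding per gene; their
concatenation (the 32-dimensional *graph-enhanced feature*) is classified
by an MLP with a logistic output. Training minimizes a class-weighted
binary cross-entropy `L = −(c·y·log σ(x) + (1−y)·log(1−σ(x)))` on the
labeled genes only, where `c = round(n_neg / n_pos)` offsets the ~1:3 class
imbalance. The per-gene probabilities rank all genes; the top K (=300)
genes per network, intersected across networks (support ≥ m = 2), are the
consensus candidate driver genes.

Node features are a 64-column grid: 4 omics types (somatic mutation
frequency MF, DNA methylation METH, gene expression GE, copy-number
alteration CNA) × 16 TCGA cancer types.

The neural layers, backpropagation and Adam are implemented in NumPy on a
small reverse-mode autodiff core (`monet.autodiff`), gradient-checked
against finite differences in the test suite.

## Worked example

Generate a synthetic six-network scenario with 600 genes, 60 planted
drivers and a 1.5-SD feature shift on the MF and GE blocks, train on the
first network, and call consensus candidates:

```bash
monet simulate --out scenario --seed 1
printf 'cv_folds: 2\nmax_epochs: 200\npatience: 25\n' > fast.yaml
for k in 0 1 2 3 4 5; do
  monet train --network scenario/synthetic_net_$k.edges.tsv \
      --features scenario/features.tsv \
      --positives scenario/positives.txt \
      --negatives scenario/negatives.txt \
      --config fast.yaml --seed 1 --out run_$k
done
monet consensus run_*/probabilities.tsv -k 60 -m 2 \
    --positives scenario/positives.txt --out calls
```

`monet train` logs per fold, e.g.

```
INFO monet.training: fold 0: AUROC=0.9702 AUPR=0.9519 (77 epochs)
INFO monet.training: fold 1: AUROC=0.9091 AUPR=0.7191 (105 epochs)
INFO monet.cli: mean AUROC 0.9397, AUPR 0.8355 over 2 folds
```

meaning the held-out labeled genes of that network are ranked almost
perfectly (AUROC ≈ 0.94 on this network; ~0.98 averaged over the six). `calls/candidates.tsv` lists each consensus
candidate with its support count (networks whose top-60 contains it), mean
probability, and whether it is already a known positive; with the planted
signal above, the large majority of candidates are planted drivers.

The same pipeline runs from Python:

```python
from monet import (SyntheticConfig, generate_network_ensemble,
                   generate_features, generate_labels, assemble_dataset,
                   ModelConfig, run_cross_validation)

cfg = SyntheticConfig(seed=1)
nets = generate_network_ensemble(cfg)
ds = assemble_dataset(nets[0], generate_features(cfg), generate_labels(cfg))
report = run_cross_validation(ds, ModelConfig(cv_folds=2, max_epochs=200,
                                              patience=25, seed=1))
print(report.metrics_mean)
# {'ACC': 0.7667, 'AUROC': 0.9555, 'AUPR': 0.8931, 'F1': 0.6682, 'MCC': 0.5682}
```

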