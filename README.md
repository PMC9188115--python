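# hierat

Contrastive refinement of protein embeddings on the CATH structural
hierarchy, and embedding-based annotation transfer (EAT).

## What it does, and for whom

Protein language models turn sequences into fixed-length embedding
vectors that carry structural signal. For structural bioinformaticians
who want to classify protein domains into the CATH hierarchy — Class,
Architecture, Topology, Homologous superfamily — even when sequence
similarity is undetectable, `hierat` learns a small projection head that
reorganises those embeddings so Euclidean distance tracks the hierarchy,
then annotates queries by transferring the label of the nearest labelled
lookup protein.

The core is contrastive metric learning on triplets. A two-layer network
`z = W2·tanh(W1·x + b1) + b2` (D → 256 → 128) is trained with the
soft-margin triplet loss

    L = (1/T) Σ_t log(1 + exp(−d_t)),   d_t = ‖z_a − z_n‖ − ‖z_a − z_p‖,

where positives/negatives are drawn by *hierarchy sampling* — a random
level α ∈ {1..4} defines the positive (shares the anchor's label through
level α) and the negative (diverges exactly at α) — and mini-batches are
re-wired by *batch-hard mining*: at every level, each anchor is paired
with its farthest eligible positive and nearest eligible negative in the
current learned space, expanding a nominal batch of 256 anchors to at
most 256 × 3 × 4 = 3072 member slots. One network learns all four levels
simultaneously. Inference is nearest-neighbour transfer with an optional
reliability threshold θ on the hit distance (coverage vs accuracy
trade-off), plus per-level accuracy / coverage / multiclass MCC with
bootstrapped 95% CIs, and intra-superfamily outlier detection that flags
potential mislabels.

Everything runs on CPU from plain numpy/scipy; no deep-learning
framework, no network access and no real CATH data are needed — a
synthetic generator plants nested hierarchical cluster structure for
development and testing.

## Worked example

```python
import hierat as h

# a dataset with planted hierarchy: 81 superfamilies x 6 members,
# 64 signal dimensions diluted by 192 pure-noise dimensions
ds = h.generate(h.recovery_regime(), seed=1)
train_ids, val_ids, _ = h.split(ds, (0.9, 0.1, 0.0), seed=1)

model = h.ContrastiveHierarchyModel(
    ds.subset(train_ids), ds.subset(val_ids),
    config=h.TrainConfig(seed=1, max_epochs=30, patience=10))
res = model.fit()
print(res.summary())
```

```
Contrastive hierarchy projection — fit summary
====================================================
train proteins:        437
validation proteins:   49
input dim:             256
projection:            256 -> 256 -> 128
optimizer:             Adam(lr=0.001)
batch size:            256 (effective member bound 3072)
hierarchy sampling:    on
batch-hard mining:     on
epochs run:            18 (max 30, patience 10)
best epoch:            8
first/last mean loss:  0.6822 / 0.1183
best val accuracy:     C=1.000, A=1.000, T=1.000, H=0.776
```

The mean triplet loss falls from 0.68 (≈ ln 2, the value for an
uninformative space) to 0.12, and training stops at the epoch with the
best validation accuracy at the homologous-superfamily (H) level.
Leave-one-out annotation transfer over the full dataset shows what the
projection bought — the coarse levels are easy either way, but at the
superfamily level the noise-diluted raw space tops out at 70% while the
learned space reaches 97%:

```python
from hierat.experiments import loo_accuracies
print(loo_accuracies(ds))               # raw embedding space
print(loo_accuracies(ds, res.network))  # learned space
```

```
{'C': 1.0, 'A': 1.0, 'T': 1.0, 'H': 0.695}
{'C': 1.0, 'A': 1.0, 'T': 1.0, 'H': 0.973}
```

The same pipeline is scriptable from the shell:

```bash
hierat synth --out data.h5 --labels data.tsv --seed 7 --dim 64
hierat train --embeddings data.h5 --labels data.tsv --out head.npz --seed 7
hierat eat   --query data.h5 --lookup data.h5 --lookup-labels data.tsv \
             --model head.npz --threshold 1.1 --out hits.tsv
hierat eval  --hits hits.tsv --truth data.tsv --lookup-labels data.tsv \
             --out report.json
```

See `docs/methods.md` for the model, sampling schemes, metrics and the
synthetic data's scope.

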