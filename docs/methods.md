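# Methods

## The problem

Remote homology detection in the "midnight zone" — pairwise sequence
identity so low that alignment-based search fails — can be recast as
nearest-neighbour search in a learned embedding space. `hierat` starts
from fixed per-protein embeddings produced upstream by a protein language
model (the package never runs one; embeddings arrive in an HDF5
container, one dataset per protein id, optionally as L×D per-residue
matrices that are mean-pooled over length). It then learns a projection
of those embeddings into a space organised by the CATH hierarchy — Class,
Architecture, Topology, Homologous superfamily — so that proteins
agreeing at deeper levels of the classification lie closer together.
Annotations are transferred to unlabelled queries from the nearest
labelled lookup protein (embedding-based annotation transfer, EAT), in
direct analogy with homology-based inference.

## Model

A two-layer feed-forward head with hard parameter sharing across triplet
members:

    z = W2 · tanh(W1 · x + b1) + b2,    x ∈ R^D → z ∈ R^128

Defaults: hidden 256, output 128, tanh between the layers only. The
output layer is affine and unnormalised — learned-space distances are
unbounded, which the reliability thresholding (below) relies on. Deeper
variants are configurable but default off; for inputs of this quality a
small head suffices, and extra parameters bought nothing in our smoke
experiments. Biases are included in both layers. Initialisation is
uniform fan-in scaling, U(−1/√fan_in, 1/√fan_in), from the run seed.

The head is trained with the soft-margin triplet loss

    L = (1/T) Σ_t log(1 + exp(−d_t)),
    d_t = ‖z_a − z_n‖₂ − ‖z_a − z_p‖₂

implemented via the numerically stable softplus (`logaddexp`). A positive
margin means the negative is already farther than the positive. The
implementation is plain numpy with hand-written backprop and Adam
(lr 1e-3, β = 0.9/0.999, ε = 1e-8); the model is two small matrices, and
the exact gradients are verified against central finite differences in
the test-suite (rel. tol 1e-4).

## Triplet construction

**Hierarchy sampling.** For every training protein used once as anchor
per epoch, a level α ∈ {1,2,3,4} is drawn uniformly. Positives share the
anchor's label down to level α (shared prefix depth ≥ α); negatives
diverge exactly at α (shared depth = α − 1) — never coarser, so triplets
are semi-hard by construction: the negative always shares the first
α − 1 levels. If the drawn α admits no (positive, negative) pair, α is
redrawn *without replacement* among the untried values (at most 4
attempts — this terminates with the same distribution over satisfiable α
as unbounded redrawing, which is why we chose it). Self-hits are excluded
by id, not by label. Anchors with no valid pair at any α are skipped and
counted.

**Batch-hard re-wiring.** The epoch's triplet stream is chunked into
mini-batches of `batch_size` (default 256) triplets; the batch member set
is the union of their anchors, positives and negatives. Within each
batch, and at every level i ∈ {1..4}, each member acts as anchor and is
re-wired to its hardest eligible positive (maximum Euclidean distance in
the *current* learned space — distances are computed on the projection
outputs refreshed each forward pass, not on raw inputs) and hardest
eligible negative (minimum distance). An (anchor, level) pair is emitted
only when both partners exist, so a nominal batch of 256 anchors expands
to at most 256 × 3 × 4 = 3072 member slots. Distance ties break to the
lexicographically smallest candidate id, making the miner deterministic
and order-invariant. Mining is restricted to within-batch deliberately:
global hard mining would keep resurfacing outliers.

Both components have ablation switches (`hierarchy`, `batch_hard` in
`TrainConfig`); disabling hierarchy sampling falls back to uniform
same-superfamily positives and uniform any-other-label negatives, and
disabling batch-hard trains directly on the sampled triplets.

## Training and early stopping

One Adam step per (re-wired) batch, fixed learning rate, no schedule.
After each epoch the model is scored by EAT accuracy of a held-out
validation set against a lookup set (by default the training set itself),
at the homologous-superfamily level — the finest, hardest level; all four
levels are logged. The best-by-validation parameters are returned.
Patience defaults to 20 epochs (epochs are cheap for this model size; the
stopping criterion itself, not the patience, is what matters). Validation
queries whose label is unachievable in the lookup at a level are excluded
from that level's metric so the criterion stays well-defined on small
sets. A single run seed fans out to named substreams (initialisation,
per-epoch sampling), so two runs with the same config and seed produce
bit-identical histories.

## Inference, thresholding, outliers

EAT transfers the full 4-level annotation of the nearest lookup protein
(Euclidean distance, exhaustive scan — datasets at the intended scale do
not need an index; ties break to the smallest id). An optional
reliability threshold θ withholds transfers whose nearest hit is farther
than θ: such queries count against coverage but not accuracy. Coverage is
monotone non-decreasing in θ by construction, and θ = ∞ reproduces
unthresholded behaviour exactly. Threshold selection is left to the user;
the natural procedure is to sweep θ over the empirical distance quantiles
and read off the accuracy/coverage trade-off.

Outlier detection scans all same-superfamily pairs for the k largest
embedding distances (default k = 5). Within a flagged pair the *suspect*
is the member with the larger mean distance to the rest of its
superfamily; its global nearest neighbour (self excluded) is reported as
the suggested alternative annotation, to be confirmed or rejected by
curation.

## Evaluation

Correctness is hierarchical: a transfer is correct at level L iff the
shared prefix depth between truth and prediction is ≥ L, so per-level
accuracies nest (never increase from C to H) in the absence of
exclusions. A query whose true label has no same-level partner in the
lookup is excluded at that level — denominators legitimately differ
across levels. The multiclass Matthews correlation coefficient is
computed from the per-level confusion matrix over observed label
prefixes,

    MCC = (c·s − Σ_k p_k t_k) / sqrt((s² − Σ p_k²)(s² − Σ t_k²)),

with the convention MCC = 0 when either factor under the root vanishes
(constant predictions); missing predictions occupy a dedicated class that
can never be correct. 95% confidence intervals are 1.96 × the bootstrap
standard error over 1000 query-level resamples (resampling queries, not
pairs, since the replicate unit is the test set). The summary's "mean"
column is the arithmetic mean of the four per-level accuracies.

## Synthetic data

The generator plants the geometry the hierarchy implies: a nested
Gaussian tree. Per class a centre is drawn at offset scale σ₁, then
per-architecture (σ₂), per-topology (σ₃) and per-superfamily (σ₄) offsets
with σ₁ > σ₂ > σ₃ > σ₄, and each member is its superfamily centre plus
isotropic noise. Defaults: branching 3×3×3×3 (81 superfamilies), 6
members each (486 proteins), 64 dimensions, scales (8, 4, 2, 1), noise
0.5 — comfortably separated clusters whose mean pairwise distances order
strictly by shared depth. Optional `nuisance_dims` append unit-variance
pure-noise coordinates.

What the generator does *not* emulate: anisotropic embedding geometry,
heavy-tailed family sizes, label noise (except via `planted_outlier`,
which swaps one member's vector into another superfamily's cluster while
keeping its label), or any sequence-level redundancy structure. Passing
tests on this data shows the machinery is correct and that hierarchical
signal is recoverable when present; it does not certify accuracy levels
on real embeddings.

**The diluted-signal (recovery) regime.** `recovery_regime()` is the
study condition for the signal-boost and ablation experiments: 64 signal
dimensions with level scales (4, 2, 1, 0.5) plus 192 unit-variance
nuisance dimensions. The scales are chosen so the per-dimension hierarchy
signal is comparable to the nuisance variance — with the default scales
the planted signal is so strong that no realistic number of unit-variance
noise coordinates degrades raw nearest-neighbour transfer, leaving
nothing for training to recover. In this regime raw leave-one-out
superfamily accuracy sits around 0.70 while the trained head reaches
≈ 0.97, and the scale-free superfamily separation (below) roughly
doubles.

**Separation measure.** Distance separations are compared across spaces
as (mean inter-superfamily − mean intra-superfamily) / mean overall
pairwise distance. The normalisation is deliberate: the raw input space
and the learned 128-d space have unrelated distance units, so the
absolute difference is not comparable between them, while the normalised
quantity captures exactly the "distributions pull apart" property of
interest.

**Splits.** `split()` holds out at most one member per superfamily for
validation/test, and a superfamily contributes to at most one of the two
— the desk-scale analogue of the redundancy constraints real evaluation
sets impose.

## Problem sizes and determinism

The reference experiments (`hierat.experiments`) train on the 486-protein
recovery regime, 90/10 train/validation split, max 30 epochs with
patience 10, three seeds per variant — chosen as the smallest setting
where the qualitative effects are stable across seeds. All stochastic
components (generation, splits, sampling, initialisation, bootstrap)
derive from explicit integer seeds; repeated runs are bit-identical.

## Known limitations

* Accuracy/MCC exclusions recompute achievability per level with a linear
  scan; fine at desk scale, quadratic-ish for very large lookups.
* The checkpoint format is a plain `.npz` with an embedded JSON header;
  it stores the head only, never the upstream embedder.
* No approximate nearest-neighbour index and no k>1 neighbour voting —
  transfer is always from the single closest hit.
* Cosine distance is not offered; the learned space is optimised for, and
  queried with, Euclidean distance.
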