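"""Training loop: optimise the projection head on triplet streams.

Each epoch hierarchy-samples one triplet per training protein, chunks the
stream into mini-batches, re-wires each batch with batch-hard mining in
the *current* learned space, and takes one Adam step per batch on the
soft-margin loss.  Early stopping monitors annotation-transfer accuracy
at the homologous-superfamily (H) level of a validation set against a
lookup set, and the best-by-validation parameters are returned.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np

from . import eat, evaluation
from .hierarchy import LEVEL_NAMES
from .network import (Adam, ProjectionConfig, ProjectionNetwork,
                      soft_margin_loss, soft_margin_loss_grad)
from .sampling import batch_hard_rewire, build_epoch
from .store import LabelledDataset


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 256
    max_epochs: int = 100
    patience: int = 20
    hidden_dim: int = 256
    output_dim: int = 128
    seed: int = 0
    hierarchy: bool = True    # ablation: alpha-stratified triplet sampling
    batch_hard: bool = True   # ablation: within-batch hard mining

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class EpochRecord:
    epoch: int
    mean_loss: float
    n_triplets: int
    n_skipped: int
    max_effective_members: int
    val_accuracy: dict[str, float | None]
    seconds: float


@dataclass
class TrainHistory:
    records: list[EpochRecord] = field(default_factory=list)
    best_epoch: int | None = None

    @property
    def losses(self) -> list[float]:
        return [r.mean_loss for r in self.records]


def evaluate_checkpoint(model: ProjectionNetwork | None,
                        val_set: LabelledDataset,
                        lookup: LabelledDataset) -> dict[str, float | None]:
    """Per-level transfer accuracy of ``val_set`` against ``lookup``.

    Shared by early stopping and final reporting; queries whose label is
    unachievable in the lookup at a level are excluded at that level.
    ``model=None`` evaluates the raw input space.
    """
    if len(val_set) == 0:
        raise ValueError("empty validation set")
    results = eat.transfer(val_set, lookup, model=model, exclude_self=True)
    out: dict[str, float | None] = {}
    for lvl, name in enumerate(LEVEL_NAMES, start=1):
        acc, _, _ = evaluation.accuracy(results, val_set.labels, lookup.labels,
                                        lvl, exclude_self=True)
        out[name] = acc
    return out


def _epoch_step(net: ProjectionNetwork, optimizer: Adam,
                train_set: LabelledDataset, rng: np.random.Generator,
                cfg: TrainConfig) -> tuple[float, int, int, int]:
    """Run one epoch; returns (mean loss, n triplets, n skipped, max members)."""
    triplets, n_skipped = build_epoch(train_set, rng, hierarchy=cfg.hierarchy)
    if not triplets:
        raise ValueError("degenerate training set: no valid triplets exist")
    labels = train_set.labels
    store = train_set.store
    losses: list[float] = []
    weights: list[int] = []
    max_members = 0

    for start in range(0, len(triplets), cfg.batch_size):
        chunk = triplets[start:start + cfg.batch_size]
        member_ids: list[str] = []
        seen: set[str] = set()
        for t in chunk:
            for pid in (t.anchor_id, t.positive_id, t.negative_id):
                if pid not in seen:
                    seen.add(pid)
                    member_ids.append(pid)
        idx_of = {pid: i for i, pid in enumerate(member_ids)}
        x = np.asarray(store.matrix[[store.index(p) for p in member_ids]],
                       dtype=np.float64)
        z, h = net._forward(x)

        if cfg.batch_hard:
            rb = batch_hard_rewire(member_ids, z, [labels[p] for p in member_ids])
            trip_idx = [(idx_of[a], idx_of[p], idx_of[n]) for a, p, n, _ in rb.triplets]
            max_members = max(max_members, 3 * len(rb.triplets))
        else:
            trip_idx = [(idx_of[t.anchor_id], idx_of[t.positive_id],
                         idx_of[t.negative_id]) for t in chunk]
            max_members = max(max_members, 3 * len(trip_idx))
        if not trip_idx:
            continue
        ai = np.array([t[0] for t in trip_idx])
        pi = np.array([t[1] for t in trip_idx])
        ni = np.array([t[2] for t in trip_idx])

        dan_vec = z[ai] - z[ni]
        dap_vec = z[ai] - z[pi]
        dan = np.linalg.norm(dan_vec, axis=1)
        dap = np.linalg.norm(dap_vec, axis=1)
        d = dan - dap
        losses.append(soft_margin_loss(d))
        weights.append(d.size)

        g = soft_margin_loss_grad(d)
        eps = 1e-12
        u_an = dan_vec / np.maximum(dan, eps)[:, None]
        u_ap = dap_vec / np.maximum(dap, eps)[:, None]
        dz = np.zeros_like(z)
        np.add.at(dz, ai, g[:, None] * (u_an - u_ap))
        np.add.at(dz, ni, -g[:, None] * u_an)
        np.add.at(dz, pi, g[:, None] * u_ap)

        grads = net._backward(x, h, dz)
        optimizer.step(net.params, grads)

    mean_loss = float(np.average(losses, weights=weights)) if losses else float("nan")
    return mean_loss, len(triplets), n_skipped, max_members


def train(train_set: LabelledDataset,
          val_set: LabelledDataset,
          lookup_for_val: LabelledDataset | None = None,
          cfg: TrainConfig = TrainConfig()
          ) -> tuple[ProjectionNetwork, TrainHistory]:
    """Fit the projection head; return the best-by-validation checkpoint.

    ``lookup_for_val`` is the annotation source during early stopping
    (defaults to the training set itself, the usual convention when the
    training set doubles as the reference collection).
    """
    if lookup_for_val is None:
        lookup_for_val = train_set
    overlap = set(train_set.ids) & set(val_set.ids)
    if overlap:
        raise ValueError(f"train/val id sets overlap: {sorted(overlap)[:5]}")

    net = ProjectionNetwork(
        ProjectionConfig(train_set.store.dim, cfg.hidden_dim, cfg.output_dim),
        rng=np.random.default_rng([cfg.seed, 0]),
    )
    optimizer = Adam(net.params, lr=cfg.learning_rate)
    history = TrainHistory()
    best_metric: float | None = None
    best_params = net.copy_params()
    bad_epochs = 0

    for epoch in range(1, cfg.max_epochs + 1):
        t0 = time.perf_counter()
        rng = np.random.default_rng([cfg.seed, 1, epoch])
        mean_loss, n_trip, n_skip, max_members = _epoch_step(
            net, optimizer, train_set, rng, cfg)
        val_acc = evaluate_checkpoint(net, val_set, lookup_for_val)
        history.records.append(EpochRecord(
            epoch=epoch, mean_loss=mean_loss, n_triplets=n_trip,
            n_skipped=n_skip, max_effective_members=max_members,
            val_accuracy=val_acc, seconds=time.perf_counter() - t0))

        metric = val_acc["H"]
        if best_metric is None or (metric is not None and
                                   (best_metric == -np.inf or metric > best_metric)):
            best_metric = metric if metric is not None else -np.inf
            best_params = net.copy_params()
            history.best_epoch = epoch
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= cfg.patience:
                break

    net.set_params(best_params)
    return net, history
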