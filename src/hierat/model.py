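"""Model/Results facade over the contrastive-learning pipeline.

`ContrastiveHierarchyModel` bundles the data (a labelled embedding
dataset, an optional validation split) with the training configuration;
``fit()`` runs the contrastive optimisation and returns a
`ContrastiveHierarchyResults` carrying the fitted projection head, the
training history, and the downstream operations — projecting new
embeddings, annotation transfer, full evaluation and outlier detection.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import numpy as np

from . import eat, evaluation
from .hierarchy import read_label_table
from .network import ProjectionNetwork
from .store import EmbeddingStore, LabelledDataset, join, read_store
from .synthetic import split as _split
from .training import TrainConfig, TrainHistory, evaluate_checkpoint, train


class ContrastiveHierarchyModel:
    """Contrastive refinement of protein embeddings on a 4-level hierarchy.

    Parameters
    ----------
    train_set:
        Labelled embeddings used for triplet sampling (and, by default, as
        the lookup set during early stopping).
    val_set:
        Held-out labelled embeddings monitored for early stopping.  When
        omitted, one member from each of ~10% of the superfamilies is
        carved out of ``train_set``.
    config:
        :class:`~hierat.training.TrainConfig`; defaults follow the method's
        published settings (Adam, learning rate 1e-3, batch size 256,
        hidden 256, output 128).
    """

    def __init__(self,
                 train_set: LabelledDataset,
                 val_set: LabelledDataset | None = None,
                 lookup_for_val: LabelledDataset | None = None,
                 config: TrainConfig | None = None):
        self.config = config or TrainConfig()
        if val_set is None:
            train_ids, val_ids, _ = _split(train_set, (0.9, 0.1, 0.0),
                                           seed=self.config.seed)
            val_set = train_set.subset(val_ids)
            train_set = train_set.subset(train_ids)
        self.train_set = train_set
        self.val_set = val_set
        self.lookup_for_val = lookup_for_val or train_set

    @classmethod
    def from_files(cls, embeddings_path, labels_path,
                   val_ids_path=None, config: TrainConfig | None = None,
                   pool: str | None = None) -> "ContrastiveHierarchyModel":
        """Build from an HDF5 embedding container and a TSV label table."""
        store = read_store(embeddings_path, pool=pool)
        labels = read_label_table(labels_path)
        dataset, _ = join(store, labels)
        val_set = None
        train_set = dataset
        if val_ids_path is not None:
            val_ids = [line.strip() for line in
                       Path(val_ids_path).read_text().splitlines() if line.strip()]
            train_ids = [pid for pid in dataset.ids if pid not in set(val_ids)]
            val_set = dataset.subset(val_ids)
            train_set = dataset.subset(train_ids)
        return cls(train_set, val_set, config=config)

    def fit(self, **overrides) -> "ContrastiveHierarchyResults":
        """Train the projection head; keyword overrides patch the config
        (e.g. ``fit(max_epochs=30, seed=3)``)."""
        cfg = replace(self.config, **overrides) if overrides else self.config
        network, history = train(self.train_set, self.val_set,
                                 self.lookup_for_val, cfg)
        return ContrastiveHierarchyResults(self, network, history, cfg)


class ContrastiveHierarchyResults:
    """Fitted projection head plus its training history and diagnostics."""

    def __init__(self, model: ContrastiveHierarchyModel,
                 network: ProjectionNetwork, history: TrainHistory,
                 config: TrainConfig):
        self.model = model
        self.network = network
        self.history = history
        self.config = config

    # --- downstream operations -------------------------------------------

    def project(self, data: EmbeddingStore | LabelledDataset | np.ndarray) -> np.ndarray:
        """Map embeddings into the learned space."""
        if isinstance(data, (EmbeddingStore, LabelledDataset)):
            return eat.embed(data, self.network)
        return self.network.project(np.asarray(data))

    def transfer(self, queries, lookup: LabelledDataset,
                 theta: float | None = None,
                 exclude_self: bool = False) -> list[eat.TransferResult]:
        return eat.transfer(queries, lookup, model=self.network,
                            theta=theta, exclude_self=exclude_self)

    def evaluate(self, queries: LabelledDataset, lookup: LabelledDataset,
                 theta: float | None = None, n_boot: int = 1000,
                 seed: int = 0, exclude_self: bool = False
                 ) -> evaluation.EvalReport:
        results = self.transfer(queries, lookup, theta=theta,
                                exclude_self=exclude_self)
        return evaluation.evaluate(results, queries.labels, lookup.labels,
                                   theta=theta, n_boot=n_boot, seed=seed,
                                   exclude_self=exclude_self)

    def detect_outliers(self, dataset: LabelledDataset | None = None,
                        k: int = 5) -> list[eat.OutlierRecord]:
        return eat.detect_outliers(dataset or self.model.train_set,
                                   model=self.network, k=k)

    def validation_accuracy(self) -> dict[str, float | None]:
        return evaluate_checkpoint(self.network, self.model.val_set,
                                   self.model.lookup_for_val)

    # --- reporting ---------------------------------------------------------

    def summary(self) -> str:
        cfg = self.config
        h = self.history
        best = h.best_epoch
        best_rec = next((r for r in h.records if r.epoch == best), None)
        lines = [
            "Contrastive hierarchy projection — fit summary",
            "=" * 52,
            f"train proteins:        {len(self.model.train_set)}",
            f"validation proteins:   {len(self.model.val_set)}",
            f"input dim:             {self.network.config.input_dim}",
            f"projection:            {self.network.config.input_dim} -> "
            f"{cfg.hidden_dim} -> {cfg.output_dim}",
            f"optimizer:             Adam(lr={cfg.learning_rate})",
            f"batch size:            {cfg.batch_size} "
            f"(effective member bound {cfg.batch_size * 3 * 4})",
            f"hierarchy sampling:    {'on' if cfg.hierarchy else 'off'}",
            f"batch-hard mining:     {'on' if cfg.batch_hard else 'off'}",
            f"epochs run:            {len(h.records)} (max {cfg.max_epochs}, "
            f"patience {cfg.patience})",
            f"best epoch:            {best}",
            f"first/last mean loss:  {h.losses[0]:.4f} / {h.losses[-1]:.4f}",
        ]
        if best_rec is not None:
            acc = ", ".join(
                f"{k}={v:.3f}" if v is not None else f"{k}=n/a"
                for k, v in best_rec.val_accuracy.items())
            lines.append(f"best val accuracy:     {acc}")
        return "\n".join(lines)

    def save(self, path) -> None:
        self.network.save(path)
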