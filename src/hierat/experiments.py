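"""Reference experiments: signal recovery and sampling ablations.

These drivers reproduce, at desk scale, the two qualitative results the
method rests on:

* contrastive training boosts the hierarchy signal — leave-one-out
  annotation transfer in the learned space beats transfer on the raw
  vectors when the signal is diluted by nuisance dimensions, and the
  inter- vs intra-superfamily distance separation widens;
* both sampling components matter — dropping hierarchy sampling or
  batch-hard mining (or both) degrades mean per-level accuracy.

The study regime is :func:`hierat.synthetic.recovery_regime` (a 3x3x3x3
hierarchy, 6 members per superfamily, 64 signal + 192 nuisance
dimensions); training runs for at most 30 epochs with patience 10, which
this small model comfortably converges within.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .eat import embed, transfer
from .evaluation import accuracy
from .hierarchy import LEVEL_NAMES, shared_depth_matrix
from .network import ProjectionNetwork
from .store import LabelledDataset
from .synthetic import generate, recovery_regime, split
from .training import TrainConfig, train

ABLATION_VARIANTS: dict[str, dict[str, bool]] = {
    "full": {"hierarchy": True, "batch_hard": True},
    "no_batch_hard": {"hierarchy": True, "batch_hard": False},
    "no_hierarchy": {"hierarchy": False, "batch_hard": True},
    "neither": {"hierarchy": False, "batch_hard": False},
}


def loo_accuracies(dataset: LabelledDataset,
                   model: ProjectionNetwork | None = None) -> dict[str, float | None]:
    """Leave-one-out transfer accuracy per level (self-hits excluded)."""
    results = transfer(dataset, dataset, model=model, exclude_self=True)
    out: dict[str, float | None] = {}
    for lvl, name in enumerate(LEVEL_NAMES, start=1):
        out[name], _, _ = accuracy(results, dataset.labels, dataset.labels,
                                   lvl, exclude_self=True)
    return out


def superfamily_separation(dataset: LabelledDataset,
                           model: ProjectionNetwork | None = None) -> float:
    """Scale-free separation of the intra- vs inter-superfamily distance
    distributions: (mean(inter) - mean(intra)) / mean(all distances).

    Normalising by the space's mean pairwise distance makes the quantity
    comparable across spaces of different dimensionality and scale (a raw
    input space and a learned 128-d space have unrelated distance units).
    """
    mat = embed(dataset, model)
    dm = squareform(pdist(mat))
    codes = dataset.label_codes
    same_sf = shared_depth_matrix(codes, codes) == 4
    iu = np.triu_indices(len(dataset), k=1)
    intra = dm[iu][same_sf[iu]]
    inter = dm[iu][~same_sf[iu]]
    return float((inter.mean() - intra.mean()) / dm[iu].mean())


def fit_variant(dataset: LabelledDataset, seed: int,
                hierarchy: bool = True, batch_hard: bool = True,
                max_epochs: int = 30, patience: int = 10
                ) -> ProjectionNetwork:
    """Train one configuration on a 90/10 split of ``dataset``."""
    train_ids, val_ids, _ = split(dataset, (0.9, 0.1, 0.0), seed=seed)
    cfg = TrainConfig(seed=seed, hierarchy=hierarchy, batch_hard=batch_hard,
                      max_epochs=max_epochs, patience=patience)
    net, _ = train(dataset.subset(train_ids), dataset.subset(val_ids), cfg=cfg)
    return net


def recovery_experiment(seeds: Sequence[int] = (0, 1, 2),
                        variants: Mapping[str, dict] = ABLATION_VARIANTS,
                        max_epochs: int = 30, patience: int = 10) -> dict:
    """Train every ablation variant on the diluted-signal regime.

    Returns per-seed raw leave-one-out accuracies and separation, and per
    (variant, seed) the trained-space equivalents.
    """
    out: dict = {"raw": {}, "variants": {v: {} for v in variants}}
    for seed in seeds:
        dataset = generate(recovery_regime(), seed=seed)
        out["raw"][seed] = {
            "loo": loo_accuracies(dataset),
            "separation": superfamily_separation(dataset),
        }
        for name, switches in variants.items():
            net = fit_variant(dataset, seed, max_epochs=max_epochs,
                              patience=patience, **switches)
            out["variants"][name][seed] = {
                "loo": loo_accuracies(dataset, net),
                "separation": superfamily_separation(dataset, net),
            }
    return out


def mean_level_accuracy(loo: Mapping[str, float | None]) -> float:
    vals = [v for v in loo.values() if v is not None]
    return float(np.mean(vals))
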