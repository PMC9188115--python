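"""Triplet construction: hierarchy sampling and batch-hard re-wiring.

Training pairs are (anchor, positive, negative) triplets.  *Hierarchy
sampling* draws a random level alpha in {1..4}: positives share the
anchor's label down to alpha, negatives diverge exactly at alpha.  This
yields semi-hard triplets — never trivially distinguishable (the negative
always shares the first alpha-1 levels) and never pathological outliers.

*Batch-hard re-wiring* then replaces, within each mini-batch and for every
level i, each anchor's partners by the farthest eligible positive and the
nearest eligible negative in the current learned space, so one nominal
batch of ``batch_size`` anchors expands to at most ``batch_size * 3 * 4``
member slots.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .hierarchy import HierarchyLabel, encode_labels, shared_depth_matrix
from .store import LabelledDataset

ALPHAS = (1, 2, 3, 4)


@dataclass(frozen=True)
class Triplet:
    anchor_id: str
    positive_id: str
    negative_id: str
    alpha: int | None  # None for uniform (non-hierarchy) sampling


@dataclass
class RewiredBatch:
    """Batch-hard triplets: (anchor_id, positive_id, negative_id, level)."""

    triplets: list[tuple[str, str, str, int]]
    member_ids: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.triplets)


def effective_batch_bound(batch_size: int) -> int:
    """Upper bound on member slots per rewired batch: one triplet (3 proteins)
    per anchor per hierarchy level."""
    return batch_size * 3 * len(ALPHAS)


def sample_triplet(
    anchor_id: str,
    dataset: LabelledDataset,
    rng: np.random.Generator,
    hierarchy: bool = True,
) -> Triplet | None:
    """Draw one triplet for ``anchor_id``, or None when no level admits one.

    With ``hierarchy=True`` a level alpha is drawn uniformly; if the drawn
    alpha has no valid (positive, negative) pair, alpha is redrawn among the
    untried values, so an anchor is only skipped when no level works at all.
    Self-hits are excluded by id.  With ``hierarchy=False`` (ablation mode)
    the positive is a uniform same-superfamily partner and the negative a
    uniform draw from proteins with any other label.
    """
    codes = dataset.label_codes
    a_idx = dataset.store.index(anchor_id)
    depths = shared_depth_matrix(codes[a_idx:a_idx + 1], codes)[0]
    not_self = np.ones(len(dataset), dtype=bool)
    not_self[a_idx] = False

    if not hierarchy:
        pos_pool = np.flatnonzero((depths >= 4) & not_self)
        neg_pool = np.flatnonzero((depths < 4) & not_self)
        if pos_pool.size == 0 or neg_pool.size == 0:
            return None
        p = int(rng.choice(pos_pool))
        n = int(rng.choice(neg_pool))
        return Triplet(anchor_id, dataset.ids[p], dataset.ids[n], None)

    for alpha in rng.permutation(ALPHAS):
        alpha = int(alpha)
        pos_pool = np.flatnonzero((depths >= alpha) & not_self)
        neg_pool = np.flatnonzero((depths == alpha - 1) & not_self)
        if pos_pool.size and neg_pool.size:
            p = int(rng.choice(pos_pool))
            n = int(rng.choice(neg_pool))
            return Triplet(anchor_id, dataset.ids[p], dataset.ids[n], alpha)
    return None


def build_epoch(
    dataset: LabelledDataset,
    rng: np.random.Generator,
    hierarchy: bool = True,
) -> tuple[list[Triplet], int]:
    """One sampling attempt per protein as anchor, in shuffled order.

    Returns the triplet list and the number of skipped anchors (those with
    no valid partner pair at any level).
    """
    order = rng.permutation(len(dataset))
    triplets: list[Triplet] = []
    n_skipped = 0
    for idx in order:
        t = sample_triplet(dataset.ids[int(idx)], dataset, rng, hierarchy=hierarchy)
        if t is None:
            n_skipped += 1
        else:
            triplets.append(t)
    return triplets, n_skipped


def batch_hard_rewire(
    member_ids: Sequence[str],
    embeddings: np.ndarray,
    labels: Sequence[HierarchyLabel],
) -> RewiredBatch:
    """Re-wire a mini-batch with batch-hard mining at all four levels.

    For each anchor a and level i the hardest positive maximises, and the
    hardest negative minimises, the Euclidean distance to a in the current
    learned space among batch members with shared depth >= i (positives) or
    == i-1 (negatives).  An (a, i) pair is emitted only when both exist.
    Distance ties break to the lexicographically smallest candidate id.
    """
    member_ids = list(member_ids)
    n = len(member_ids)
    emb = np.asarray(embeddings, dtype=np.float64)
    if emb.shape[0] != n:
        raise ValueError(f"{n} ids but {emb.shape[0]} embedding rows")
    codes = encode_labels(list(labels))
    depths = shared_depth_matrix(codes, codes)

    diff = emb[:, None, :] - emb[None, :, :]
    dist = np.sqrt((diff * diff).sum(axis=2))

    # rank of each member id in lexicographic order, for tie-breaking
    id_rank = np.empty(n, dtype=np.int64)
    id_rank[np.argsort(np.array(member_ids, dtype=object))] = np.arange(n)

    eye = np.eye(n, dtype=bool)
    triplets: list[tuple[str, str, str, int]] = []
    BIG = np.int64(n + 1)

    out: dict[int, list[tuple[int, int, int]]] = {}
    for level in ALPHAS:
        pos_mask = (depths >= level) & ~eye
        neg_mask = (depths == level - 1) & ~eye
        has_pos = pos_mask.any(axis=1)
        has_neg = neg_mask.any(axis=1)
        anchors = np.flatnonzero(has_pos & has_neg)
        if anchors.size == 0:
            continue
        pd = np.where(pos_mask, dist, -np.inf)
        nd = np.where(neg_mask, dist, np.inf)
        pmax = pd.max(axis=1)
        nmin = nd.min(axis=1)
        # among argmax/argmin ties pick smallest id rank
        pos_tie = (pd == pmax[:, None]) & pos_mask
        neg_tie = (nd == nmin[:, None]) & neg_mask
        pos_pick = np.where(pos_tie, id_rank[None, :], BIG).argmin(axis=1)
        neg_pick = np.where(neg_tie, id_rank[None, :], BIG).argmin(axis=1)
        for a in anchors:
            out.setdefault(int(a), []).append((int(pos_pick[a]), int(neg_pick[a]), level))

    # emit grouped by anchor, levels ascending, for a stable deterministic order
    for a in sorted(out):
        for p, ng, level in out[a]:
            triplets.append((member_ids[a], member_ids[p], member_ids[ng], level))
    return RewiredBatch(triplets=triplets, member_ids=tuple(member_ids))
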