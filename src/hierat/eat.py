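"""Embedding-based annotation transfer (EAT).

The contrastively learned space outputs embeddings, not class predictions,
so inference mirrors homology-based inference: a query inherits the
hierarchy label of the lookup protein at the smallest Euclidean distance.
An optional reliability threshold theta withholds transfers whose nearest
hit is farther than theta — trading coverage for accuracy.

Large within-superfamily distances flag potentially wrong annotations;
:func:`detect_outliers` surfaces the worst same-superfamily pairs together
with each suspect's global nearest neighbour as an alternative-label
suggestion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

from .hierarchy import HierarchyLabel
from .network import ProjectionNetwork
from .store import EmbeddingStore, LabelledDataset


@dataclass(frozen=True)
class TransferResult:
    query_id: str
    hit_id: str | None
    distance: float | None
    label: HierarchyLabel | None


@dataclass(frozen=True)
class OutlierRecord:
    """A suspicious same-superfamily pair.

    ``id_a`` is the suspect (the pair member farther on average from the
    rest of its superfamily); ``neighbor_id`` / ``neighbor_label`` give its
    global nearest neighbour as the suggested alternative annotation.
    """

    id_a: str
    id_b: str
    distance: float
    neighbor_id: str
    neighbor_label: HierarchyLabel


def embed(data: EmbeddingStore | LabelledDataset,
          model: ProjectionNetwork | None) -> np.ndarray:
    """The evaluation-space matrix for a store: raw vectors, or the model's
    projections when a model is given."""
    store = data.store if isinstance(data, LabelledDataset) else data
    mat = np.asarray(store.matrix, dtype=np.float64)
    return model.project(mat) if model is not None else mat


def nearest_neighbor(query: np.ndarray, lookup_ids, lookup_matrix: np.ndarray,
                     exclude_ids: set[str] | frozenset[str] = frozenset()
                     ) -> tuple[str, float]:
    """Exhaustive nearest neighbour by Euclidean distance.

    Ties break to the lexicographically smallest id; ``exclude_ids``
    supports self-hit removal.  Raises when nothing remains to search.
    """
    keep = [(pid, i) for i, pid in enumerate(lookup_ids) if pid not in exclude_ids]
    if not keep:
        raise ValueError("lookup set is empty after exclusions")
    ids = [pid for pid, _ in keep]
    rows = [i for _, i in keep]
    d = np.linalg.norm(np.asarray(lookup_matrix, dtype=np.float64)[rows]
                       - np.asarray(query, dtype=np.float64), axis=1)
    best = d.min()
    hit = min(pid for pid, dd in zip(ids, d) if dd == best)
    return hit, float(best)


def transfer(queries: EmbeddingStore | LabelledDataset,
             lookup: LabelledDataset,
             model: ProjectionNetwork | None = None,
             theta: float | None = None,
             exclude_self: bool = False) -> list[TransferResult]:
    """Transfer each query's annotation from its nearest lookup protein.

    Both sides are embedded with the same ``model`` (or compared raw when
    no model is given).  When ``theta`` is set, queries whose nearest hit
    lies farther than theta get no hit: they count against coverage, not
    accuracy.  ``exclude_self=True`` enables the leave-one-out convention
    (a query never matches its own id).
    """
    q_store = queries.store if isinstance(queries, LabelledDataset) else queries
    qm = embed(queries, model)
    lm = embed(lookup, model)
    if qm.shape[1] != lm.shape[1]:
        raise ValueError(
            f"query dimension {qm.shape[1]} != lookup dimension {lm.shape[1]}"
        )
    dist = cdist(qm, lm)
    lookup_ids = np.array(lookup.ids, dtype=object)
    if exclude_self:
        for qi, qid in enumerate(q_store.ids):
            if qid in lookup.store:
                dist[qi, lookup.store.index(qid)] = np.inf
    # lexicographic tie-break on equal distances
    id_rank = np.empty(len(lookup_ids), dtype=np.int64)
    id_rank[np.argsort(lookup_ids)] = np.arange(len(lookup_ids))
    best = dist.min(axis=1)
    tie = dist == best[:, None]
    pick = np.where(tie, id_rank[None, :], len(lookup_ids) + 1).argmin(axis=1)

    results: list[TransferResult] = []
    for qi, qid in enumerate(q_store.ids):
        if not np.isfinite(best[qi]):
            raise ValueError(f"no lookup candidates for query {qid!r}")
        hit = str(lookup_ids[pick[qi]])
        d = float(best[qi])
        if theta is not None and d > theta:
            results.append(TransferResult(qid, None, d, None))
        else:
            results.append(TransferResult(qid, hit, d, lookup.labels[hit]))
    return results


def detect_outliers(dataset: LabelledDataset,
                    model: ProjectionNetwork | None = None,
                    k: int = 5) -> list[OutlierRecord]:
    """The k largest-distance pairs within any one homologous superfamily.

    Pairs are sorted by distance descending; within each pair the suspect
    (``id_a``) is the member with the larger mean distance to the rest of
    its superfamily.  Returns fewer than k records (possibly none, with a
    warning) when fewer same-superfamily pairs exist.
    """
    mat = embed(dataset, model)
    codes = dataset.label_codes
    ids = dataset.ids

    groups: dict[tuple, list[int]] = {}
    for i, row in enumerate(codes):
        groups.setdefault(tuple(row), []).append(i)

    pairs: list[tuple[float, str, str, int, int]] = []
    for members in groups.values():
        if len(members) < 2:
            continue
        sub = mat[members]
        dm = squareform(pdist(sub))
        mean_intra = dm.sum(axis=1) / (len(members) - 1)
        for ai in range(len(members)):
            for bi in range(ai + 1, len(members)):
                i, j = members[ai], members[bi]
                # suspect first: larger mean intra-family distance
                if (mean_intra[bi], ids[i]) > (mean_intra[ai], ids[j]):
                    i, j, = members[bi], members[ai]
                pairs.append((float(dm[ai, bi]), ids[i], ids[j], i, j))
    if not pairs:
        import warnings
        warnings.warn("no superfamily has >= 2 members; no outlier pairs exist")
        return []
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))

    records: list[OutlierRecord] = []
    for d, ida, idb, i, j in pairs[:k]:
        nn_id, _ = nearest_neighbor(mat[i], ids, mat, exclude_ids={ida})
        records.append(OutlierRecord(ida, idb, d, nn_id, dataset.labels[nn_id]))
    return records


def write_hits(results: list[TransferResult], path) -> None:
    """TSV: query_id, hit_id, distance (6 decimals), transferred C.A.T.H."""
    with open(path, "w", encoding="utf-8") as fh:
        for r in results:
            hit = r.hit_id or ""
            lab = str(r.label) if r.label is not None else ""
            d = f"{r.distance:.6f}" if r.distance is not None else ""
            fh.write(f"{r.query_id}\t{hit}\t{d}\t{lab}\n")
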