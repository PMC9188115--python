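"""Embedding stores: id-keyed matrices of per-protein vectors.

The on-disk format is the de-facto standard for protein language model
embedding dumps: one HDF5 dataset per protein id, value either a 1xD / (D,)
per-protein vector or an LxD per-residue matrix (pooled on read when
requested).  Values are stored as float32; half-precision inputs are
up-cast on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import h5py
import numpy as np

from .hierarchy import HierarchyLabel, encode_labels

FORMAT_VERSION = "1"


class StoreError(ValueError):
    pass


def mean_pool(per_residue: np.ndarray) -> np.ndarray:
    """Collapse an LxD per-residue matrix to a length-D per-protein vector
    by averaging over protein length."""
    arr = np.asarray(per_residue, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[0] == 0:
        raise StoreError("empty protein: need an LxD matrix with L >= 1")
    if not np.all(np.isfinite(arr)):
        raise StoreError("non-finite values in per-residue matrix")
    return arr.mean(axis=0)


class EmbeddingStore:
    """Ordered, id-keyed N x D matrix of fixed-length protein embeddings."""

    def __init__(self, ids: Sequence[str], matrix: np.ndarray):
        ids = list(ids)
        matrix = np.asarray(matrix, dtype=np.float32)
        if matrix.ndim == 1:
            matrix = matrix.reshape(len(ids), -1) if len(ids) else matrix.reshape(0, 0)
        if matrix.shape[0] != len(ids):
            raise StoreError(f"{len(ids)} ids but {matrix.shape[0]} rows")
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise StoreError(f"duplicate ids: {dupes[:5]}")
        if matrix.size and not np.all(np.isfinite(matrix)):
            raise StoreError("non-finite values in embedding matrix")
        self.ids: tuple[str, ...] = tuple(ids)
        self.matrix = matrix
        self._index = {pid: i for i, pid in enumerate(self.ids)}

    @property
    def dim(self) -> int:
        return int(self.matrix.shape[1]) if self.matrix.ndim == 2 else 0

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, pid: str) -> bool:
        return pid in self._index

    def __iter__(self) -> Iterator[str]:
        return iter(self.ids)

    def index(self, pid: str) -> int:
        return self._index[pid]

    def vector(self, pid: str) -> np.ndarray:
        return self.matrix[self._index[pid]]

    def subset(self, ids: Sequence[str]) -> "EmbeddingStore":
        rows = [self._index[i] for i in ids]
        return EmbeddingStore(list(ids), self.matrix[rows])


def write_store(store: EmbeddingStore, path: str | Path) -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs["format_version"] = FORMAT_VERSION
        for pid in store.ids:
            fh.create_dataset(pid, data=store.vector(pid).astype(np.float32))
        fh.attrs["id_order"] = list(store.ids)


def read_store(path: str | Path, pool: str | None = None) -> EmbeddingStore:
    """Read a keyed HDF5 embedding container.

    ``pool="mean"`` collapses LxD per-residue records by length-averaging;
    without it, 2-D records are an error.  All vectors must share one
    dimension D.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"embedding container not found: {path}")
    ids: list[str] = []
    vectors: list[np.ndarray] = []
    with h5py.File(path, "r") as fh:
        if "id_order" in fh.attrs:
            keys = [k for k in fh.attrs["id_order"]]
        else:
            keys = sorted(fh.keys())
        for pid in keys:
            arr = np.asarray(fh[pid], dtype=np.float32)
            if arr.ndim == 2 and arr.shape[0] == 1:
                arr = arr[0]
            if arr.ndim == 2:
                if pool == "mean":
                    arr = mean_pool(arr).astype(np.float32)
                else:
                    raise StoreError(
                        f"record {pid!r} is per-residue (L x D); pass pool='mean'"
                    )
            elif arr.ndim != 1:
                raise StoreError(f"record {pid!r} has ndim={arr.ndim}")
            ids.append(str(pid))
            vectors.append(arr)
    if not ids:
        return EmbeddingStore([], np.zeros((0, 0), dtype=np.float32))
    dims = {v.shape[0] for v in vectors}
    if len(dims) > 1:
        offenders = [pid for pid, v in zip(ids, vectors)
                     if v.shape[0] != vectors[0].shape[0]]
        raise StoreError(
            f"mixed embedding dimensions {sorted(dims)}; offending ids: {offenders[:5]}"
        )
    return EmbeddingStore(ids, np.vstack(vectors))


@dataclass
class JoinReport:
    n_joined: int
    n_unlabelled_embeddings: int
    n_unembedded_labels: int


class LabelledDataset:
    """An embedding store paired with a total id -> label mapping."""

    def __init__(self, store: EmbeddingStore, labels: Mapping[str, HierarchyLabel]):
        missing = [pid for pid in store.ids if pid not in labels]
        if missing:
            raise StoreError(f"ids without labels: {missing[:5]}")
        extra = [pid for pid in labels if pid not in store]
        if extra:
            raise StoreError(f"labelled ids without embeddings: {extra[:5]}")
        self.store = store
        self.labels = {pid: labels[pid] for pid in store.ids}
        self._codes: np.ndarray | None = None

    @property
    def ids(self) -> tuple[str, ...]:
        return self.store.ids

    def __len__(self) -> int:
        return len(self.store)

    @property
    def label_codes(self) -> np.ndarray:
        """(N, 4) integer label codes aligned with store order (cached)."""
        if self._codes is None:
            self._codes = encode_labels([self.labels[pid] for pid in self.ids])
        return self._codes

    def label_list(self) -> list[HierarchyLabel]:
        return [self.labels[pid] for pid in self.ids]

    def subset(self, ids: Sequence[str]) -> "LabelledDataset":
        return LabelledDataset(self.store.subset(ids),
                               {pid: self.labels[pid] for pid in ids})


def join(store: EmbeddingStore, labels: Mapping[str, HierarchyLabel]
         ) -> tuple[LabelledDataset, JoinReport]:
    """Inner-join embeddings with labels on id.

    Returns the aligned dataset plus counts of embeddings without labels
    and labels without embeddings.  An empty intersection is an error —
    there is nothing to train or evaluate on.
    """
    common = [pid for pid in store.ids if pid in labels]
    if not common:
        raise StoreError("no ids shared between embedding store and label table")
    report = JoinReport(
        n_joined=len(common),
        n_unlabelled_embeddings=len(store) - len(common),
        n_unembedded_labels=len(labels) - len(common),
    )
    ds = LabelledDataset(store.subset(common), {pid: labels[pid] for pid in common})
    return ds, report
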