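"""Four-level structural hierarchy labels and triplet eligibility.

CATH classifies protein domains at four nested levels: Class (secondary
structure content), Architecture (arrangement of secondary structures),
Topology (fold), and Homologous superfamily (common ancestry).  A label is
written as a dotted string, e.g. ``"1.25.10.60"``.  Two labels "share depth
k" when their first ``k`` tokens agree; the deeper the shared prefix, the
more similar the underlying 3D structures are expected to be.

Tokens are opaque strings compared by equality only — CATH tokens happen to
be numeric today, but nothing here relies on that.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

N_LEVELS = 4
LEVEL_NAMES = ("C", "A", "T", "H")

POSITIVE = "positive"
NEGATIVE = "negative"
NEITHER = "neither"


class LabelError(ValueError):
    """Raised for malformed hierarchy labels or label tables."""


@dataclass(frozen=True)
class HierarchyLabel:
    """An ordered 4-tuple of level tokens (class, architecture, topology,
    homologous superfamily)."""

    levels: tuple[str, str, str, str]

    def __post_init__(self) -> None:
        if len(self.levels) != N_LEVELS:
            raise LabelError(
                f"hierarchy label needs exactly {N_LEVELS} levels, "
                f"got {len(self.levels)}: {self.levels!r}"
            )
        if any(not tok for tok in self.levels):
            raise LabelError(f"empty level token in {self.levels!r}")

    def __str__(self) -> str:
        return ".".join(self.levels)

    def prefix(self, depth: int) -> tuple[str, ...]:
        """The first ``depth`` tokens (the class at hierarchy level ``depth``)."""
        return self.levels[:depth]


def parse_label(text: str, context: str = "") -> HierarchyLabel:
    """Parse a dotted ``C.A.T.H`` string into a :class:`HierarchyLabel`.

    Raises :class:`LabelError` for anything but exactly four non-empty
    dot-separated tokens; ``context`` (e.g. a record id) is included in the
    message so bad table rows are easy to find.
    """
    tokens = text.split(".")
    where = f" ({context})" if context else ""
    if len(tokens) != N_LEVELS:
        raise LabelError(
            f"expected 4 dot-separated tokens, got {len(tokens)} in {text!r}{where}"
        )
    if any(tok == "" for tok in tokens):
        raise LabelError(f"empty token in label {text!r}{where}")
    return HierarchyLabel(tuple(tokens))


def shared_depth(a: HierarchyLabel, b: HierarchyLabel) -> int:
    """Length of the longest common prefix of two labels, in [0, 4]."""
    depth = 0
    for ta, tb in zip(a.levels, b.levels):
        if ta != tb:
            break
        depth += 1
    return depth


def eligibility(anchor: HierarchyLabel, candidate: HierarchyLabel, alpha: int) -> str:
    """Classify ``candidate`` relative to ``anchor`` at sampling level ``alpha``.

    A positive shares the anchor's label down to level ``alpha``
    (shared depth >= alpha); a negative diverges exactly at ``alpha``
    (shared depth == alpha - 1).  Everything else is neither: such
    candidates are too dissimilar to carry signal at this level.
    """
    if alpha not in (1, 2, 3, 4):
        raise LabelError(f"alpha must be in 1..4, got {alpha}")
    d = shared_depth(anchor, candidate)
    if d >= alpha:
        return POSITIVE
    if d == alpha - 1:
        return NEGATIVE
    return NEITHER


# --- label tables -----------------------------------------------------------


def read_label_table(path: str | Path, header: bool = False) -> dict[str, HierarchyLabel]:
    """Read a two-column TSV ``id<TAB>C.A.T.H`` into an ordered mapping.

    Duplicate ids are an error; a single header line may be skipped with
    ``header=True``.
    """
    labels: dict[str, HierarchyLabel] = {}
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if header and lineno == 1:
                continue
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise LabelError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}"
                )
            pid, text = parts
            if pid in labels:
                raise LabelError(f"{path}:{lineno}: duplicate id {pid!r}")
            labels[pid] = parse_label(text, context=f"{path}:{lineno} id={pid}")
    return labels


def write_label_table(labels: Mapping[str, HierarchyLabel], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for pid, lab in labels.items():
            fh.write(f"{pid}\t{lab}\n")


# --- vectorised label codes -------------------------------------------------


def encode_labels(labels: Sequence[HierarchyLabel]) -> np.ndarray:
    """Encode labels as an (N, 4) integer matrix for vectorised comparison.

    Token codes are assigned per level in order of first appearance; only
    equality of codes is meaningful.
    """
    codes = np.empty((len(labels), N_LEVELS), dtype=np.int64)
    for lvl in range(N_LEVELS):
        seen: dict[str, int] = {}
        for i, lab in enumerate(labels):
            tok = lab.levels[lvl]
            codes[i, lvl] = seen.setdefault(tok, len(seen))
    return codes


def shared_depth_matrix(codes_a: np.ndarray, codes_b: np.ndarray) -> np.ndarray:
    """Pairwise shared prefix depths between two code matrices.

    Both arguments must come from a single :func:`encode_labels` call so the
    integer codes are comparable.  Returns an (Na, Nb) int matrix.
    """
    eq = codes_a[:, None, :] == codes_b[None, :, :]  # (Na, Nb, 4)
    # prefix length = number of leading levels that all agree
    prefix_ok = np.cumprod(eq, axis=2)
    return prefix_ok.sum(axis=2).astype(np.int64)
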