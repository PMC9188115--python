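"""Per-level evaluation of annotation transfer.

Correctness is hierarchical: a prediction can only be correct at level L
if all coarser levels are also correct, so a query is scored per level by
the shared prefix depth between truth and transferred label.  A query
whose true label has no same-level partner anywhere in the lookup set is
*excluded* at that level — no classifier could get it right — so the
denominators legitimately differ across levels.  A query with an
achievable label but no hit (e.g. thresholded out) counts as incorrect.

Metrics: accuracy (fraction correct among evaluated), coverage (fraction
of evaluated queries with a hit below the reliability threshold), the
multiclass Matthews correlation coefficient

    MCC = (c*s - sum_k p_k t_k) /
          sqrt((s^2 - sum_k p_k^2) * (s^2 - sum_k t_k^2))

over the confusion matrix C at one level (t_k true counts, p_k predicted
counts, c the correctly predicted total, s the grand total), and 95%
bootstrap confidence intervals (1.96 x bootstrap standard error over
resampled query sets).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .hierarchy import N_LEVELS, LEVEL_NAMES, HierarchyLabel, shared_depth
from .eat import TransferResult


def level_correctness(truth: HierarchyLabel,
                      predicted: HierarchyLabel | None) -> tuple[bool, bool, bool, bool]:
    """Per-level booleans; an absent prediction is incorrect at all levels."""
    if predicted is None:
        return (False,) * N_LEVELS
    d = shared_depth(truth, predicted)
    return tuple(d >= lvl for lvl in range(1, N_LEVELS + 1))


def _achievable(query_id: str, truth: HierarchyLabel,
                lookup_labels: Mapping[str, HierarchyLabel],
                level: int, exclude_self: bool) -> bool:
    prefix = truth.prefix(level)
    for pid, lab in lookup_labels.items():
        if exclude_self and pid == query_id:
            continue
        if lab.prefix(level) == prefix:
            return True
    return False


def _evaluated_mask(results: Sequence[TransferResult],
                    truths: Mapping[str, HierarchyLabel],
                    lookup_labels: Mapping[str, HierarchyLabel] | None,
                    level: int, exclude_self: bool) -> list[bool]:
    if lookup_labels is None:
        return [True] * len(results)
    return [_achievable(r.query_id, truths[r.query_id], lookup_labels, level,
                        exclude_self) for r in results]


def accuracy(results: Sequence[TransferResult],
             truths: Mapping[str, HierarchyLabel],
             lookup_labels: Mapping[str, HierarchyLabel] | None,
             level: int,
             exclude_self: bool = False) -> tuple[float | None, int, int]:
    """Fraction correct at ``level`` among non-excluded queries.

    Returns (accuracy | None when nothing is evaluable, n_evaluated,
    n_excluded).  ``exclude_self`` applies the leave-one-out convention to
    the achievability check as well.
    """
    mask = _evaluated_mask(results, truths, lookup_labels, level, exclude_self)
    evaluated = [r for r, keep in zip(results, mask) if keep]
    n_excl = len(results) - len(evaluated)
    if not evaluated:
        return None, 0, n_excl
    correct = sum(
        level_correctness(truths[r.query_id], r.label)[level - 1] for r in evaluated
    )
    return correct / len(evaluated), len(evaluated), n_excl


def coverage(results: Sequence[TransferResult],
             theta: float,
             level: int,
             truths: Mapping[str, HierarchyLabel] | None = None,
             lookup_labels: Mapping[str, HierarchyLabel] | None = None,
             exclude_self: bool = False) -> float:
    """Fraction of (non-excluded) queries whose nearest-hit distance < theta."""
    if truths is not None and lookup_labels is not None:
        mask = _evaluated_mask(results, truths, lookup_labels, level, exclude_self)
        evaluated = [r for r, keep in zip(results, mask) if keep]
    else:
        evaluated = list(results)
    if not evaluated:
        return 0.0
    made = sum(1 for r in evaluated if r.distance is not None and r.distance < theta)
    return made / len(evaluated)


# --- multiclass MCC ---------------------------------------------------------

_MISSING = "__no_hit__"


def confusion_counts(truths: Sequence[HierarchyLabel | str],
                     preds: Sequence[HierarchyLabel | str | None],
                     level: int | None = None) -> np.ndarray:
    """Square confusion matrix over the union of observed class keys.

    With ``level`` given, labels collapse to their prefix at that level;
    missing predictions occupy a dedicated class of their own (they can
    never be correct).
    """
    def key(lab):
        if lab is None:
            return _MISSING
        if isinstance(lab, HierarchyLabel):
            return ".".join(lab.prefix(level)) if level else str(lab)
        return str(lab)

    t = [key(x) for x in truths]
    p = [key(x) for x in preds]
    classes = sorted(set(t) | set(p))
    idx = {c: i for i, c in enumerate(classes)}
    mat = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for ti, pi in zip(t, p):
        mat[idx[ti], idx[pi]] += 1
    return mat


def mcc(counts: np.ndarray) -> float:
    """Multiclass Matthews correlation coefficient of a confusion matrix.

    Returns 0 when either factor under the root vanishes (e.g. constant
    predictions), where the coefficient is otherwise undefined.
    """
    c_mat = np.asarray(counts, dtype=np.float64)
    t_k = c_mat.sum(axis=1)  # true occurrences per class
    p_k = c_mat.sum(axis=0)  # predicted occurrences per class
    c = np.trace(c_mat)
    s = c_mat.sum()
    if s < 1:
        raise ValueError("empty confusion matrix")
    num = c * s - (p_k * t_k).sum()
    f1 = s * s - (p_k * p_k).sum()
    f2 = s * s - (t_k * t_k).sum()
    if f1 <= 0 or f2 <= 0:
        return 0.0
    return float(num / np.sqrt(f1 * f2))


# --- bootstrap --------------------------------------------------------------


def bootstrap_ci(outcomes: Sequence[float] | np.ndarray,
                 statistic: Callable[[np.ndarray], float] = np.mean,
                 n_boot: int = 1000,
                 seed: int = 0) -> tuple[float, float]:
    """(point estimate, 95% CI half-width) by query-level resampling.

    Draws ``n_boot`` resamples with replacement, and multiplies the
    bootstrap standard error of the statistic by 1.96.
    """
    arr = np.asarray(outcomes, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("no outcomes to bootstrap")
    rng = np.random.default_rng(seed)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        stats[b] = statistic(arr[rng.integers(0, arr.size, size=arr.size)])
    se = float(np.sqrt(np.mean((stats - stats.mean()) ** 2)))
    return float(statistic(arr)), 1.96 * se


# --- full report ------------------------------------------------------------


@dataclass
class LevelReport:
    level: str
    n_evaluated: int
    n_excluded: int
    accuracy: float | None
    accuracy_ci: float | None
    mcc: float | None
    mcc_ci: float | None
    coverage: float | None


@dataclass
class EvalReport:
    levels: dict[str, LevelReport]
    mean_accuracy: float | None
    theta: float | None = None

    def summary(self) -> str:
        lines = ["level  n_eval  n_excl  accuracy        MCC             coverage",
                 "-" * 66]
        for name in LEVEL_NAMES:
            lr = self.levels[name]
            acc = (f"{lr.accuracy:.3f} ± {lr.accuracy_ci:.3f}"
                   if lr.accuracy is not None else "undefined")
            m = (f"{lr.mcc:.3f} ± {lr.mcc_ci:.3f}" if lr.mcc is not None else "—")
            cov = f"{lr.coverage:.3f}" if lr.coverage is not None else "—"
            lines.append(f"{name:<5}  {lr.n_evaluated:>6}  {lr.n_excluded:>6}  "
                         f"{acc:<14}  {m:<14}  {cov}")
        mean = (f"{self.mean_accuracy:.3f}" if self.mean_accuracy is not None
                else "undefined")
        lines.append("-" * 66)
        lines.append(f"mean accuracy over levels: {mean}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        out = {"mean_accuracy": self.mean_accuracy, "theta": self.theta, "levels": {}}
        for name, lr in self.levels.items():
            out["levels"][name] = {
                "n_evaluated": lr.n_evaluated, "n_excluded": lr.n_excluded,
                "accuracy": lr.accuracy, "accuracy_ci95": lr.accuracy_ci,
                "mcc": lr.mcc, "mcc_ci95": lr.mcc_ci, "coverage": lr.coverage,
            }
        return out


def evaluate(results: Sequence[TransferResult],
             truths: Mapping[str, HierarchyLabel],
             lookup_labels: Mapping[str, HierarchyLabel] | None,
             theta: float | None = None,
             n_boot: int = 1000,
             seed: int = 0,
             exclude_self: bool = False) -> EvalReport:
    """Full per-level report: accuracy, MCC, coverage, bootstrap 95% CIs."""
    levels: dict[str, LevelReport] = {}
    accs: list[float] = []
    for lvl in range(1, N_LEVELS + 1):
        name = LEVEL_NAMES[lvl - 1]
        mask = _evaluated_mask(results, truths, lookup_labels, lvl, exclude_self)
        evaluated = [r for r, keep in zip(results, mask) if keep]
        n_excl = len(results) - len(evaluated)
        if not evaluated:
            levels[name] = LevelReport(name, 0, n_excl, None, None, None, None, None)
            continue
        outcomes = np.array([
            float(level_correctness(truths[r.query_id], r.label)[lvl - 1])
            for r in evaluated
        ])
        acc, acc_ci = bootstrap_ci(outcomes, np.mean, n_boot=n_boot, seed=seed + lvl)

        t_labs = [truths[r.query_id] for r in evaluated]
        p_labs = [r.label for r in evaluated]
        m = mcc(confusion_counts(t_labs, p_labs, level=lvl))
        rng = np.random.default_rng(seed + 10 + lvl)
        boot = np.empty(n_boot)
        idx_all = np.arange(len(evaluated))
        for b in range(n_boot):
            pick = rng.integers(0, len(evaluated), size=len(evaluated))
            boot[b] = mcc(confusion_counts([t_labs[i] for i in pick],
                                           [p_labs[i] for i in pick], level=lvl))
        m_ci = 1.96 * float(np.sqrt(np.mean((boot - boot.mean()) ** 2)))

        cov = None
        if theta is not None:
            cov = coverage(results, theta, lvl, truths, lookup_labels, exclude_self)
        levels[name] = LevelReport(name, len(evaluated), n_excl, acc, acc_ci, m, m_ci, cov)
        accs.append(acc)
    mean_acc = float(np.mean(accs)) if accs else None
    return EvalReport(levels=levels, mean_accuracy=mean_acc, theta=theta)
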