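"""Per-level metrics: hierarchical correctness, exclusions, MCC, bootstrap."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import matthews_corrcoef

from hierat import (EmbeddingStore, LabelledDataset, SyntheticSpec, accuracy,
                    bootstrap_ci, confusion_counts, coverage, evaluate,
                    generate, level_correctness, mcc, parse_label, transfer)
from hierat.eat import TransferResult


def res(qid, label_text, dist=0.5):
    lab = parse_label(label_text) if label_text else None
    return TransferResult(qid, "hit" if lab else None,
                          dist if lab else dist, lab)


class TestLevelCorrectness:
    @pytest.mark.parametrize("truth,pred,expected", [
        ("1.25.10.60", "1.25.10.60", (True, True, True, True)),
        ("1.25.10.60", "1.25.40.5", (True, True, False, False)),
        ("1.25.10.60", "2.25.10.60", (False, False, False, False)),
    ])
    def test_shared_prefix_semantics(self, truth, pred, expected):
        assert level_correctness(parse_label(truth), parse_label(pred)) == expected

    def test_absent_prediction_incorrect_everywhere(self):
        assert level_correctness(parse_label("1.2.3.4"), None) == (False,) * 4


class TestAccuracy:
    def test_all_exact_predictions(self):
        truths = {f"q{i}": parse_label("1.2.3.4") for i in range(3)}
        results = [res(q, "1.2.3.4") for q in truths]
        lookup = {"x": parse_label("1.2.3.4")}
        for lvl in (1, 2, 3, 4):
            acc, n_eval, n_excl = accuracy(results, truths, lookup, lvl)
            assert acc == 1.0 and n_eval == 3 and n_excl == 0

    def test_exclusion_rule_traced_by_hand(self):
        # the query's H label is achievable nowhere in the lookup: excluded
        # at H; at T a partner exists and the prediction is correct there
        truths = {"q": parse_label("1.2.3.4")}
        lookup = {"x": parse_label("1.2.3.9")}
        results = [res("q", "1.2.3.9")]
        acc_h, n_eval_h, n_excl_h = accuracy(results, truths, lookup, 4)
        assert acc_h is None and n_eval_h == 0 and n_excl_h == 1
        acc_t, n_eval_t, _ = accuracy(results, truths, lookup, 3)
        assert acc_t == 1.0 and n_eval_t == 1

    def test_achievable_but_no_hit_counts_incorrect(self):
        truths = {"q": parse_label("1.2.3.4")}
        lookup = {"x": parse_label("1.2.3.4")}
        results = [TransferResult("q", None, 9.9, None)]  # thresholded out
        acc, n_eval, _ = accuracy(results, truths, lookup, 4)
        assert acc == 0.0 and n_eval == 1

    def test_simple_fraction(self):
        truths = {"q0": parse_label("1.1.1.1"), "q1": parse_label("1.1.1.1"),
                  "q2": parse_label("1.1.1.1"), "q3": parse_label("2.1.1.1")}
        results = [res("q0", "1.9.9.9"), res("q1", "1.9.9.9"),
                   res("q2", "1.9.9.9"), res("q3", "1.9.9.9")]
        acc, _, _ = accuracy(results, truths, None, 1)
        assert acc == 0.75

    def test_nested_correctness_monotone_without_exclusions(self, default_dataset):
        results = transfer(default_dataset, default_dataset, exclude_self=True)
        accs = [accuracy(results, default_dataset.labels, None, lvl)[0]
                for lvl in (1, 2, 3, 4)]
        assert accs == sorted(accs, reverse=True)


class TestCoverage:
    def test_extreme_thresholds(self):
        truths = {"q": parse_label("1.2.3.4")}
        results = [res("q", "1.2.3.4", dist=0.7)]
        assert coverage(results, np.inf, 1) == 1.0
        assert coverage(results, 0.0, 1) == 0.0

    def test_percentile_construction(self, rng):
        n = 200
        dists = rng.uniform(0, 2, size=n)
        results = [TransferResult(f"q{i}", "h", float(d), parse_label("1.1.1.1"))
                   for i, d in enumerate(dists)]
        theta = float(np.percentile(dists, 75))
        assert coverage(results, theta, 1) == pytest.approx(0.75, abs=1.5 / n)

    def test_monotone_in_theta(self, rng):
        dists = rng.uniform(0, 2, size=50)
        results = [TransferResult(f"q{i}", "h", float(d), parse_label("1.1.1.1"))
                   for i, d in enumerate(dists)]
        covs = [coverage(results, t, 1) for t in np.linspace(0, 2.5, 26)]
        assert all(a <= b for a, b in zip(covs, covs[1:]))


def reference_mcc(counts):
    """Independent closed-form implementation over the confusion matrix."""
    counts = np.asarray(counts, dtype=float)
    K = counts.shape[0]
    s = counts.sum()
    c = sum(counts[k, k] for k in range(K))
    t = [counts[k, :].sum() for k in range(K)]
    p = [counts[:, k].sum() for k in range(K)]
    num = c * s - sum(p[k] * t[k] for k in range(K))
    den = np.sqrt((s**2 - sum(pk**2 for pk in p)) *
                  (s**2 - sum(tk**2 for tk in t)))
    return num / den if den > 0 else 0.0


class TestMCC:
    def test_perfect_diagonal(self):
        assert mcc(np.diag([3, 5, 2])) == pytest.approx(1.0)

    def test_constant_prediction_degenerate_zero(self):
        m = np.zeros((2, 2), dtype=int)
        m[0, 0], m[1, 0] = 5, 5  # everything predicted as class 0
        assert mcc(m) == 0.0

    def test_matches_reference_on_random_matrices(self, rng):
        for _ in range(200):
            k = int(rng.integers(2, 7))
            m = rng.integers(0, 20, size=(k, k))
            if m.sum() == 0:
                continue
            assert mcc(m) == pytest.approx(reference_mcc(m), abs=1e-12)

    def test_binary_case_equals_sklearn(self, rng):
        for _ in range(50):
            y_true = rng.integers(0, 2, size=40)
            y_pred = rng.integers(0, 2, size=40)
            m = confusion_counts([str(t) for t in y_true],
                                 [str(p) for p in y_pred])
            assert mcc(m) == pytest.approx(
                matthews_corrcoef(y_true, y_pred), abs=1e-12)

    def test_multiclass_equals_sklearn(self, rng):
        for _ in range(50):
            y_true = rng.integers(0, 4, size=60)
            y_pred = rng.integers(0, 4, size=60)
            m = confusion_counts([str(t) for t in y_true],
                                 [str(p) for p in y_pred])
            assert mcc(m) == pytest.approx(
                matthews_corrcoef(y_true, y_pred), abs=1e-12)


class TestBootstrap:
    def test_constant_outcomes_zero_width(self):
        point, hw = bootstrap_ci(np.ones(50), n_boot=200, seed=1)
        assert point == 1.0 and hw == 0.0

    def test_bernoulli_matches_binomial_closed_form(self):
        rng = np.random.default_rng(3)
        outcomes = rng.integers(0, 2, size=1000).astype(float)
        p = outcomes.mean()
        _, hw = bootstrap_ci(outcomes, n_boot=1000, seed=5)
        analytic = 1.96 * np.sqrt(p * (1 - p) / 1000)
        assert abs(hw - analytic) / analytic < 0.2

    def test_seed_reproducibility(self):
        out = np.arange(30, dtype=float)
        assert bootstrap_ci(out, n_boot=300, seed=9) == \
            bootstrap_ci(out, n_boot=300, seed=9)


class TestEvaluateReport:
    def test_full_report_structure(self, tiny_dataset):
        results = transfer(tiny_dataset, tiny_dataset, exclude_self=True,
                           theta=np.inf)
        report = evaluate(results, tiny_dataset.labels, tiny_dataset.labels,
                          theta=np.inf, n_boot=100, seed=0, exclude_self=True)
        for name in "CATH":
            lr = report.levels[name]
            assert lr.n_evaluated + lr.n_excluded == len(tiny_dataset)
            if lr.accuracy is not None:
                assert 0.0 <= lr.accuracy <= 1.0
                assert -1.0 <= lr.mcc <= 1.0
                assert lr.coverage == 1.0
        assert "mean accuracy" in report.summary()

    def test_unthresholded_equals_infinite_threshold(self, tiny_dataset):
        r_inf = transfer(tiny_dataset, tiny_dataset, theta=np.inf,
                         exclude_self=True)
        r_none = transfer(tiny_dataset, tiny_dataset, exclude_self=True)
        for lvl in (1, 2, 3, 4):
            a1, _, _ = accuracy(r_inf, tiny_dataset.labels,
                                tiny_dataset.labels, lvl, exclude_self=True)
            a2, _, _ = accuracy(r_none, tiny_dataset.labels,
                                tiny_dataset.labels, lvl, exclude_self=True)
            assert a1 == a2

    def test_random_transfer_near_class_frequency(self, default_dataset, rng):
        """Random annotation transfer should score near the class-frequency
        expectation at the top level (3 equi-sized classes -> 1/3)."""
        ids = list(default_dataset.ids)
        perm = rng.permutation(len(ids))
        results = [TransferResult(q, ids[j], 1.0, default_dataset.labels[ids[j]])
                   for q, j in zip(ids, perm)]
        outcomes = np.array([
            float(level_correctness(default_dataset.labels[r.query_id],
                                    r.label)[0]) for r in results])
        acc, hw = bootstrap_ci(outcomes, n_boot=300, seed=2)
        se = hw / 1.96
        assert abs(acc - 1.0 / 3.0) <= 3 * se
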