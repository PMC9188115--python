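"""Hierarchy sampling and batch-hard re-wiring.

The batch-hard miner is checked against an exhaustive O(|B|^2 x 4)
double-loop oracle written independently of the vectorised path.
"""

import numpy as np
import pytest

from hierat import (EmbeddingStore, LabelledDataset, batch_hard_rewire,
                    build_epoch, effective_batch_bound, eligibility,
                    parse_label, sample_triplet, shared_depth)
from hierat.hierarchy import POSITIVE, NEGATIVE


def make_dataset(label_map, dim=4, seed=0):
    rng = np.random.default_rng(seed)
    ids = list(label_map)
    store = EmbeddingStore(ids, rng.normal(size=(len(ids), dim)))
    return LabelledDataset(store, {k: parse_label(v) for k, v in label_map.items()})


def random_labelled_batch(rng, n, n_tokens=2):
    """Random ids, labels and vectors for oracle comparisons."""
    ids = [f"B{int(i):03d}" for i in rng.permutation(n)]
    labels = [parse_label(".".join(str(rng.integers(1, n_tokens + 1))
                                   for _ in range(4))) for _ in range(n)]
    emb = rng.normal(size=(n, 3))
    return ids, labels, emb


def brute_force_rewire(ids, labels, emb):
    """Independent double-loop oracle for batch-hard mining."""
    out = []
    for i, a_lab in enumerate(labels):
        for level in (1, 2, 3, 4):
            best_p, best_p_d = None, -np.inf
            best_n, best_n_d = None, np.inf
            for j in range(len(ids)):
                if i == j:
                    continue
                d = float(np.linalg.norm(emb[i] - emb[j]))
                sd = shared_depth(a_lab, labels[j])
                if sd >= level and (d > best_p_d or
                                    (d == best_p_d and ids[j] < best_p)):
                    best_p, best_p_d = ids[j], d
                if sd == level - 1 and (d < best_n_d or
                                        (d == best_n_d and ids[j] < best_n)):
                    best_n, best_n_d = ids[j], d
            if best_p is not None and best_n is not None:
                out.append((ids[i], best_p, best_n, level))
    return sorted(out)


class TestSampleTriplet:
    def test_only_one_alpha_satisfiable(self, rng):
        ds = make_dataset({"A": "1.1.1.1", "P": "1.1.1.2", "N": "2.1.1.1"})
        # only alpha=1 admits a (positive, negative) pair for anchor A
        for _ in range(20):
            t = sample_triplet("A", ds, rng)
            assert (t.anchor_id, t.positive_id, t.negative_id, t.alpha) == \
                ("A", "P", "N", 1)

    def test_alpha_redrawn_for_singleton_superfamily(self, rng):
        # anchor's superfamily is a singleton: alpha=4 has no positive,
        # but a triplet is still produced at a coarser level
        ds = make_dataset({"A": "1.1.1.1", "B": "1.1.1.2", "C": "1.1.2.1",
                           "D": "2.1.1.1"})
        for _ in range(40):
            t = sample_triplet("A", ds, rng)
            assert t is not None and t.alpha < 4

    def test_all_same_label_skipped(self, rng):
        ds = make_dataset({f"p{i}": "1.1.1.1" for i in range(4)})
        assert sample_triplet("p0", ds, rng) is None

    def test_emitted_triplets_satisfy_eligibility(self, default_dataset, rng):
        for _ in range(100):
            anchor = default_dataset.ids[int(rng.integers(len(default_dataset)))]
            t = sample_triplet(anchor, default_dataset, rng)
            a = default_dataset.labels[t.anchor_id]
            assert t.anchor_id not in (t.positive_id, t.negative_id)
            assert eligibility(a, default_dataset.labels[t.positive_id], t.alpha) == POSITIVE
            assert eligibility(a, default_dataset.labels[t.negative_id], t.alpha) == NEGATIVE

    def test_uniform_mode_positive_shares_superfamily(self, default_dataset, rng):
        t = sample_triplet(default_dataset.ids[0], default_dataset, rng,
                           hierarchy=False)
        assert t.alpha is None
        a = default_dataset.labels[t.anchor_id]
        assert shared_depth(a, default_dataset.labels[t.positive_id]) == 4
        assert shared_depth(a, default_dataset.labels[t.negative_id]) < 4


class TestBuildEpoch:
    def test_one_attempt_per_protein_and_determinism(self, tiny_dataset):
        t1, s1 = build_epoch(tiny_dataset, np.random.default_rng(5))
        t2, s2 = build_epoch(tiny_dataset, np.random.default_rng(5))
        assert len(t1) + s1 == len(tiny_dataset)
        assert t1 == t2 and s1 == s2

    def test_all_identical_labels_gives_empty_epoch(self, rng):
        ds = make_dataset({f"p{i}": "1.1.1.1" for i in range(5)})
        triplets, skipped = build_epoch(ds, rng)
        assert triplets == [] and skipped == 5

    def test_different_seeds_same_anchor_multiset(self, tiny_dataset):
        t1, _ = build_epoch(tiny_dataset, np.random.default_rng(1))
        t2, _ = build_epoch(tiny_dataset, np.random.default_rng(2))
        assert sorted(t.anchor_id for t in t1) == sorted(t.anchor_id for t in t2)
        assert [t.positive_id for t in t1] != [t.positive_id for t in t2]


class TestBatchHard:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(60):
            n = int(rng.integers(2, 33))
            ids, labels, emb = random_labelled_batch(rng, n)
            rb = batch_hard_rewire(ids, emb, labels)
            assert sorted(rb.triplets) == brute_force_rewire(ids, labels, emb)

    def test_identical_labels_no_negatives(self, rng):
        labels = [parse_label("1.1.1.1")] * 2
        rb = batch_hard_rewire(["a", "b"], rng.normal(size=(2, 3)), labels)
        assert len(rb) == 0

    def test_effective_batch_member_bound(self):
        assert effective_batch_bound(256) == 3072

    def test_size_bound_holds(self, rng):
        ids, labels, emb = random_labelled_batch(rng, 20)
        rb = batch_hard_rewire(ids, emb, labels)
        assert len(rb) <= 4 * len(ids)

    def test_order_invariance(self, rng):
        ids, labels, emb = random_labelled_batch(rng, 16)
        rb1 = batch_hard_rewire(ids, emb, labels)
        perm = rng.permutation(len(ids))
        rb2 = batch_hard_rewire([ids[i] for i in perm], emb[perm],
                                [labels[i] for i in perm])
        assert sorted(rb1.triplets) == sorted(rb2.triplets)

    def test_distance_ties_break_to_smallest_id(self):
        labels = [parse_label(t) for t in
                  ("1.1.1.1", "1.1.1.2", "1.1.1.2", "2.1.1.1", "2.1.1.1")]
        # two equidistant positives (z, b) and negatives (y, c) for anchor a
        emb = np.array([[0.0], [1.0], [-1.0], [2.0], [-2.0]])
        ids = ["a", "z", "b", "y", "c"]
        rb = batch_hard_rewire(ids, emb, labels)
        picks = {(t[0], t[3]): (t[1], t[2]) for t in rb.triplets}
        assert picks[("a", 1)] == ("b", "c")
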