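"""Split hygiene and metric implementations against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tcrbind import (PairRecord, auc_pr, auc_roc, ppv_at_k, youden_cutoff,
                     zero_shot_partition, resampled_eval)


def _pairs(epitope_counts):
    out = []
    for ep, n in epitope_counts.items():
        for i in range(n):
            out.append(PairRecord(cdr3b="CASSLGQAYEQY" + "F",
                                  epitope=ep, pseudo="A" * 34, label=1))
    return out


def _auc_bruteforce(scores, labels):
    """O(n²) pairwise Mann–Whitney count with ½ for ties."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def _ap_stepsum(scores, labels):
    """Step-wise average precision: sum precision@k over positive hits."""
    order = np.argsort(-np.asarray(scores), kind="stable")
    lab = np.asarray(labels)[order]
    hits = 0
    total = 0.0
    for k, l in enumerate(lab, start=1):
        if l == 1:
            hits += 1
            total += hits / k
    return total / lab.sum()


class TestZeroShotPartition:
    def test_threshold_toy_case(self):
        split = zero_shot_partition(_pairs({"AAAAKAAA": 12, "CCCCKCCC": 3}),
                                    min_count=10)
        assert split.train_epitopes == {"AAAAKAAA"}
        assert split.test_epitopes == {"CCCCKCCC"}
        assert len(split.train) == 12 and len(split.test) == 3

    def test_disjointness_over_random_masters(self, rng):
        eps = [f"{'ACDEFGHIK'[i % 9] * 8}" for i in range(20)]
        for _ in range(25):
            counts = {e: int(rng.integers(1, 30)) for e in
                      rng.choice(eps, size=8, replace=False)}
            split = zero_shot_partition(_pairs(counts), min_count=10)
            assert not (split.train_epitopes & split.test_epitopes)
            assert len(split.train) + len(split.test) == sum(counts.values())

    def test_min_count_zero_puts_all_in_train(self):
        split = zero_shot_partition(_pairs({"AAAAKAAA": 2}), min_count=0)
        assert split.test == []

    def test_empty_master_rejected(self):
        with pytest.raises(ValueError):
            zero_shot_partition([])


class TestAucRoc:
    def test_perfect_separation(self):
        assert auc_roc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_partial_overlap_brute_forced(self):
        assert auc_roc([0.8, 0.3, 0.5, 0.1], [1, 1, 0, 0]) == 0.75

    def test_all_ties_give_half(self):
        assert auc_roc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_matches_bruteforce_on_random_instances(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 31))
            scores = rng.choice([0.1, 0.25, 0.5, 0.8], size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert auc_roc(scores, labels) == pytest.approx(
                _auc_bruteforce(scores, labels), abs=1e-12)

    @given(st.floats(min_value=0.1, max_value=5.0))
    @settings(max_examples=30, deadline=None)
    def test_invariant_under_monotone_transform(self, a):
        rng = np.random.default_rng(3)
        scores = rng.random(40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        assert auc_roc(scores, labels) == pytest.approx(
            auc_roc(np.exp(a * scores), labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_roc([0.1, 0.2], [1, 1])


class TestAucPr:
    def test_perfect_separation(self):
        assert auc_pr([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_matches_stepsum_oracle(self, rng):
        for _ in range(100):
            scores = rng.random(10)
            labels = rng.integers(0, 2, 10)
            labels[0] = 1
            assert auc_pr(scores, labels) == pytest.approx(
                _ap_stepsum(scores, labels), abs=1e-12)

    def test_random_scores_concentrate_near_prevalence(self, rng):
        scores = rng.random(2000)
        labels = np.repeat([0, 1], 1000)
        assert auc_pr(scores, labels) == pytest.approx(0.5, abs=0.05)

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            auc_pr([0.5, 0.6], [0, 0])


class TestPpvAtK:
    def test_top1_positive(self):
        assert ppv_at_k([0.9, 0.1], [1, 0], 1) == 1.0

    def test_two_of_three(self):
        assert ppv_at_k([0.9, 0.8, 0.7, 0.1], [1, 0, 1, 1], 3) == \
            pytest.approx(2 / 3)

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            ppv_at_k([0.5], [1], 2)
        with pytest.raises(ValueError):
            ppv_at_k([0.5], [1], 0)


class TestYoudenCutoff:
    def test_perfect_separation(self):
        t, j = youden_cutoff([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert j == 1.0
        assert 0.2 < t < 0.8

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            youden_cutoff([0.5, 0.6], [1, 1])

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(100):
            scores = rng.choice(np.linspace(0, 1, 9), size=15)
            labels = rng.integers(0, 2, 15)
            labels[:2] = [0, 1]
            t, j = youden_cutoff(scores, labels)
            # exhaustive: every midpoint of adjacent distinct scores
            uniq = np.unique(scores)
            best = -np.inf
            for c in (uniq[:-1] + uniq[1:]) / 2:
                pred = scores > c
                tpr = (pred & (labels == 1)).sum() / (labels == 1).sum()
                fpr = (pred & (labels == 0)).sum() / (labels == 0).sum()
                best = max(best, tpr - fpr)
            assert j == pytest.approx(best, abs=1e-12)


class TestResampledEval:
    def _setup(self, rng):
        positives = [PairRecord(cdr3b="CASS" + "A" * 8, epitope="AAAAKAAA",
                                pseudo="A" * 34, label=1) for _ in range(5)]
        pool = ["C" + "".join(rng.choice(list("ACDEFGHIKL"), 11))
                for _ in range(300)]

        def scorer(records):
            return [1.0 if r.label == 1 else float(rng.random())
                    for r in records]
        return positives, pool, scorer

    def test_counts_and_determinism(self, rng):
        positives, pool, scorer = self._setup(rng)
        reports, summary = resampled_eval(scorer, positives, pool, ratio=10,
                                          n_sets=7, seed=3, ppv_ks=(5,))
        assert len(reports) == 7
        assert summary["n_sets"] == 7

        def det_scorer(records):
            return [float(r.label) for r in records]
        r1, s1 = resampled_eval(det_scorer, positives, pool, ratio=10,
                                n_sets=3, seed=5)
        r2, s2 = resampled_eval(det_scorer, positives, pool, ratio=10,
                                n_sets=3, seed=5)
        assert [r.auc_roc for r in r1] == [r.auc_roc for r in r2]
        assert s1 == s2

    def test_metric_report_bounds(self, rng):
        positives, pool, scorer = self._setup(rng)
        reports, _ = resampled_eval(scorer, positives, pool, ratio=10,
                                    n_sets=3, seed=1, ppv_ks=(5,))
        for r in reports:
            assert 0 <= r.auc_roc <= 1 and 0 <= r.auc_pr <= 1
            assert all(0 <= v <= 1 for v in r.ppv.values())
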