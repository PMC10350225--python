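"""Batch-mixing, QC and classification metrics against independent oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import (adjusted_mutual_info_score, adjusted_rand_score)

from debatch import (BatchProbe, SyntheticConfig, adjusted_mutual_information,
                     adjusted_rand_index, evaluate_representation,
                     generate_synthetic, knn_batch_probabilities, matthews_cc,
                     normalized_batch_entropy, qc_average_pcc,
                     qc_normalized_med)
from debatch.errors import ValidationError
from debatch.metrics import ContingencyTable, expected_mutual_information


# ---------------------------------------------------------------------------
# brute-force oracles

def brute_ari(pred, truth):
    """Pair-counting route: agreement over all unordered sample pairs."""
    n = len(pred)
    a11 = a00 = a10 = a01 = 0
    for i, j in itertools.combinations(range(n), 2):
        sp, st_ = pred[i] == pred[j], truth[i] == truth[j]
        if sp and st_:
            a11 += 1
        elif not sp and not st_:
            a00 += 1
        elif sp:
            a10 += 1
        else:
            a01 += 1
    num = 2.0 * (a11 * a00 - a10 * a01)
    den = (a11 + a10) * (a10 + a00) + (a11 + a01) * (a01 + a00)
    return 1.0 if den == 0 else num / den


def brute_ami(pred, truth):
    """Direct factorial evaluation of the hypergeometric E[MI] sum."""
    t = ContingencyTable.from_labels(pred, truth)
    n = t.total
    a, b = t.row_sums, t.col_sums
    mi = 0.0
    for i in range(t.counts.shape[0]):
        for j in range(t.counts.shape[1]):
            nij = t.counts[i, j]
            if nij:
                mi += (nij / n) * math.log(n * nij / (a[i] * b[j]))
    emi = _emi_reference(t)

    def ent(margin):
        p = np.asarray(margin) / n
        p = p[p > 0]
        return float(-(p * np.log(p)).sum())

    hu, hv = ent(a), ent(b)
    if t.counts.shape == (1, 1) or (t.counts.shape[0] == t.counts.shape[1] == n):
        return 1.0
    denom = (hu + hv) / 2 - emi
    if abs(denom) < 1e-15:
        denom = 1e-15
    return (mi - emi) / denom


def _partitions(n, max_blocks=3):
    """All set partitions of n items into <= max_blocks blocks, as canonical
    label vectors (first occurrences in increasing order)."""
    out = []

    def rec(prefix, used):
        if len(prefix) == n:
            out.append(tuple(prefix))
            return
        for lab in range(min(used + 1, max_blocks)):
            rec(prefix + [lab], max(used, lab + 1))

    rec([0], 1)
    return out


# ---------------------------------------------------------------------------
# kNN batch probe

class TestKnnProbe:
    def test_probabilities_match_brute_force_neighbour_counts(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 3))
        batch = np.array(list("AABBBABABA"), dtype=object)
        P, levels = knn_batch_probabilities(X, batch, BatchProbe(k=4))
        # independent all-pairs distance ranking
        for i in range(10):
            d = np.sqrt(((X - X[i]) ** 2).sum(axis=1))
            d[i] = np.inf
            nn = np.argsort(d, kind="stable")[:4]
            for j, lev in enumerate(levels):
                assert P[i, j] == pytest.approx((batch[nn] == lev).mean())

    def test_separated_clusters_are_pure(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.1, (8, 2)),
                       rng.normal(100, 0.1, (8, 2))])
        batch = np.array(["A"] * 8 + ["B"] * 8, dtype=object)
        P, levels = knn_batch_probabilities(X, batch, BatchProbe(k=3))
        own = np.array([levels.index(b) for b in batch])
        assert np.allclose(P[np.arange(16), own], 1.0)

    def test_identical_points_rows_still_sum_to_one(self):
        X = np.zeros((6, 2))
        batch = np.array(["A", "B"] * 3, dtype=object)
        P, _ = knn_batch_probabilities(X, batch, BatchProbe(k=3))
        assert np.allclose(P.sum(axis=1), 1.0)

    def test_invariance_to_feature_permutation_and_rotation(self, rng):
        X = rng.normal(size=(30, 4))
        batch = np.array(["A", "B", "C"] * 10, dtype=object)
        P0, _ = knn_batch_probabilities(X, batch, BatchProbe(k=5))
        P1, _ = knn_batch_probabilities(X[:, rng.permutation(4)], batch,
                                        BatchProbe(k=5))
        Q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        P2, _ = knn_batch_probabilities(X @ Q, batch, BatchProbe(k=5))
        assert np.allclose(P0, P1)
        assert np.allclose(P0, P2)

    def test_k_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            knn_batch_probabilities(np.zeros((4, 2)),
                                    np.array(list("ABAB")), BatchProbe(k=4))


# ---------------------------------------------------------------------------
# normalized batch entropy

class TestNBE:
    def test_indicator_rows_give_one(self):
        P = np.eye(4)[np.arange(40) % 4]
        assert normalized_batch_entropy(P, K=4) == pytest.approx(1.0)

    def test_uniform_rows_give_zero(self):
        P = np.full((40, 4), 0.25)
        assert normalized_batch_entropy(P, K=4) == pytest.approx(0.0)

    def test_hand_computed_mixed_rows(self):
        P = np.array([[1.0, 0.0, 0.0], [0.5, 0.25, 0.25]])
        be = (0.0 + -(0.5 * math.log(0.5) + 0.5 * math.log(0.25))) / 2
        assert normalized_batch_entropy(P, K=3) == pytest.approx(
            (math.log(3) - be) / math.log(3))

    def test_negative_probability_rejected(self):
        with pytest.raises(ValidationError):
            normalized_batch_entropy(np.array([[1.5, -0.5]]), K=2)


# ---------------------------------------------------------------------------
# ARI / AMI

class TestPartitionScores:
    def test_identical_partitions_score_one(self):
        labels = ["a", "a", "b", "c", "b", "c"]
        assert adjusted_rand_index(labels, labels) == pytest.approx(1.0)
        assert adjusted_mutual_information(labels, labels) == pytest.approx(1.0)

    def test_random_labelings_average_near_zero(self, rng):
        truth = rng.integers(0, 3, size=200)
        aris, amis = [], []
        for _ in range(100):
            pred = rng.permutation(truth)
            aris.append(adjusted_rand_index(pred, truth))
            amis.append(adjusted_mutual_information(pred, truth))
        assert abs(np.mean(aris)) < 0.05
        assert abs(np.mean(amis)) < 0.05

    def test_printed_2x2_table_case(self):
        pred = ["p0", "p0", "p0", "p1", "p1", "p1"]
        truth = ["t0", "t0", "t1", "t0", "t1", "t1"]  # table [[2,1],[1,2]]
        assert adjusted_rand_index(pred, truth) == pytest.approx(
            brute_ari(pred, truth))
        assert adjusted_mutual_information(pred, truth) == pytest.approx(
            brute_ami(pred, truth))

    def test_exhaustive_equivalence_small_partitions(self):
        """Implementation == brute-force pair counting / factorial E[MI] on
        every ordered pair of partitions of up to 6 items into <= 3 blocks."""
        for n in (3, 5, 6):
            parts = _partitions(n)
            for pred in parts:
                for truth in parts:
                    assert adjusted_rand_index(pred, truth) == pytest.approx(
                        brute_ari(pred, truth), abs=1e-10)
            # AMI's factorial oracle is slower: subsample the pair grid
            rng = np.random.default_rng(n)
            for _ in range(150):
                pred = parts[rng.integers(len(parts))]
                truth = parts[rng.integers(len(parts))]
                assert adjusted_mutual_information(pred, truth) == \
                    pytest.approx(brute_ami(pred, truth), abs=1e-9)

    def test_sampled_equivalence_n7_n8_and_sklearn_cross_check(self):
        rng = np.random.default_rng(11)
        for n in (7, 8):
            parts = _partitions(n)
            for _ in range(200):
                pred = parts[rng.integers(len(parts))]
                truth = parts[rng.integers(len(parts))]
                ari = adjusted_rand_index(pred, truth)
                ami = adjusted_mutual_information(pred, truth)
                assert ari == pytest.approx(brute_ari(pred, truth), abs=1e-10)
                assert ari == pytest.approx(
                    adjusted_rand_score(truth, pred), abs=1e-10)
                if len(set(pred)) > 1 or len(set(truth)) > 1:
                    assert ami == pytest.approx(
                        adjusted_mutual_info_score(truth, pred), abs=1e-8)

    def test_gammaln_emi_matches_exact_factorial_sum(self):
        pred = ["a"] * 4 + ["b"] * 3 + ["c"] * 2
        truth = ["x", "y", "z"] * 3
        t = ContingencyTable.from_labels(pred, truth)
        assert expected_mutual_information(t) == pytest.approx(
            _emi_reference(t), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            adjusted_rand_index([1, 2], [1, 2, 3])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 3), min_size=2, max_size=40),
           st.integers(0, 2 ** 31 - 1))
    def test_bounds_hold_on_fuzzed_partitions(self, truth, seed):
        pred = np.random.default_rng(seed).integers(0, 4, size=len(truth))
        assert adjusted_rand_index(pred, truth) <= 1.0 + 1e-12
        assert adjusted_mutual_information(pred, truth) <= 1.0 + 1e-9


def _emi_reference(table):
    """Factorial-form E[MI], independent of the gammaln implementation."""
    f = math.factorial
    a, b, n = table.row_sums, table.col_sums, table.total
    emi = 0.0
    for ai in a:
        for bj in b:
            for nij in range(max(1, ai + bj - n), min(ai, bj) + 1):
                w = (f(ai) * f(bj) * f(n - ai) * f(n - bj)) / (
                    f(n) * f(nij) * f(ai - nij) * f(bj - nij)
                    * f(n - ai - bj + nij))
                emi += (nij / n) * math.log(n * nij / (ai * bj)) * w
    return emi


# ---------------------------------------------------------------------------
# QC metrics

class TestQCMetrics:
    def test_affine_copies_correlate_perfectly(self, rng):
        base = rng.normal(size=20)
        X = np.vstack([2 * base + 1, base, 0.5 * base - 3])
        assert qc_average_pcc(X) == pytest.approx(1.0)

    def test_negated_pair_scores_minus_one(self, rng):
        base = rng.normal(size=30)
        base -= base.mean()
        assert qc_average_pcc(np.vstack([base, -base])) == pytest.approx(-1.0)

    def test_three_rows_average_hand_computed_pccs(self, rng):
        X = rng.normal(size=(3, 15))
        expected = np.mean([np.corrcoef(X[i], X[j])[0, 1]
                            for i, j in [(0, 1), (0, 2), (1, 2)]])
        assert qc_average_pcc(X) == pytest.approx(expected)

    def test_zero_variance_rows_dropped_then_error(self, rng):
        flat = np.ones(10)
        ok = rng.normal(size=(2, 10))
        val = qc_average_pcc(np.vstack([ok, flat]))
        assert val == pytest.approx(np.corrcoef(ok[0], ok[1])[0, 1])
        with pytest.raises(ValidationError):
            qc_average_pcc(np.vstack([flat, flat]))

    def test_nmed_identical_qcs_give_zero(self, rng):
        qc = np.tile(rng.normal(size=5), (3, 1))
        non = rng.normal(size=(5, 5))
        assert qc_normalized_med(qc, non) == pytest.approx(0.0)

    def test_nmed_equal_spreads_give_about_one(self, rng):
        X = rng.normal(size=(200, 10))
        assert qc_normalized_med(X[:100], X[100:]) == pytest.approx(1.0, abs=0.15)

    def test_nmed_hand_case(self):
        qc = np.array([[0.0], [1.0], [2.0]])        # pairwise 1,2,1 -> med 1
        non = np.array([[0.0], [4.0], [8.0]])       # pairwise 4,8,4 -> med 4
        assert qc_normalized_med(qc, non) == pytest.approx(0.25)

    def test_degenerate_reference_rejected(self):
        with pytest.raises(ValidationError):
            qc_normalized_med(np.ones((2, 3)), np.ones((3, 3)))


# ---------------------------------------------------------------------------
# MCC

class TestMCC:
    def test_perfect_prediction_is_one(self):
        y = ["a", "b", "a", "c"]
        assert matthews_cc(y, y) == pytest.approx(1.0)

    def test_constant_prediction_is_zero(self):
        y = ["a"] * 9 + ["b"]
        assert matthews_cc(y, ["a"] * 10) == pytest.approx(0.0)

    def test_binary_closed_form(self):
        # TP=40, TN=30, FP=10, FN=20
        y_true = ["+"] * 60 + ["-"] * 40
        y_pred = ["+"] * 40 + ["-"] * 20 + ["-"] * 30 + ["+"] * 10
        expected = (40 * 30 - 10 * 20) / math.sqrt(50 * 60 * 40 * 50)
        assert matthews_cc(y_true, y_pred) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            matthews_cc([], [])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_bounded_on_random_labelings(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 3, size=30)
        p = rng.integers(0, 3, size=30)
        assert -1.0 - 1e-12 <= matthews_cc(y, p) <= 1.0 + 1e-12


# ---------------------------------------------------------------------------
# composite report

class TestEvaluateRepresentation:
    def test_no_qc_dataset_leaves_qc_metrics_absent(self):
        ds, _ = generate_synthetic(SyntheticConfig(
            n_samples=60, n_features=20, n_qc_per_batch=0, seed=4))
        rep = evaluate_representation(ds.values, ds, probe=BatchProbe(k=5))
        assert rep.aPCC is None and rep.nMED is None
        assert rep.mcc is None

    def test_perfect_batch_separation_maxes_all_mixing_scores(self, rng):
        ds, _ = generate_synthetic(SyntheticConfig(
            n_samples=60, n_features=4, n_informative=2, n_qc_per_batch=0,
            seed=4))
        X = rng.normal(scale=0.01, size=(ds.n_samples, 2))
        X[:, 0] += 1000 * ds.batch_indices()
        rep = evaluate_representation(X, ds, probe=BatchProbe(k=5))
        assert rep.nBE == pytest.approx(1.0)
        assert rep.ARI == pytest.approx(1.0)
        assert rep.AMI == pytest.approx(1.0)

    def test_report_matches_component_wise_computation(self, small_dataset):
        ds, _ = small_dataset
        probe = BatchProbe(k=10)
        rep = evaluate_representation(ds.values, ds, probe=probe)
        P, levels = knn_batch_probabilities(ds.values, ds.batch, probe)
        pred = [levels[j] for j in P.argmax(axis=1)]
        assert rep.nBE == pytest.approx(
            normalized_batch_entropy(P, len(levels)))
        assert rep.ARI == pytest.approx(adjusted_rand_index(pred, ds.batch))
        assert rep.AMI == pytest.approx(
            adjusted_mutual_information(pred, ds.batch))
        assert rep.aPCC == pytest.approx(qc_average_pcc(ds.values[ds.is_qc]))
        assert rep.nMED == pytest.approx(
            qc_normalized_med(ds.values[ds.is_qc], ds.values[~ds.is_qc]))

    def test_misaligned_predictions_rejected(self, small_dataset):
        ds, _ = small_dataset
        with pytest.raises(ValidationError):
            evaluate_representation(ds.values, ds, y_pred=["x"] * 3,
                                    probe=BatchProbe(k=5))
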