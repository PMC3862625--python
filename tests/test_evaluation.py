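"""Retrieval ranking, AP/MAP, KNN-score ROC and diagnostic metrics."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from mvlle.evaluation import (
    ContingencyTable,
    average_precision_at_n,
    diagnostic_test,
    dor,
    dor_ci95,
    f1,
    knn_positive_score,
    map_at_n,
    rank_retrieve,
    roc_curve,
    sensitivity,
    specificity,
)


class TestRankRetrieve:
    def test_one_dimensional_example(self):
        r = rank_retrieve(np.array([[0.0], [1.0], [3.0]]), 0)
        assert np.array_equal(r.ranking, [1, 2])
        assert np.allclose(r.distances, [1.0, 3.0])

    def test_ties_broken_by_lower_index(self):
        r = rank_retrieve(np.array([[0.0], [2.0], [2.0], [1.0]]), 0)
        assert np.array_equal(r.ranking, [3, 1, 2])

    def test_matches_full_sort_oracle(self, rng):
        y = rng.standard_normal((30, 4))
        for q in (0, 7, 29):
            r = rank_retrieve(y, q)
            d = np.linalg.norm(y - y[q], axis=1)
            expected = sorted((dd, i) for i, dd in enumerate(d) if i != q)
            assert np.array_equal(r.ranking, [i for _, i in expected])


class TestAveragePrecision:
    @pytest.mark.parametrize(
        "flags,n,r_total,expected",
        [
            ((1, 1, 1), 3, 5, 1.0),
            ((1, 0, 1), 3, 2, (1.0 + 2 / 3) / 2),
            ((0, 0, 0), 3, 2, 0.0),
            ((1, 0, 0, 1, 1), 5, 3, (1 + 2 / 4 + 3 / 5) / 3),
        ],
    )
    def test_formula(self, flags, n, r_total, expected):
        assert average_precision_at_n(flags, n, r_total) == pytest.approx(expected)

    def test_cutoff_beyond_list_warns_and_uses_full_list(self):
        with pytest.warns(UserWarning, match="full list"):
            v = average_precision_at_n((1, 0), 5, 1)
        assert v == pytest.approx(1.0)


class TestMapAtN:
    def test_perfectly_clustered_embedding_gives_one(self):
        y = np.vstack([np.zeros((6, 2)), np.full((6, 2), 10.0)])
        y += np.linspace(0, 0.1, 12)[:, None]  # small within-cluster spread
        labels = np.repeat([0, 1], 6)
        assert map_at_n(y, labels, 5) == 1.0

    def test_random_labels_match_monte_carlo_reference(self, rng):
        # labels independent of the embedding: MAP@N should agree with the
        # expected AP of i.i.d. Bernoulli(1/C) relevance flags, estimated
        # by direct simulation of the AP formula
        y = rng.standard_normal((400, 3))
        labels = rng.integers(0, 4, 400)
        got = map_at_n(y, labels, 50)
        sims = []
        for _ in range(400):
            flags = rng.random(399) < 0.25
            top = flags[:50]
            hits = np.cumsum(top)
            ap = (hits[top] / (np.flatnonzero(top) + 1)).sum() / 50
            sims.append(ap)
        mc = np.mean(sims)
        assert got == pytest.approx(mc, abs=4 * np.std(sims) / np.sqrt(len(sims)) + 0.02)

    def test_invariant_to_rigid_rotation(self, rng):
        y = rng.standard_normal((40, 3))
        labels = rng.integers(0, 3, 40)
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        assert map_at_n(y, labels, 10) == pytest.approx(
            map_at_n(y @ q, labels, 10)
        )

    def test_query_policy_random_is_seeded(self, rng):
        y = rng.standard_normal((30, 2))
        labels = rng.integers(0, 3, 30)
        a = map_at_n(y, labels, 5, query_policy="random", seed=1)
        b = map_at_n(y, labels, 5, query_policy="random", seed=1)
        assert a == b


class TestKnnScoreAndRoc:
    def test_extreme_scores(self):
        y = np.arange(20.0)[:, None]
        positive = np.zeros(20, bool)
        positive[:16] = True
        assert knn_positive_score(y, 0, positive, k=15) == 1.0
        assert knn_positive_score(y, 19, positive, k=3) == 0.0

    def test_matches_ranking_recount(self, rng):
        y = rng.standard_normal((40, 3))
        positive = rng.random(40) < 0.4
        for i in (0, 13, 39):
            r = rank_retrieve(y, i)
            expected = positive[r.ranking[:15]].mean()
            assert knn_positive_score(y, i, positive, 15) == pytest.approx(expected)

    def test_perfect_and_uninformative_areas(self):
        pos = np.array([0, 0, 1, 1], bool)
        _, a = roc_curve(np.array([0.1, 0.2, 0.8, 0.9]), pos)
        assert a == pytest.approx(1.0)
        _, a = roc_curve(np.full(4, 0.5), pos)
        assert a == pytest.approx(0.5)

    def test_area_equals_mann_whitney_u(self, rng):
        scores = rng.integers(0, 5, 30).astype(float)  # many ties
        positive = rng.random(30) < 0.5
        _, area = roc_curve(scores, positive)
        ps, ns = scores[positive], scores[~positive]
        u = sum(
            1.0 if p > n else 0.5 if p == n else 0.0 for p in ps for n in ns
        )
        assert area == pytest.approx(u / (len(ps) * len(ns)))
        assert area == pytest.approx(roc_auc_score(positive, scores))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve(np.arange(4.0), np.ones(4, bool))


class TestDiagnosticTest:
    def test_distant_clusters_classify_perfectly(self):
        y = np.vstack([np.zeros((20, 2)), np.full((20, 2), 50.0)])
        y += np.arange(40)[:, None] * 1e-3
        labels = np.repeat([1, 0], 20)
        t = diagnostic_test(
            y, np.arange(20), np.arange(20, 40), labels == 1, k=15
        )
        assert (t.TP, t.FP, t.FN, t.TN) == (20, 0, 0, 20)

    def test_counts_conserve_test_set_sizes(self, rng):
        y = rng.standard_normal((50, 3))
        labels = rng.integers(0, 2, 50)
        pos = np.flatnonzero(labels == 1)[:10]
        neg = np.flatnonzero(labels == 0)[:12]
        t = diagnostic_test(y, pos, neg, labels == 1, k=7)
        assert t.TP + t.FN == 10 and t.FP + t.TN == 12

    def test_matches_per_sample_majority_oracle(self, rng):
        y = rng.standard_normal((40, 2))
        labels = rng.integers(0, 2, 40)
        pos = np.flatnonzero(labels == 1)
        neg = np.flatnonzero(labels == 0)
        k = 15
        t = diagnostic_test(y, pos, neg, labels == 1, k=k)
        tp = fp = fn = tn = 0
        for i in range(40):
            d = np.linalg.norm(y - y[i], axis=1)
            d[i] = np.inf
            top = np.argsort(d, kind="stable")[:k]
            called = (labels[top] == 1).sum() >= 8  # more than half of 15
            if labels[i] == 1:
                tp, fn = tp + called, fn + (not called)
            else:
                fp, tn = fp + called, tn + (not called)
        assert (t.TP, t.FP, t.FN, t.TN) == (tp, fp, fn, tn)

    def test_overlapping_sets_rejected(self, rng):
        y = rng.standard_normal((10, 2))
        with pytest.raises(ValueError, match="disjoint"):
            diagnostic_test(y, [0, 1], [1, 2], np.zeros(10, bool), k=3)


class TestContingencyMetrics:
    def test_basic_formulas(self):
        t = ContingencyTable(TP=8, FP=2, FN=4, TN=6)
        assert sensitivity(t) == pytest.approx(8 / 12)
        assert specificity(t) == pytest.approx(6 / 8)
        assert dor(t) == pytest.approx((8 * 6) / (2 * 4))
        assert f1(t) == pytest.approx(16 / (16 + 2 + 4))

    def test_symmetric_table_identity(self):
        # TP=TN and FP=FN gives DOR = (TP/FP)^2
        t = ContingencyTable(TP=30, FP=5, FN=5, TN=30)
        assert dor(t) == pytest.approx(36.0)

    def test_truth_role_swap_inverts_dor(self):
        # exchanging which class counts as diseased (keeping the test's
        # calls fixed) maps TP<->FP and FN<->TN, inverting the odds ratio
        t = ContingencyTable(TP=50, FP=7, FN=13, TN=40)
        swapped = ContingencyTable(TP=t.FP, FP=t.TP, FN=t.TN, TN=t.FN)
        assert dor(t) * dor(swapped) == pytest.approx(1.0)

    def test_ci_brackets_point_estimate(self):
        t = ContingencyTable(TP=2129, FP=29, FN=185, TN=2285)
        lo, hi = dor_ci95(t)
        assert lo < dor(t) < hi

    def test_zero_cells_require_continuity_policy(self):
        t = ContingencyTable(TP=10, FP=0, FN=5, TN=10)
        with pytest.raises(ZeroDivisionError):
            dor(t)
        assert dor(t, continuity=True) == pytest.approx(
            (10.5 * 10.5) / (0.5 * 5.5)
        )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(TP=-1, FP=0, FN=0, TN=0)
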