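"""Confusion-matrix metrics, AUC and threshold optimisation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import habsuit as hs
from habsuit.metrics import threshold_grid, tss_curve


class TestConfusion:
    def test_perfect_agreement(self):
        cm = hs.confusion([1, 1, 0, 0], [1, 1, 0, 0])
        assert (cm.a, cm.b, cm.c, cm.d) == (2, 0, 0, 2)

    def test_complement_predictions(self):
        cm = hs.confusion([0, 0, 1, 1], [1, 1, 0, 0])
        assert (cm.a, cm.d) == (0, 0)
        assert (cm.b, cm.c) == (2, 2)

    def test_mixed_cells(self):
        cm = hs.confusion([1, 0, 1, 0], [1, 1, 0, 0])
        assert (cm.a, cm.b, cm.c, cm.d) == (1, 1, 1, 1)

    def test_rejects_mismatched_or_nonbinary(self):
        with pytest.raises(hs.DataError):
            hs.confusion([1, 0], [1])
        with pytest.raises(hs.DataError):
            hs.confusion([2, 0], [1, 0])


class TestComputeMetrics:
    def test_balanced_hand_example(self):
        m = hs.compute_metrics(hs.ConfusionMatrix(40, 10, 10, 40))
        assert m == pytest.approx(
            {"kappa": 0.6, "cci": 0.8, "sn": 0.8, "sp": 0.8, "tss": 0.6})

    def test_unbalanced_hand_example(self):
        m = hs.compute_metrics(hs.ConfusionMatrix(45, 5, 15, 35))
        assert m == pytest.approx(
            {"kappa": 0.6, "cci": 0.8, "sn": 0.75, "sp": 0.875, "tss": 0.625})

    def test_perfect_classifier(self):
        m = hs.compute_metrics(hs.ConfusionMatrix(25, 0, 0, 25))
        assert all(v == pytest.approx(1.0) for v in m.values())

    def test_undefined_marginals_reported_as_nan_not_zero(self):
        m = hs.compute_metrics(hs.ConfusionMatrix(0, 3, 0, 7))  # no positives
        assert np.isnan(m["sn"]) and np.isnan(m["tss"])
        assert m["sp"] == pytest.approx(0.7)

    @given(st.tuples(*[st.integers(0, 200) for _ in range(4)])
           .filter(lambda t: t[0] + t[2] > 0 and t[1] + t[3] > 0))
    def test_tss_identity_and_kappa_oracle(self, cells):
        a, b, c, d = cells
        m = hs.compute_metrics(hs.ConfusionMatrix(a, b, c, d))
        assert m["tss"] == pytest.approx(m["sn"] + m["sp"] - 1.0, abs=1e-12)
        n = a + b + c + d
        pe = ((a + b) * (a + c) + (c + d) * (d + b)) / n**2
        if pe < 1.0:
            assert m["kappa"] == pytest.approx((m["cci"] - pe) / (1 - pe), abs=1e-12)

    @given(st.integers(0, 100), st.integers(0, 100), st.integers(1, 100))
    def test_kappa_equals_tss_on_marginal_balanced_matrices(self, a, d, k):
        # A+B = A+C requires b = c
        m = hs.compute_metrics(hs.ConfusionMatrix(a, k, k, d))
        if not np.isnan(m["kappa"]):
            assert m["kappa"] == pytest.approx(m["tss"], abs=1e-9)

    def test_kappa_matches_sklearn_on_random_matrices(self):
        from sklearn.metrics import cohen_kappa_score
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b, c, d = rng.integers(1, 60, 4)
            m = hs.compute_metrics(hs.ConfusionMatrix(a, b, c, d))
            obs = np.r_[np.ones(a + c), np.zeros(b + d)]
            pred = np.r_[np.ones(a), np.zeros(c), np.ones(b), np.zeros(d)]
            assert m["kappa"] == pytest.approx(cohen_kappa_score(obs, pred), abs=1e-9)


class TestAUC:
    def test_analytic_anchors(self):
        scores = np.r_[np.linspace(0.6, 1.0, 100), np.linspace(0.0, 0.4, 100)]
        labels = np.r_[np.ones(100), np.zeros(100)]
        assert hs.compute_auc(scores, labels) == 1.0
        assert hs.compute_auc(np.full(200, 0.5), labels) == 0.5

    def test_pair_enumeration_example(self):
        # positives {0.9, 0.4}, negatives {0.6, 0.1}: 3 of 4 pairs concordant
        assert hs.compute_auc([0.9, 0.4, 0.6, 0.1], [1, 1, 0, 0]) == 0.75

    def test_single_class_undefined(self):
        assert np.isnan(hs.compute_auc([0.3, 0.7], [1, 1]))

    @given(st.lists(st.tuples(st.floats(0, 1).map(lambda v: round(v, 3)),
                              st.booleans()),
                    min_size=4, max_size=40)
           .filter(lambda s: 0 < sum(l for _, l in s) < len(s)))
    def test_matches_all_pairs_oracle_and_monotone_invariance(self, scored):
        scores = np.array([s for s, _ in scored])
        labels = np.array([l for _, l in scored])
        auc = hs.compute_auc(scores, labels)
        pos, neg = scores[labels], scores[~labels]
        pairs = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
        assert auc == pytest.approx(pairs / (len(pos) * len(neg)), abs=1e-12)
        # strictly monotone transform leaves AUC unchanged
        assert hs.compute_auc(np.exp(3 * scores), labels) == pytest.approx(auc, abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(1)
        scores = rng.random(200)
        labels = rng.integers(0, 2, 200)
        assert hs.compute_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)


class TestOptimalThreshold:
    def test_separating_threshold_is_smallest_grid_point(self):
        thr, tss = hs.optimal_threshold([0.9, 0.7, 0.4, 0.2], [1, 1, 0, 0])
        assert thr == pytest.approx(0.41)
        assert tss == pytest.approx(1.0)

    def test_constant_scores_give_zero_tss_at_zero_threshold(self):
        thr, tss = hs.optimal_threshold([0.5] * 6, [1, 1, 1, 0, 0, 0])
        assert thr == 0.0
        assert tss == pytest.approx(0.0)

    def test_grid_contract(self):
        assert threshold_grid(0.5) == pytest.approx([0.0, 0.5, 1.0])
        thr, tss = hs.optimal_threshold([0.9, 0.1], [1, 0], grid_step=0.5)
        assert thr == 0.5

    def test_scan_agrees_with_per_threshold_metrics(self):
        rng = np.random.default_rng(2)
        scores = rng.random(60)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        thr_grid, curve = tss_curve(scores, labels)
        for t, tss in zip(thr_grid[::10], curve[::10]):
            cm = hs.confusion((scores >= t).astype(int), labels)
            assert tss == pytest.approx(hs.compute_metrics(cm)["tss"], abs=1e-12)
        best_thr, best_tss = hs.optimal_threshold(scores, labels)
        assert best_tss == pytest.approx(curve.max())
        assert best_thr == thr_grid[np.argmax(curve)]


class TestClassifyPerformance:
    @pytest.mark.parametrize("kappa, expected", [
        (0.61, "well-performing"), (0.6, "below-standard"), (0.2, "below-standard"),
    ])
    def test_kappa_bands(self, kappa, expected):
        assert hs.classify_performance(kappa=kappa)["kappa"] == expected

    @pytest.mark.parametrize("auc, expected", [
        (0.55, "poor"), (0.7, "reasonable"), (0.89, "reasonable"),
        (0.9, "very good"), (0.95, "very good"),
    ])
    def test_auc_bands_with_upper_edge_convention(self, auc, expected):
        assert hs.classify_performance(auc=auc)["auc"] == expected

    def test_accepts_a_full_report(self):
        report = hs.evaluate_scores([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        labels = hs.classify_performance(report)
        assert labels == {"kappa": "well-performing", "auc": "very good"}
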