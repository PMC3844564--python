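import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import auc, precision_recall_curve

from ppi_impact.centrality import centrality_table
from ppi_impact.model_eval import (
    CVConfig,
    aupr,
    aupr_from_scores,
    compare_paired,
    cross_validate,
    feature_importances,
    pr_curve,
    r50,
    random_baseline,
    rank_all_edges,
    score_edges,
    train_forest,
)

from conftest import random_network


class TestPRCurve:
    def test_single_positive_ranked_last(self):
        curve = pr_curve([0.9, 0.8, 0.7, 0.1], [0, 0, 0, 1])
        assert np.allclose(curve.recall, [0, 0, 0, 0, 1])
        assert np.allclose(curve.precision, [0, 0, 0, 0, 0.25])

    def test_perfect_ranking_ends_at_prevalence(self):
        curve = pr_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert curve.recall[0] == 0.0
        assert curve.recall[-1] == 1.0
        assert curve.precision[-1] == pytest.approx(0.5)  # full-list prevalence
        assert aupr(curve) == pytest.approx(1.0)

    def test_recall_non_decreasing(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            y = rng.integers(0, 2, size=30)
            if y.sum() in (0, 30):
                continue
            curve = pr_curve(rng.uniform(size=30), y)
            assert (np.diff(curve.recall) >= 0).all()

    def test_tied_scores_give_permutation_invariant_curve(self):
        scores = [0.9, 0.5, 0.5, 0.5, 0.1]
        labels_a = [1, 1, 0, 0, 1]
        labels_b = [1, 0, 0, 1, 1]  # permuted within the tie block
        ca, cb = pr_curve(scores, labels_a), pr_curve(scores, labels_b)
        assert np.allclose(ca.recall, cb.recall)
        assert np.allclose(ca.precision, cb.precision)

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            pr_curve([0.5, 0.4], [0, 0])


class TestAUPR:
    def test_single_positive_ranked_last_area(self):
        assert aupr_from_scores([0.9, 0.8, 0.7, 0.1], [0, 0, 0, 1]) == pytest.approx(
            0.125
        )

    def test_random_scores_near_prevalence_when_balanced(self):
        rng = np.random.default_rng(1)
        y = np.repeat([0, 1], 2000)
        value = aupr_from_scores(rng.uniform(size=4000), y)
        assert value == pytest.approx(0.5, abs=0.03)

    def test_agrees_with_sklearn_on_tie_free_input(self):
        # independent route: sklearn curve + trapezoid; conventions coincide
        # when scores are distinct and the top-ranked item is positive
        rng = np.random.default_rng(2)
        for _ in range(10):
            scores = rng.permutation(np.linspace(0.01, 0.99, 40))
            y = (rng.uniform(size=40) < 0.4).astype(int)
            top = int(np.argmax(scores))
            y[top] = 1
            if y.sum() == 40:
                y[int(np.argmin(scores))] = 0
            prec, rec, _ = precision_recall_curve(y, scores)
            expected = auc(rec[::-1], prec[::-1])
            assert aupr_from_scores(scores, y) == pytest.approx(expected, abs=1e-12)


class TestR50:
    def test_equals_aupr_when_few_negatives(self):
        rng = np.random.default_rng(3)
        y = np.concatenate([np.ones(60, int), np.zeros(50, int)])
        scores = rng.uniform(size=110)
        assert r50(scores, y) == pytest.approx(aupr_from_scores(scores, y), abs=1e-12)

    def test_perfect_ranking(self):
        y = np.concatenate([np.ones(10, int), np.zeros(60, int)])
        scores = np.linspace(1, 0, 70)
        assert r50(scores, y) == pytest.approx(1.0)
        assert aupr_from_scores(scores, y) == pytest.approx(1.0)

    def test_truncation_strictly_below_aupr(self):
        # 120 alternating items: the 51st negative appears at rank 102,
        # so recall past that point is lost to the truncated score
        y = np.tile([1, 0], 60)
        scores = np.linspace(1, 0, 120)
        assert r50(scores, y) < aupr_from_scores(scores, y)

    def test_bounds_hold_on_random_draws(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            n = int(rng.integers(10, 200))
            y = rng.integers(0, 2, size=n)
            if y.sum() in (0, n):
                continue
            s = rng.uniform(size=n)
            lo, hi = r50(s, y), aupr_from_scores(s, y)
            assert 0.0 <= lo <= hi <= 1.0


class TestTrainForest:
    def test_separable_signal_is_learned(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(size=(400, 17))
        y = (X[:, 16] > 0.5).astype(int)
        model = train_forest(X, y, CVConfig(seed=0))
        assert aupr_from_scores(score_edges(model, X), y) >= 0.99

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        X = rng.uniform(size=(200, 17))
        y = rng.integers(0, 2, size=200)
        s1 = score_edges(train_forest(X, y, CVConfig(seed=9)), X)
        s2 = score_edges(train_forest(X, y, CVConfig(seed=9)), X)
        assert np.array_equal(s1, s2)

    def test_single_class_rejected(self):
        X = np.zeros((10, 17))
        with pytest.raises(ValueError):
            train_forest(X, np.zeros(10, int), CVConfig())

    def test_permuted_labels_score_at_prevalence(self):
        rng = np.random.default_rng(7)
        X = rng.uniform(size=(600, 17))
        y = rng.permutation(np.repeat([0, 1], 300))
        res = cross_validate(X, y, CVConfig(folds=5, repeats=2, seed=1))
        assert res.mean_aupr["forest"] == pytest.approx(0.5, abs=0.05)


class TestFeatureImportances:
    def test_planted_informative_feature_dominates(self):
        rng = np.random.default_rng(8)
        X = rng.uniform(size=(500, 17))
        y = (X[:, 4] > 0.6).astype(int)
        model = train_forest(X, y, CVConfig(seed=2))
        imp = feature_importances(model)
        assert imp.argmax() == 4
        assert imp.sum() == pytest.approx(1.0, abs=1e-6)
        assert (imp >= 0).all()

    def test_all_noise_has_no_dominant_feature(self):
        rng = np.random.default_rng(9)
        X = rng.uniform(size=(500, 17))
        y = rng.integers(0, 2, size=500)
        imp = feature_importances(train_forest(X, y, CVConfig(seed=3)))
        assert imp.max() <= 3 * imp.mean()

    def test_untrained_model_rejected(self):
        from sklearn.ensemble import RandomForestClassifier

        with pytest.raises(ValueError):
            feature_importances(RandomForestClassifier())


class TestRandomBaseline:
    def test_open_interval_and_reproducibility(self):
        a = random_baseline(1000, seed=42)
        b = random_baseline(1000, seed=42)
        assert np.array_equal(a, b)
        assert ((a > 0) & (a < 1)).all()

    def test_uniformity(self):
        draws = random_baseline(10_000, seed=0)
        d, _ = stats.kstest(draws, "uniform")
        assert d < 0.05


class TestCrossValidate:
    def test_planted_signal_beats_random(self):
        rng = np.random.default_rng(10)
        X = rng.uniform(size=(500, 17))
        y = (X[:, 16] + 0.3 * rng.standard_normal(500) > 0.5).astype(int)
        res = cross_validate(X, y, CVConfig(folds=5, repeats=2, seed=4))
        assert res.mean_aupr["forest"] > res.mean_aupr["random"]
        assert res.p_value < 0.01
        assert len(res.aupr["forest"]) == 10

    def test_too_few_positives_rejected(self):
        X = np.zeros((100, 17))
        y = np.zeros(100, int)
        y[:3] = 1
        with pytest.raises(ValueError, match="folds"):
            cross_validate(X, y, CVConfig(folds=10, repeats=1))

    def test_per_fold_metrics_bounded(self):
        rng = np.random.default_rng(11)
        X = rng.uniform(size=(200, 17))
        y = rng.permutation(np.repeat([0, 1], 100))
        res = cross_validate(X, y, CVConfig(folds=4, repeats=2, seed=5))
        for method in ("forest", "random"):
            assert (res.r50[method] <= res.aupr[method] + 1e-12).all()
            assert (res.aupr[method] >= 0).all()
            assert (res.aupr[method] <= 1).all()


class TestComparePaired:
    def test_identical_lists(self):
        a = np.linspace(0.1, 0.9, 20)
        with pytest.warns(UserWarning):
            assert compare_paired(a, a) == 1.0

    def test_uniform_shift_is_detected(self):
        rng = np.random.default_rng(12)
        b = rng.uniform(0.2, 0.6, size=200)
        assert compare_paired(b + 0.1, b) < 1e-6

    def test_swap_symmetry(self):
        rng = np.random.default_rng(13)
        a = rng.uniform(size=50)
        b = rng.uniform(size=50)
        assert compare_paired(a, b) == pytest.approx(compare_paired(b, a))

    def test_short_lists_rejected(self):
        with pytest.raises(ValueError):
            compare_paired([0.1] * 3, [0.2] * 3)


class TestRankAllEdges:
    def test_totality_determinism_and_tie_order(self):
        rng = np.random.default_rng(14)
        net = random_network(rng, 30, 0.15)
        table = centrality_table(net)
        from ppi_impact.dataset import feature_matrix

        X = feature_matrix(table, net.edges)
        y = (X[:, 16] > np.median(X[:, 16])).astype(int)
        if y.sum() in (0, len(y)):
            pytest.skip("degenerate random draw")
        model = train_forest(X, y, CVConfig(seed=6))
        r1 = rank_all_edges(model, net, table)
        r2 = rank_all_edges(model, net, table)
        assert r1 == r2
        assert len(r1) == len(net.edges)
        scores = [s for _, s in r1]
        assert scores == sorted(scores, reverse=True)
        for (e1, s1), (e2, s2) in zip(r1, r1[1:]):
            if s1 == s2:
                assert e1 < e2
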