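"""Split, standardization, IRLS logistic fit, PR curve, threshold, CV."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.special import expit
from sklearn.base import clone
from sklearn.metrics import precision_recall_curve as sk_pr_curve

import sfindex as sf
from sfindex.errors import (
    DegenerateFeatureError,
    EmptyBandError,
    PerfectSeparationError,
    StratificationError,
)
from .conftest import brute_force_best_f1, brute_force_pr


def make_dataset(X, y):
    return sf.TrainingDataset(pd.DataFrame(np.asarray(X, dtype=float)), np.asarray(y))


class TestSplitDataset:
    def test_split_sizes_at_n106(self, small_training_data):
        train, test = sf.split_dataset(small_training_data, 0.7, seed=0)
        assert small_training_data.n == 106
        assert train.n in (74, 75)
        assert train.n + test.n == 106
        # stratified: class ratio preserved up to rounding
        assert abs(np.bincount(train.target)[0] - np.bincount(train.target)[1]) <= 1

    def test_balanced_split_preserves_class_balance(self):
        data = make_dataset(np.arange(20).reshape(10, 2), [0] * 5 + [1] * 5)
        train, test = sf.split_dataset(data, 0.5, seed=3)
        assert np.bincount(train.target)[0] == np.bincount(train.target)[1]
        assert np.bincount(test.target)[0] == np.bincount(test.target)[1]
        assert train.n + test.n == 10

    def test_same_seed_identical_split(self, small_training_data):
        a = sf.split_dataset(small_training_data, 0.7, seed=42)
        b = sf.split_dataset(small_training_data, 0.7, seed=42)
        pd.testing.assert_frame_equal(a[0].features, b[0].features)
        np.testing.assert_array_equal(a[1].target, b[1].target)

    def test_tiny_class_impossible(self):
        data = make_dataset(np.zeros((5, 1)), [0, 0, 0, 0, 1])
        with pytest.raises(StratificationError):
            sf.split_dataset(data, 0.7, seed=0)


class TestStandardize:
    def test_population_sd_convention(self):
        z, params = sf.standardize(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(z.ravel(), [-1.224744871, 0.0, 1.224744871], atol=1e-9)
        assert params.sd[0] == pytest.approx(np.sqrt(2.0 / 3.0))

    def test_training_columns_zero_mean_unit_sd(self, small_training_data):
        z, _ = sf.standardize(small_training_data.features)
        np.testing.assert_allclose(np.asarray(z).mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(np.asarray(z).std(axis=0), 1.0, atol=1e-9)

    def test_constant_column_degenerate(self):
        with pytest.raises(DegenerateFeatureError):
            sf.standardize(np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]]))

    def test_stored_params_reproduce_training_zscores(self):
        X = np.random.default_rng(0).normal(3.0, 2.0, size=(30, 3))
        z1, params = sf.standardize(X)
        z2, _ = sf.standardize(X, params=params)
        np.testing.assert_allclose(z1, z2)

    def test_no_leakage_shifted_test_set(self):
        rng = np.random.default_rng(1)
        train = rng.normal(0.0, 1.0, size=(50, 3))
        test = train + 5.0  # same shape, shifted distribution
        _, params = sf.standardize(train)
        z_test, _ = sf.standardize(test, params=params)
        # if test statistics leaked, the transformed mean would be ~0
        assert np.all(np.abs(np.asarray(z_test).mean(axis=0)) > 1.0)


class TestFitLogistic:
    def test_odds_ratios_are_exp_coefficients(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((200, 3))
        y = (rng.random(200) < expit(X @ [0.5, -0.3, 1.0])).astype(int)
        fit = sf.fit_logistic(X, y)
        np.testing.assert_allclose(fit.odds_ratios, np.exp(fit.coefficients))

    def test_symmetric_two_point_data_zero_intercept(self):
        X = np.array([[-1.0], [1.0]] * 50)
        y = np.array([0, 1] * 50)
        fit = sf.fit_logistic(X, y, ridge=0.01)
        assert fit.intercept == pytest.approx(0.0, abs=1e-6)

    def test_matches_statsmodels_unweighted(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        X = rng.standard_normal((300, 3))
        y = (rng.random(300) < expit(X @ [0.8, -0.5, 0.2] + 0.3)).astype(int)
        ours = sf.fit_logistic(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(ours.intercept, ref.params[0], atol=1e-6)
        np.testing.assert_allclose(ours.coefficients, ref.params[1:], atol=1e-6)

    def test_parameter_recovery_and_shrinking_error(self):
        true = np.array([1.0, 3.0, 0.5])

        def recover(n, seed):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((n, 3))
            y = (rng.random(n) < expit(X @ true)).astype(int)
            return sf.fit_logistic(X, y).coefficients

        # average over a few seeds so the check targets bias, not one draw
        small = np.mean([recover(500, s) for s in range(5)], axis=0)
        large = np.mean([recover(5000, s) for s in range(5)], axis=0)
        assert np.max(np.abs(large - true) / true) < 0.10
        assert np.linalg.norm(large - true) < np.linalg.norm(small - true)

    def test_perfect_separation_without_ridge_raises(self):
        X = np.array([[-2.0], [-1.5], [1.5], [2.0]] * 5)
        y = np.array([0, 0, 1, 1] * 5)
        with pytest.raises(PerfectSeparationError):
            sf.fit_logistic(X, y, ridge=0.0)
        fit = sf.fit_logistic(X, y, ridge=0.1)  # penalized fit is fine
        assert fit.converged

    def test_class_weighting_lifts_minority_recall(self):
        rng = np.random.default_rng(7)
        n0, n1 = 450, 50  # 9:1 imbalance, minority positive
        X = np.concatenate([rng.normal(0, 1, n0), rng.normal(1.5, 1, n1)]).reshape(-1, 1)
        y = np.array([0] * n0 + [1] * n1)
        p_unw = expit(
            X @ sf.fit_logistic(X, y).coefficients + sf.fit_logistic(X, y).intercept
        )
        fit_w = sf.fit_logistic(X, y, class_weights="balanced")
        p_w = expit(X @ fit_w.coefficients + fit_w.intercept)
        recall = lambda p: ((p.ravel() >= 0.5) & (y == 1)).sum() / (y == 1).sum()
        assert recall(p_w) > recall(p_unw)


class TestPrCurve:
    def test_worked_confusion_matrix_example(self):
        # any threshold in (0.4, 0.8] calls exactly {0.9, 0.8} positive:
        # TP=2, FP=0, FN=1 → precision 1, recall 2/3
        curve = sf.pr_curve([0.9, 0.8, 0.4, 0.2], [1, 1, 0, 1])
        i = list(curve.thresholds).index(0.8)
        assert curve.precision[i] == pytest.approx(1.0)
        assert curve.recall[i] == pytest.approx(2.0 / 3.0)

    def test_endpoint_conventions(self):
        curve = sf.pr_curve([0.9, 0.8, 0.4, 0.2], [1, 1, 0, 1])
        assert curve.recall[curve.thresholds == 0.0] == 1.0  # everything positive
        assert curve.precision[curve.thresholds == 1.0] == 1.0  # empty-positive
        assert curve.recall[curve.thresholds == 1.0] == 0.0

    @given(
        data=st.lists(
            st.tuples(st.floats(0.001, 0.999), st.integers(0, 1)),
            min_size=3,
            max_size=20,
        ).filter(lambda d: len({y for _, y in d}) == 2)
    )
    def test_equals_brute_force_and_recall_monotone(self, data):
        scores = [s for s, _ in data]
        labels = [y for _, y in data]
        curve = sf.pr_curve(scores, labels)
        oracle = brute_force_pr(scores, labels, list(curve.thresholds))
        for (t, p, r), tp, tr in zip(oracle, curve.precision, curve.recall):
            assert tp == pytest.approx(p)
            assert tr == pytest.approx(r)
        assert np.all(np.diff(curve.recall) <= 1e-12)

    def test_agrees_with_sklearn_at_shared_thresholds(self):
        rng = np.random.default_rng(5)
        scores = rng.random(50)
        labels = (rng.random(50) < scores).astype(int)
        curve = sf.pr_curve(scores, labels)
        skp, skr, skt = sk_pr_curve(labels, scores)
        ours = {t: (p, r) for t, p, r in curve.triples()}
        for t, p, r in zip(skt, skp[:-1], skr[:-1]):
            assert ours[t][0] == pytest.approx(p)
            assert ours[t][1] == pytest.approx(r)


class TestSelectThreshold:
    def test_unique_perfect_threshold(self):
        curve = sf.pr_curve([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        t = sf.select_threshold(curve)
        p, r = dict(zip(curve.thresholds, zip(curve.precision, curve.recall)))[t]
        assert p == 1.0 and r == 1.0

    def test_ties_resolve_to_lowest_threshold(self):
        # thresholds 0.0 and 0.3 predict identically here → identical F1; lowest wins
        curve = sf.pr_curve([0.3, 0.7], [1, 0])
        assert sf.select_threshold(curve) == 0.0

    def test_band_restricts_search(self):
        scores = [0.1, 0.2, 0.8, 0.9]
        curve = sf.pr_curve(scores, [0, 0, 1, 1])
        t = sf.select_threshold(curve, band=(0.15, 0.25))
        assert 0.15 <= t <= 0.25

    def test_empty_band_errors(self):
        curve = sf.pr_curve([0.1, 0.9], [0, 1])
        with pytest.raises(EmptyBandError):
            sf.select_threshold(curve, band=(0.3, 0.4))

    @given(
        data=st.lists(
            st.tuples(st.floats(0.001, 0.999), st.integers(0, 1)),
            min_size=3,
            max_size=20,
        ).filter(lambda d: len({y for _, y in d}) == 2)
    )
    def test_matches_brute_force_f1_oracle(self, data):
        scores = [s for s, _ in data]
        labels = [y for _, y in data]
        assert sf.select_threshold(sf.pr_curve(scores, labels)) == pytest.approx(
            brute_force_best_f1(scores, labels)
        )

    def test_asymmetric_separation_selects_below_half(self):
        # majority-positive Gaussian scores: F1 optimum sits below 0.5
        rng = np.random.default_rng(9)
        pos = np.clip(rng.normal(0.55, 0.15, 70), 0.01, 0.99)
        neg = np.clip(rng.normal(0.25, 0.10, 30), 0.01, 0.99)
        scores = np.concatenate([pos, neg])
        labels = np.array([1] * 70 + [0] * 30)
        t = sf.select_threshold(sf.pr_curve(scores, labels))
        assert t < 0.5
        assert t == pytest.approx(brute_force_best_f1(scores, labels))


class TestExpressionClassifier:
    def test_fit_predict_and_artifact_roundtrip(self, small_training_data):
        train, test = sf.split_dataset(small_training_data, 0.7, seed=1)
        clf = sf.ExpressionClassifier(ridge=0.01, optimize_threshold=True)
        clf.fit(train.features, train.target)
        assert 0 < clf.decision_threshold_ < 1
        np.testing.assert_allclose(clf.odds_ratios_, np.exp(clf.coef_))
        # HDAC4 should carry the dominant odds ratio under default simulation
        names = list(train.features.columns)
        assert names[int(np.argmax(clf.coef_))] == "delta_hdac4"
        restored = sf.ExpressionClassifier.from_artifact(clf.to_artifact())
        np.testing.assert_array_equal(
            restored.predict(test.features), clf.predict(test.features)
        )

    def test_sklearn_clone_compatible(self):
        clf = sf.ExpressionClassifier(ridge=0.5, decision_threshold=0.4)
        cloned = clone(clf)
        assert cloned.get_params()["ridge"] == 0.5
        assert cloned.get_params()["decision_threshold"] == 0.4


class TestEvaluate:
    def test_perfect_and_degenerate_predictions(self):
        data = sf.simulate_training(sf.TrainingSimConfig(n_per_class=20, seed=5))
        clf = sf.ExpressionClassifier(ridge=0.01).fit(data.features, data.target)
        report = sf.evaluate(clf, data, split="train")
        assert report.tp + report.fp + report.fn + report.tn == data.n
        if report.fp == 0 and report.fn == 0:
            assert report.precision == report.recall == report.accuracy == 1.0

    def test_all_negative_predictions_zero_recall(self, small_training_data):
        clf = sf.ExpressionClassifier(ridge=0.01).fit(
            small_training_data.features, small_training_data.target
        )
        clf.decision_threshold_ = 1.5  # unreachable by any probability → all-negative
        report = sf.evaluate(clf, small_training_data)
        assert report.recall == 0.0
        assert report.tp == 0

    def test_matches_brute_force_confusion_counts(self):
        data = sf.simulate_training(sf.TrainingSimConfig(n_per_class=10, seed=13))
        clf = sf.ExpressionClassifier(ridge=0.05).fit(data.features, data.target)
        report = sf.evaluate(clf, data, split="train")
        pred = clf.predict(data.features)
        tp = sum(1 for p, y in zip(pred, data.target) if p == 1 and y == 1)
        fp = sum(1 for p, y in zip(pred, data.target) if p == 1 and y == 0)
        fn = sum(1 for p, y in zip(pred, data.target) if p == 0 and y == 1)
        tn = sum(1 for p, y in zip(pred, data.target) if p == 0 and y == 0)
        assert (report.tp, report.fp, report.fn, report.tn) == (tp, fp, fn, tn)
        assert report.accuracy == pytest.approx((tp + tn) / data.n)


class TestCrossValidate:
    def test_leave_one_out_on_tiny_stratified_data_impossible(self):
        data = make_dataset(np.arange(8).reshape(4, 2), [0, 0, 1, 1])
        with pytest.raises(StratificationError):
            sf.cross_validate(data, k=4, seed=0)

    def test_separable_data_perfect_folds(self):
        rng = np.random.default_rng(21)
        X = rng.normal(0.0, 1.0, size=(60, 3))
        y = np.array([0] * 30 + [1] * 30)
        X[y == 1] += 10.0  # far-separated classes in every feature
        reports = sf.cross_validate(
            make_dataset(X, y), k=2, seed=1, ridge=0.01
        )
        assert len(reports) == 2
        assert all(r.accuracy == 1.0 for r in reports)

    def test_folds_partition_data_evenly(self, small_training_data):
        k = 5
        reports = sf.cross_validate(small_training_data, k=k, seed=2, ridge=0.01)
        sizes = [r.tp + r.fp + r.fn + r.tn for r in reports]
        assert sum(sizes) == small_training_data.n
        assert max(sizes) - min(sizes) <= 2  # ≤1 per class, 2 classes
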