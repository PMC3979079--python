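"""Whitening, outlier trimming, k-NN, cross-validation, metrics, Yates intervals."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2

from conftest import gaussian_classes
from sfdikit.classify import (
    LabeledFeatureSet,
    compute_metrics,
    crossvalidate,
    fit_whitening,
    knn_predict,
    remove_outliers,
    roc_over_k,
    to_binary_task,
    yates_interval,
)


def feature_set(feats, labels):
    return LabeledFeatureSet(np.asarray(feats, float), np.asarray(labels))


class TestWhitening:
    def test_transformed_training_data_has_identity_covariance(self):
        x, y = gaussian_classes(2, 200, 5, 2.0, seed=0)
        x[:, 2] *= 50  # anisotropic scales
        data = feature_set(x, y)
        wt = fit_whitening(data)
        cov = np.cov(wt.apply(x), rowvar=False)
        assert np.allclose(cov, np.eye(5), atol=1e-8)

    def test_per_feature_rescaling_leaves_whitened_geometry_unchanged(self):
        # whitened coordinates are defined up to rotation, so the invariant
        # content is the pairwise-distance geometry the classifier sees
        x, y = gaussian_classes(2, 100, 5, 2.0, seed=1)
        scaled = x.copy()
        scaled[:, 0] *= 1000
        w1 = fit_whitening(feature_set(x, y)).apply(x)
        w2 = fit_whitening(feature_set(scaled, y)).apply(scaled)
        d1 = np.linalg.norm(w1[:, None] - w1[None, :], axis=-1)
        d2 = np.linalg.norm(w2[:, None] - w2[None, :], axis=-1)
        assert np.allclose(d1, d2, atol=1e-8)

    def test_already_white_data_gives_near_identity_transform(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((10_000, 5))
        wt = fit_whitening(feature_set(x, ["a"] * 5000 + ["b"] * 5000))
        assert np.max(np.abs(wt.matrix - np.eye(5))) < 0.05

    def test_singular_covariance_requires_ridge(self):
        x = np.zeros((10, 3))
        x[:, 0] = np.arange(10)
        data = feature_set(x, ["a"] * 10)
        with pytest.raises(ValueError, match="singular"):
            fit_whitening(data, ridge=False)
        wt = fit_whitening(data)  # ridge path succeeds
        assert np.isfinite(wt.matrix).all()


class TestOutlierRemoval:
    def test_zero_target_is_a_no_op(self):
        x, y = gaussian_classes(2, 50, 5, 1.0, seed=3)
        data = feature_set(x, y)
        assert remove_outliers(data, 0.0) is data

    def test_five_percent_budget_removes_about_five_percent(self):
        rng = np.random.default_rng(4)
        x = rng.standard_t(df=2, size=(2000, 5))  # heavy tails
        data = feature_set(x, ["a"] * 1000 + ["b"] * 1000)
        kept = remove_outliers(data, 0.05)
        removed = len(data.labels) - len(kept.labels)
        assert 0.035 * len(data.labels) <= removed <= 0.05 * len(data.labels) + 0.5

    def test_gross_outlier_always_removed(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((100, 5))
        q1, q3 = np.percentile(x[:, 0], [25, 75])
        x[0, 0] = q3 + 20 * (q3 - q1)
        data = feature_set(x, ["a"] * 100)
        kept = remove_outliers(data, 0.02)
        assert x[0, 0] not in kept.features[:, 0]

    def test_budget_above_twenty_percent_rejected(self):
        x, y = gaussian_classes(2, 20, 3, 1.0, seed=6)
        with pytest.raises(ValueError, match="target_fraction"):
            remove_outliers(feature_set(x, y), 0.3)


class TestKnn:
    def test_query_equal_to_training_point_returns_its_label(self):
        x, y = gaussian_classes(3, 30, 5, 3.0, seed=7)
        data = feature_set(x, y)
        assert knn_predict(x[17], data, k=1) == y[17]

    def test_well_separated_classes_classified_almost_perfectly(self):
        x, y = gaussian_classes(2, 400, 5, 6.0, seed=8)
        train = feature_set(x[::2], y[::2])
        pred = knn_predict(x[1::2], train, k=9)
        assert np.mean(pred != y[1::2]) <= 0.01

    def test_tree_search_equals_brute_force_scan(self):
        rng = np.random.default_rng(9)
        x, y = gaussian_classes(4, 250, 5, 1.0, seed=9)
        train = feature_set(x, y)
        queries = rng.standard_normal((1000, 5)) * 2
        for k in (1, 5, 9):
            pred = knn_predict(queries, train, k=k)
            # brute-force oracle with identical tie rule
            d2 = ((queries[:, None, :] - x[None, :, :]) ** 2).sum(-1)
            for i in range(len(queries)):
                order = np.lexsort((np.arange(len(x)), d2[i]))[:k]
                neigh = y[order]
                classes, counts = np.unique(neigh, return_counts=True)
                tied = set(classes[counts == counts.max()])
                want = next(lab for lab in neigh if lab in tied)
                assert pred[i] == want

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            knn_predict(np.zeros(5), feature_set(np.empty((0, 5)), []), k=1)


class TestCrossValidation:
    def test_separable_classes_reach_perfect_accuracy(self):
        x, y = gaussian_classes(3, 30, 5, 60.0, seed=10, sd=0.1)
        rep = crossvalidate(feature_set(x, y), k=3, seed=0)
        assert rep.accuracy == 1.0
        assert np.all(rep.confusion == np.diag(np.diag(rep.confusion)))

    def test_folds_have_equal_per_class_counts_and_remainders_dropped(self):
        x, y = gaussian_classes(3, 31, 5, 2.0, seed=11)  # 31 = 3*10 + 1 per class
        rep = crossvalidate(feature_set(x, y), k=3, seed=1)
        assert rep.fold_sizes == {"C0": 10, "C1": 10, "C2": 10}
        assert rep.dropped == 3
        assert rep.confusion.sum() == 90

    def test_confusion_percentages_sum_to_one_hundred(self):
        x, y = gaussian_classes(4, 30, 5, 2.0, seed=12)
        rep = crossvalidate(feature_set(x, y), k=5, seed=2)
        assert rep.confusion_percent.sum() == pytest.approx(100.0)

    def test_deterministic_for_fixed_seed(self):
        x, y = gaussian_classes(3, 40, 5, 1.5, seed=13)
        r1 = crossvalidate(feature_set(x, y), k=7, seed=5)
        r2 = crossvalidate(feature_set(x, y), k=7, seed=5)
        assert np.array_equal(r1.confusion, r2.confusion)
        assert r1.accuracy == r2.accuracy

    def test_class_with_too_few_samples_rejected(self):
        x = np.random.default_rng(14).standard_normal((8, 5))
        y = ["a"] * 6 + ["b"] * 2
        with pytest.raises(ValueError, match="fewer than"):
            crossvalidate(feature_set(x, y), k=1)


class TestMetrics:
    def test_hand_checked_two_class_confusion(self):
        df = compute_metrics(np.array([[8, 2], [1, 9]]), ["pos", "neg"])
        row = df[df["class"] == "pos"].iloc[0]
        assert row["sensitivity"] == pytest.approx(0.8)
        assert row["specificity"] == pytest.approx(0.9)
        assert row["ppv"] == pytest.approx(8 / 9)
        assert df.attrs["accuracy"] == pytest.approx(0.85)

    def test_diagonal_confusion_gives_perfect_metrics(self):
        df = compute_metrics(np.diag([5, 7, 3]), ["a", "b", "c"])
        for col in ("sensitivity", "specificity", "ppv", "npv"):
            assert np.allclose(df[col], 1.0)
        assert df.attrs["accuracy"] == 1.0

    def test_empty_predicted_column_flags_undefined_ppv(self):
        df = compute_metrics(np.array([[0, 5], [0, 5]]), ["a", "b"])
        row = df[df["class"] == "a"].iloc[0]
        assert np.isnan(row["ppv"])
        assert row["undefined"]


class TestYatesInterval:
    def test_boundaries_are_closed_at_zero_and_n(self):
        lo, hi = yates_interval(10, 10)
        assert hi == 1.0
        lo0, hi0 = yates_interval(0, 10)
        assert lo0 == 0.0

    @given(st.integers(min_value=1, max_value=500), st.data())
    @settings(max_examples=200, deadline=None)
    def test_interval_contains_the_point_estimate(self, n, data):
        x = data.draw(st.integers(min_value=0, max_value=n))
        lo, hi = yates_interval(x, n)
        assert lo <= x / n <= hi
        assert 0.0 <= lo <= hi <= 1.0

    def test_endpoints_match_chi_square_test_inversion(self):
        # brute-force inversion of the continuity-corrected test
        from scipy.optimize import brentq

        crit = chi2.ppf(0.95, df=1)

        def stat(p, x, n):
            return (max(abs(x - n * p) - 0.5, 0.0)) ** 2 / (n * p * (1 - p)) - crit

        for n in (10, 25, 50, 117):
            for x in {1, n // 3, n // 2, n - 1}:
                lo, hi = yates_interval(x, n)
                lo_oracle = brentq(stat, 1e-12, x / n, args=(x, n), xtol=1e-13)
                hi_oracle = brentq(stat, x / n, 1 - 1e-12, args=(x, n), xtol=1e-13)
                assert lo == pytest.approx(lo_oracle, abs=1e-6)
                assert hi == pytest.approx(hi_oracle, abs=1e-6)


class TestRocOverK:
    def _binary_blobs(self, n_pos, n_neg, sep, seed, sd=1.0):
        rng = np.random.default_rng(seed)
        pos = sd * rng.standard_normal((n_pos, 5)) + sep
        neg = sd * rng.standard_normal((n_neg, 5))
        return feature_set(
            np.vstack([pos, neg]), ["malignant"] * n_pos + ["benign"] * n_neg
        )

    def test_single_class_data_refused(self):
        x = np.random.default_rng(15).standard_normal((30, 5))
        with pytest.raises(ValueError):
            roc_over_k(feature_set(x, ["benign"] * 30), k_values=(1, 3))

    def test_widely_separated_classes_give_near_perfect_operating_points(self):
        # after total-covariance whitening a binary separation is compressed to
        # ~2 whitened units against unit orthogonal noise, so a small residual
        # error floor is intrinsic; operating points must still be near (1, 1)
        data = self._binary_blobs(60, 60, sep=50.0, seed=16, sd=0.1)
        df = roc_over_k(data, k_values=(1, 3, 5))
        assert np.all(df["sensitivity"] >= 0.97)
        assert np.all(df["specificity"] >= 0.97)
        best = df.loc[df["youden"].idxmax()]
        assert df.attrs["optimal_k"] == best["k"]

    def test_sensitivity_specificity_trade_off_with_k_under_imbalance(self):
        # minority positives: larger k dilutes their votes
        data = self._binary_blobs(30, 150, sep=1.2, seed=17)
        df = roc_over_k(data, k_values=(1, 21))
        s1 = df[df.k == 1].iloc[0]
        s21 = df[df.k == 21].iloc[0]
        assert s21["sensitivity"] < s1["sensitivity"]
        assert s21["specificity"] > s1["specificity"]

    def test_even_k_rejected(self):
        data = self._binary_blobs(20, 20, 2.0, 18)
        with pytest.raises(ValueError, match="odd"):
            roc_over_k(data, k_values=(2, 4))


def test_pathology_subtype_labels_collapse_to_benign_malignant():
    x = np.zeros((5, 5))
    data = feature_set(x, ["NOR", "FA", "DCIS", "INV", "INV_RX"])
    binary = to_binary_task(data)
    assert list(binary.labels) == ["benign", "benign", "malignant", "malignant", "malignant"]
    with pytest.raises(ValueError, match="outside"):
        to_binary_task(feature_set(x, ["NOR", "FA", "DCIS", "INV", "weird"]))
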