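"""Bhattacharyya separability, SFFS ranking, and spectral-IHC correlates."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from conftest import gaussian_classes
from sfdikit.classify import LabeledFeatureSet
from sfdikit.ranking import (
    ClassSummary,
    bhattacharyya_pair,
    generalized_separability,
    pearson_correlates,
    sffs_rank,
)


def bhattacharyya_quadrature(mu1, s1, mu2, s2):
    """-ln of the Bhattacharyya coefficient of two 1-D normals, by quadrature."""

    def integrand(x):
        p = np.exp(-0.5 * ((x - mu1) / s1) ** 2) / (s1 * np.sqrt(2 * np.pi))
        q = np.exp(-0.5 * ((x - mu2) / s2) ** 2) / (s2 * np.sqrt(2 * np.pi))
        return np.sqrt(p * q)

    bc, _ = quad(integrand, -50, 50, limit=200)
    return -np.log(bc)


def summary_1d(mu, var):
    return ClassSummary(np.array([mu]), np.array([[var]]))


class TestBhattacharyya:
    def test_identical_distributions_have_zero_distance(self):
        s = ClassSummary(np.array([1.0, 2.0]), np.eye(2))
        assert bhattacharyya_pair(s, s) == pytest.approx(0.0, abs=1e-12)

    def test_unit_variance_mean_shift_matches_closed_form_and_quadrature(self):
        # mu 0 vs 2, sigma^2 = 1 both: J = (1/8) * 4 / 1 = 0.5, mean term only
        j = bhattacharyya_pair(summary_1d(0.0, 1.0), summary_1d(2.0, 1.0))
        assert j == pytest.approx(0.5, rel=1e-12)
        assert j == pytest.approx(bhattacharyya_quadrature(0, 1, 2, 1), abs=1e-3)

    @pytest.mark.parametrize(
        "mu1,s1,mu2,s2",
        [(0.0, 1.0, 1.5, 2.0), (-1.0, 0.5, 1.0, 0.5), (0.0, 1.0, 0.0, 3.0)],
    )
    def test_one_dimensional_form_matches_quadrature_oracle(self, mu1, s1, mu2, s2):
        j = bhattacharyya_pair(summary_1d(mu1, s1**2), summary_1d(mu2, s2**2))
        assert j == pytest.approx(bhattacharyya_quadrature(mu1, s1, mu2, s2), abs=1e-3)

    def test_invariant_under_invertible_linear_maps(self):
        rng = np.random.default_rng(0)
        mu1, mu2 = rng.standard_normal(3), rng.standard_normal(3)
        a1 = rng.standard_normal((3, 3))
        a2 = rng.standard_normal((3, 3))
        c1 = a1 @ a1.T + 0.5 * np.eye(3)
        c2 = a2 @ a2.T + 0.5 * np.eye(3)
        j0 = bhattacharyya_pair(ClassSummary(mu1, c1), ClassSummary(mu2, c2))
        for _ in range(5):
            m = rng.standard_normal((3, 3)) + 2 * np.eye(3)
            jt = bhattacharyya_pair(
                ClassSummary(m @ mu1, m @ c1 @ m.T), ClassSummary(m @ mu2, m @ c2 @ m.T)
            )
            assert jt == pytest.approx(j0, rel=1e-8, abs=1e-8)


class TestGeneralizedSeparability:
    def test_identical_classes_give_zero(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((200, 3))
        data = LabeledFeatureSet(np.vstack([x, x]), ["a"] * 200 + ["b"] * 200)
        assert generalized_separability(data) == pytest.approx(0.0, abs=1e-12)

    def test_single_class_rejected(self):
        x = np.random.default_rng(2).standard_normal((50, 3))
        with pytest.raises(ValueError):
            generalized_separability(LabeledFeatureSet(x, ["a"] * 50))

    def test_independent_noise_feature_barely_changes_j(self):
        x, y = gaussian_classes(3, 4000, 3, 2.0, seed=3)
        rng = np.random.default_rng(4)
        with_noise = np.column_stack([x, rng.standard_normal(len(x))])
        d0 = LabeledFeatureSet(x, y)
        d1 = LabeledFeatureSet(with_noise, y, feature_names=("a", "b", "c", "noise"))
        j0 = generalized_separability(d0)
        j1 = generalized_separability(d1)
        assert abs(j1 - j0) / j0 < 0.05

    def test_prior_weighting_uses_class_fractions(self):
        # doubling one class's samples changes the priors, hence J
        x, y = gaussian_classes(2, 100, 2, 2.0, seed=5)
        dup = LabeledFeatureSet(
            np.vstack([x, x[y == "C0"]]), np.concatenate([y, y[y == "C0"]])
        )
        j_bal = generalized_separability(LabeledFeatureSet(x, y))
        j_dup = generalized_separability(dup)
        # priors (2/3, 1/3): 2*P1*P2 = 4/9 < 1/2, with near-identical pair distance
        assert j_dup < j_bal


class TestSFFS:
    def test_single_informative_feature_ranked_first(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 300
            informative = np.concatenate([rng.standard_normal(n), 3 + rng.standard_normal(n)])
            noise = rng.standard_normal((2 * n, 4))
            x = np.column_stack([noise[:, :2], informative, noise[:, 2:]])
            data = LabeledFeatureSet(
                x, ["a"] * n + ["b"] * n,
                feature_names=("n1", "n2", "sig", "n3", "n4"),
            )
            if sffs_rank(data).order[0] == "sig":
                hits += 1
        assert hits >= 19

    def test_jointly_informative_pair_beats_best_single_feature(self):
        # XOR-like rotated Gaussians: marginals overlap, joint separates
        rng = np.random.default_rng(6)
        n = 500
        half = n // 2
        a = np.column_stack([rng.standard_normal(n) * 3, rng.standard_normal(n) * 0.3])
        b = a.copy()
        b[:, 1] += np.where(a[:, 0] > 0, 2.5, -2.5)
        rot = np.array([[np.cos(0.5), -np.sin(0.5)], [np.sin(0.5), np.cos(0.5)]])
        x = np.vstack([a @ rot.T, b @ rot.T])
        data = LabeledFeatureSet(x, ["a"] * n + ["b"] * n, feature_names=("f1", "f2"))
        ranking = sffs_rank(data)
        j_single = max(
            generalized_separability(data, (0,)), generalized_separability(data, (1,))
        )
        assert ranking.j_trace[-1] > j_single

    def test_duplicated_top_feature_adds_no_separability(self):
        x, y = gaussian_classes(2, 400, 2, 3.0, seed=7)
        dup = np.column_stack([x, x[:, 0]])
        data = LabeledFeatureSet(dup, y, feature_names=("f1", "f2", "f1_copy"))
        ranking = sffs_rank(data)
        assert ranking.order[0] != "f1_copy"
        # the collinear copy makes the covariance singular (ridge engages), so
        # the gain is only approximately zero
        assert ranking.j_trace[-1] == pytest.approx(ranking.j_trace[-2], rel=1e-2)

    def test_j_trace_is_non_decreasing_along_the_ranked_chain(self):
        x, y = gaussian_classes(3, 200, 5, 1.0, seed=8)
        ranking = sffs_rank(LabeledFeatureSet(x, y))
        assert sorted(ranking.order) == ["A", "HbT", "O2_percent", "b", "water_percent"]
        assert np.all(np.diff(ranking.j_trace) >= -1e-10)

    def test_never_worse_than_plain_forward_selection(self):
        x, y = gaussian_classes(4, 150, 5, 1.2, seed=9)
        data = LabeledFeatureSet(x, y)
        ranking = sffs_rank(data)
        # plain sequential forward selection
        selected = []
        remaining = list(range(5))
        sfs_trace = []
        while remaining:
            best = max(remaining, key=lambda f: generalized_separability(data, tuple(selected + [f])))
            selected.append(best)
            remaining.remove(best)
            sfs_trace.append(generalized_separability(data, tuple(selected)))
        assert all(j1 >= j2 - 1e-10 for j1, j2 in zip(ranking.j_trace, sfs_trace))

    def test_constant_feature_excluded_with_warning(self):
        x, y = gaussian_classes(2, 100, 3, 2.0, seed=10)
        x[:, 1] = 7.0
        data = LabeledFeatureSet(x, y, feature_names=("f1", "const", "f3"))
        with pytest.warns(UserWarning, match="constant"):
            ranking = sffs_rank(data)
        assert "const" not in ranking.order


class TestPearsonCorrelates:
    def _frames(self, n=20, seed=0):
        rng = np.random.default_rng(seed)
        means = pd.DataFrame(
            {
                "roi_id": np.arange(n),
                "A": rng.uniform(0.8, 1.4, n),
                "b": rng.uniform(0.5, 1.2, n),
                "HbT": rng.uniform(10, 30, n),
                "O2_percent": rng.uniform(40, 90, n),
                "water_percent": rng.uniform(20, 60, n),
            }
        )
        ihc = pd.DataFrame(
            {
                "roi_id": np.arange(n),
                "percent_epithelium": rng.uniform(10, 50, n),
                "percent_stroma": 30.0 + 40.0 * means["b"],  # perfectly linear in b
                "percent_fat": rng.uniform(5, 40, n),
                "mvd_cd31": rng.uniform(0, 5, n),
                "mvd_cd105": rng.uniform(0, 3, n),
                "mva_cd31": rng.uniform(50, 400, n),
                "mva_cd105": rng.uniform(20, 250, n),
            }
        )
        return means, ihc

    def test_perfectly_linear_pair_has_unit_correlation(self):
        means, ihc = self._frames()
        out = pearson_correlates(means, ihc)
        r = out[(out.spectral == "b") & (out.ihc == "percent_stroma")]["r"].iloc[0]
        assert r == pytest.approx(1.0, abs=1e-12)
        assert out.shape[0] == 5 * 7
        assert (out["n"] == 20).all()

    def test_correlation_is_symmetric_in_the_paired_columns(self):
        means, ihc = self._frames(seed=1)
        out = pearson_correlates(means, ihc)
        r1 = out[(out.spectral == "A") & (out.ihc == "mvd_cd31")]["r"].iloc[0]
        from scipy.stats import pearsonr

        merged = means.merge(ihc, on="roi_id")
        r2, _ = pearsonr(merged["mvd_cd31"], merged["A"])
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_zero_variance_column_flagged_undefined(self):
        means, ihc = self._frames(seed=2)
        ihc["mvd_cd105"] = 1.0
        out = pearson_correlates(means, ihc)
        row = out[(out.spectral == "A") & (out.ihc == "mvd_cd105")].iloc[0]
        assert np.isnan(row["r"]) and row["undefined"]

    def test_too_few_rois_rejected(self):
        means, ihc = self._frames(n=2, seed=3)
        with pytest.raises(ValueError, match="3 paired"):
            pearson_correlates(means, ihc)
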