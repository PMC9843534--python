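"""Ordination, MANOVA, discriminant analysis and vector fitting."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wheatlocust import multivariate as mv

TRAITS5 = ["lt_um", "sws", "lnc_pct", "macronutrient_sum", "macronutrient_ratio"]


def _two_group_data(n_per=30, shift=(0, 0, 0, 0, 0), seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, size=(n_per, 5))
    b = rng.normal(0, 1, size=(n_per, 5)) + np.asarray(shift)
    X = np.vstack([a, b])
    labels = np.array(["ancestral"] * n_per + ["modern"] * n_per)
    return X, labels


class TestPca:
    def test_rank_one_correlation_toy(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 50)
        X = np.column_stack([x, 2 * x + 3])  # perfectly correlated pair
        res = mv.pca_standardized(X)
        assert res.eigenvalues == pytest.approx([2.0, 0.0], abs=1e-10)

    def test_independent_traits_give_unit_eigenvalues(self):
        rng = np.random.default_rng(1)
        res = mv.pca_standardized(rng.normal(0, 1, size=(20_000, 5)))
        assert np.allclose(res.eigenvalues, 1.0, atol=0.05)

    def test_eigenvalue_sum_equals_trait_count(self):
        X, _ = _two_group_data(shift=(1, 0.5, 0, 0, 0), seed=2)
        res = mv.pca_standardized(X)
        assert res.eigenvalues.sum() == pytest.approx(5.0)
        assert res.variance_explained.sum() == pytest.approx(1.0)

    def test_reconstruction_and_orthonormal_loadings(self):
        X, _ = _two_group_data(seed=3)
        res = mv.pca_standardized(X)
        Z = mv.standardize(X)
        assert np.allclose(res.scores @ res.loadings.T, Z, atol=1e-10)
        assert np.allclose(res.loadings.T @ res.loadings, np.eye(5), atol=1e-10)

    def test_deterministic_sign_convention(self):
        X, _ = _two_group_data(shift=(2, 0, 0, 0, 0), seed=4)
        res = mv.pca_standardized(X)
        for j in range(5):
            k = np.argmax(np.abs(res.loadings[:, j]))
            assert res.loadings[k, j] > 0

    def test_constant_column_rejected(self):
        X = np.ones((10, 2))
        with pytest.raises(ValueError, match="constant"):
            mv.pca_standardized(X)


class TestManova:
    def test_null_p_roughly_uniform(self):
        ps = [
            mv.manova_two_group(*_two_group_data(n_per=25, seed=s)).p for s in range(60)
        ]
        # Kolmogorov-Smirnov against uniform at a generous level
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_huge_separation_drives_lambda_to_zero(self):
        X, labels = _two_group_data(shift=(30, 0, 0, 0, 0), seed=5)
        res = mv.manova_two_group(X, labels)
        assert res.wilks_lambda < 0.01 and res.p < 1e-10

    def test_matches_label_permutation_reference(self):
        X, labels = _two_group_data(n_per=12, shift=(0.9, 0, 0, 0, 0), seed=6)
        res = mv.manova_two_group(X, labels)
        rng = np.random.default_rng(7)
        n_perm = 2000
        hits = 0
        for _ in range(n_perm):
            perm = mv.manova_two_group(X, rng.permutation(labels))
            if perm.wilks_lambda <= res.wilks_lambda:
                hits += 1
        p_perm = (1 + hits) / (1 + n_perm)
        mc_err = 3 * np.sqrt(res.p * (1 - res.p) / n_perm)
        assert abs(res.p - p_perm) < mc_err + 0.01

    def test_tiny_group_rejected(self):
        X, labels = _two_group_data(n_per=4, seed=8)
        with pytest.raises(ValueError, match="members"):
            mv.manova_two_group(X, labels)


class TestLda:
    def test_concentrates_on_informative_trait(self):
        X, labels = _two_group_data(n_per=4000, shift=(0, 0, 2, 0, 0), seed=9)
        res = mv.lda_two_group(X, labels, TRAITS5, [str(i) for i in range(8000)])
        assert abs(res.coefficients["lnc_pct"]) > 0.98
        assert np.linalg.norm(res.coefficients.to_numpy()) == pytest.approx(1.0)

    def test_sign_convention_lnc_positive(self):
        X, labels = _two_group_data(n_per=30, shift=(0.5, 0.2, -1.0, 0, 0), seed=10)
        res = mv.lda_two_group(X, labels, TRAITS5, [str(i) for i in range(60)])
        assert res.coefficients["lnc_pct"] > 0

    def test_invariant_to_column_reordering(self):
        X, labels = _two_group_data(n_per=30, shift=(1.0, 0.5, 0.3, 0, 0), seed=11)
        ids = [str(i) for i in range(60)]
        base = mv.lda_two_group(X, labels, TRAITS5, ids)
        perm = [2, 0, 4, 1, 3]
        names_p = [TRAITS5[i] for i in perm]
        res_p = mv.lda_two_group(X[:, perm], labels, names_p, ids)
        for name in TRAITS5:
            assert res_p.coefficients[name] == pytest.approx(
                base.coefficients[name], abs=1e-10
            )

    def test_group_mean_scores_ordered_by_shift(self):
        X, labels = _two_group_data(n_per=30, shift=(0, 0, 1.5, 0, 0), seed=12)
        res = mv.lda_two_group(X, labels, TRAITS5, [str(i) for i in range(60)])
        gm = res.group_means["df_score"]
        assert gm["modern"] > gm["ancestral"]  # positive LNC coefficient, modern higher


class TestVectorFit:
    def _ordination(self, seed=13):
        X, _ = _two_group_data(n_per=10, shift=(1.5, 1.0, 0, 0, 0), seed=seed)
        return mv.pca_standardized(X)

    def test_response_equal_to_pc1(self):
        ord_ = self._ordination()
        fit = mv.vector_fit(ord_.scores[:, 0], ord_, min_eigenvalue=1.0)
        assert fit.r_squared == pytest.approx(1.0)
        assert abs(fit.direction[0]) == pytest.approx(1.0)

    def test_response_equal_to_negative_pc2(self):
        ord_ = self._ordination()
        fit = mv.vector_fit(-ord_.scores[:, 1], ord_, min_eigenvalue=1.0)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.direction[1] == pytest.approx(-1.0)

    def test_independent_response_null(self):
        ord_ = self._ordination()
        rng = np.random.default_rng(14)
        ps = []
        for _ in range(30):
            fit = mv.vector_fit(
                rng.normal(0, 1, ord_.scores.shape[0]), ord_,
                n_permutations=199, seed=int(rng.integers(2**31)),
            )
            ps.append(fit.permutation_p)
        assert min(ps) > 1 / 200  # no spurious certainty
        assert 0.2 < np.mean(ps) < 0.8

    def test_no_retained_component_rejected(self):
        ord_ = self._ordination()
        with pytest.raises(ValueError, match="eigenvalue"):
            mv.vector_fit(np.zeros(20), ord_, min_eigenvalue=100.0)


class TestRegression:
    def test_exact_linear_relation(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        res = mv.regress_response_on_df(x, 2.0 * x + 1.0)
        assert res.slope == pytest.approx(2.0)
        assert res.p < 1e-12

    def test_textbook_five_points_closed_form(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.1, 3.9, 6.2, 8.1, 9.8])
        res = mv.regress_response_on_df(x, y)
        sxx = np.sum((x - x.mean()) ** 2)
        slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
        resid = y - (y.mean() + slope * (x - x.mean()))
        se = np.sqrt(np.sum(resid**2) / 3 / sxx)
        assert res.slope == pytest.approx(slope)
        assert res.se_slope == pytest.approx(se)
        t = slope / se
        assert res.p == pytest.approx(2 * stats.t.sf(abs(t), 3))

    def test_matches_permutation_reference(self):
        rng = np.random.default_rng(15)
        x = rng.normal(0, 1, 20)
        y = 0.5 * x + rng.normal(0, 1, 20)
        res = mv.regress_response_on_df(x, y)
        n_perm = 4000
        hits = 0
        for _ in range(n_perm):
            r = stats.linregress(x, rng.permutation(y))
            if abs(r.rvalue) >= abs(np.sqrt(res.r_squared)):
                hits += 1
        p_perm = (1 + hits) / (1 + n_perm)
        assert abs(res.p - p_perm) < 3 * np.sqrt(max(res.p, 0.01) / n_perm) + 0.01

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            mv.regress_response_on_df(np.ones(5), np.arange(5.0))
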