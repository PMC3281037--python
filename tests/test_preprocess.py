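import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from eqtnatlas.preprocess import (
    DEFAULT_LAMBDA2_GRID,
    _cd_elastic_net,
    center_by_population,
    filter_non_expressed,
    filter_probes_overlapping_variants,
    quantile_normalize,
    regress_out_factors,
    select_num_pcs,
)

from conftest import toy_expression


class TestVariantFilter:
    def probe(self, start=100, end=125):
        return pd.DataFrame(
            {"chrom": ["chr1"], "start": [start], "end": [end]},
            index=pd.Index(["p0"], name="feature_id"),
        )

    def test_snp_inside_probe_drops_it(self):
        variants = pd.DataFrame({"chrom": ["chr1"], "pos": [110]})
        assert list(filter_probes_overlapping_variants(self.probe(), variants)) == []

    def test_half_open_boundary_retains(self):
        variants = pd.DataFrame({"chrom": ["chr1"], "pos": [125]})
        assert list(filter_probes_overlapping_variants(self.probe(), variants)) == ["p0"]

    def test_empty_variant_list_vacuous(self):
        variants = pd.DataFrame({"chrom": [], "pos": []})
        assert list(filter_probes_overlapping_variants(self.probe(), variants)) == ["p0"]

    def test_interval_variant_overlap(self):
        cnv = pd.DataFrame({"chrom": ["chr1"], "start": [120], "end": [200]})
        assert list(filter_probes_overlapping_variants(self.probe(), cnv)) == []
        cnv2 = pd.DataFrame({"chrom": ["chr1"], "start": [125], "end": [200]})
        assert list(filter_probes_overlapping_variants(self.probe(), cnv2)) == ["p0"]

    def test_missing_interval_errors_with_names(self):
        feats = self.probe()
        feats.loc["p0", "start"] = np.nan
        with pytest.raises(ValueError, match="p0"):
            filter_probes_overlapping_variants(
                feats, pd.DataFrame({"chrom": ["chr1"], "pos": [1]})
            )

    def test_retained_order_preserved(self):
        feats = pd.DataFrame(
            {"chrom": "chr1", "start": [300, 100, 200], "end": [350, 150, 250]},
            index=pd.Index(["pc", "pa", "pb"], name="feature_id"),
        )
        variants = pd.DataFrame({"chrom": ["chr1"], "pos": [120]})
        assert list(filter_probes_overlapping_variants(feats, variants)) == ["pc", "pb"]


class TestNonExpressedFilter:
    def test_zero_median_counts_dropped(self):
        expr = toy_expression(
            [[0, 0, 1, 0, 0, 0], [5, 6, 7, 4, 5, 6]],
            populations=["A"] * 3 + ["B"] * 3,
        )
        assert list(filter_non_expressed(expr, "zero_median_count")) == ["f1"]

    def test_constant_feature_dropped_by_mad(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(9, 10))
        vals = np.vstack([vals, np.full((1, 10), 3.0)])
        expr = toy_expression(vals)
        kept = filter_non_expressed(expr, "mad", threshold=1e-6)
        assert "f9" not in set(kept) and len(kept) == 9

    def test_median_level_requires_all_populations_low(self):
        expr = toy_expression(
            [[5, 5, 5, 0, 0, 0]], populations=["A"] * 3 + ["B"] * 3
        )
        # median 5 in one population -> retained under the ALL-populations rule
        assert list(filter_non_expressed(expr, "median_level", threshold=1.0)) == ["f0"]

    def test_unknown_method(self):
        with pytest.raises(ValueError, match="unknown"):
            filter_non_expressed(toy_expression([[1, 2]]), "tpm")


PHI_QUARTILE = 0.674489750196082  # Phi^-1(0.75)


class TestQuantileNormalize:
    def test_three_value_scores(self):
        expr = toy_expression([[5.0, 2.0, 9.0]])
        out = quantile_normalize(expr).values.to_numpy()[0]
        np.testing.assert_allclose(out, [0.0, -PHI_QUARTILE, PHI_QUARTILE],
                                   atol=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(size=(4, 12))
        a = quantile_normalize(toy_expression(vals)).values.to_numpy()
        b = quantile_normalize(toy_expression(np.exp(vals))).values.to_numpy()
        c = quantile_normalize(toy_expression(vals**3)).values.to_numpy()
        np.testing.assert_allclose(a, b, atol=1e-12)
        np.testing.assert_allclose(a, c, atol=1e-12)

    def test_all_tied_maps_to_zero(self):
        out = quantile_normalize(toy_expression([[4.0] * 7])).values.to_numpy()
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_tie_gets_average_of_rank_scores(self):
        out = quantile_normalize(toy_expression([[1.0, 1.0, 5.0]])).values.to_numpy()[0]
        lo = stats.norm.ppf([0.25, 0.5]).mean()
        np.testing.assert_allclose(out, [lo, lo, PHI_QUARTILE], atol=1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        expr = toy_expression(rng.normal(size=(5, 15)),
                              populations=["A"] * 7 + ["B"] * 8)
        once = quantile_normalize(expr)
        twice = quantile_normalize(once)
        np.testing.assert_allclose(once.values.to_numpy(),
                                   twice.values.to_numpy(), atol=1e-12)

    def test_normalization_is_within_population(self):
        expr = toy_expression([[1.0, 2.0, 3.0, 100.0, 200.0, 300.0]],
                              populations=["A"] * 3 + ["B"] * 3)
        out = quantile_normalize(expr).values.to_numpy()[0]
        np.testing.assert_allclose(out[:3], out[3:], atol=1e-12)

    def test_single_sample_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            quantile_normalize(toy_expression([[1.0, 2.0]],
                                              populations=["A", "B"]))


class TestCentering:
    def test_two_group_centering(self):
        expr = toy_expression([[1, 2, 3, 10, 20, 30]],
                              populations=["A"] * 3 + ["B"] * 3)
        out = center_by_population(expr).values.to_numpy()[0]
        np.testing.assert_allclose(out, [-1, 0, 1, -10, 0, 10])

    def test_idempotent_and_single_group_is_global(self):
        expr = toy_expression([[1.0, 5.0, 6.0]])
        once = center_by_population(expr)
        np.testing.assert_allclose(once.values.to_numpy().mean(), 0, atol=1e-12)
        twice = center_by_population(once)
        np.testing.assert_allclose(once.values.to_numpy(),
                                   twice.values.to_numpy(), atol=1e-14)


class TestSelectNumPcs:
    def test_default_arguments(self):
        import inspect

        sig = inspect.signature(select_num_pcs)
        assert sig.parameters["n_perm"].default == 100
        assert sig.parameters["upper_quantile"].default == 0.975

    def test_noise_gives_zero_factors(self):
        rng = np.random.default_rng(5)
        sel = select_num_pcs(rng.normal(size=(50, 40)), n_perm=50, seed=5)
        assert sel.n_pcs == 0

    def test_three_planted_factors_recovered(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 2, size=(50, 3)) @ rng.normal(size=(3, 40))
        x += rng.normal(size=(50, 40))
        sel = select_num_pcs(x, n_perm=50, seed=6)
        assert sel.n_pcs == 3

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            select_num_pcs(np.zeros((5, 2)))
        with pytest.raises(ValueError, match="n_perm"):
            select_num_pcs(np.zeros((5, 5)), n_perm=0)


class TestRegressOutFactors:
    def test_perfect_predictor_gives_near_zero_residual(self):
        from eqtnatlas.preprocess import FactorCorrection

        rng = np.random.default_rng(0)
        n = 30
        pcs = np.linalg.qr(rng.normal(size=(n, 3)))[0]
        vals = np.vstack([2.0 * pcs[:, 0] - pcs[:, 2],
                          rng.normal(size=(20, n))])
        expr = toy_expression(vals)
        corr = FactorCorrection(3, np.ones(3), np.zeros(3), pcs, 1, 0.975)
        resid, _ = regress_out_factors(expr, corr, covariates=None)
        # a feature exactly in the span of the retained PCs is annihilated
        # up to the shrinkage of the smallest grid penalty (~lambda2/n)
        signal = np.abs(vals[0]).max()
        assert np.abs(resid.values.to_numpy()[0]).max() < 1e-3 * signal

    def test_empty_design_returns_centered_input(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(4, 10))
        expr = toy_expression(vals)
        resid, report = regress_out_factors(expr, 0, covariates=None)
        np.testing.assert_allclose(
            resid.values.to_numpy(), vals - vals.mean(axis=1, keepdims=True),
            atol=1e-12,
        )
        assert (report["lambda2"] == 0).all()

    def test_independent_feature_keeps_its_variance(self):
        rng = np.random.default_rng(2)
        n, f = 200, 40
        fac = rng.normal(size=(2, n))
        vals = rng.normal(0, 1.5, size=(f, 2)) @ fac + rng.normal(size=(f, n))
        indep = rng.normal(size=(1, n))
        expr = toy_expression(np.vstack([vals, indep]))
        resid, _ = regress_out_factors(expr, 2, covariates=None)
        out = resid.values.to_numpy()[-1]
        assert abs(out.var() / indep.var() - 1.0) < 0.10

    def test_k_larger_than_samples_rejected(self):
        expr = toy_expression(np.random.default_rng(0).normal(size=(3, 5)))
        with pytest.raises(ValueError, match="exceeds sample count"):
            regress_out_factors(expr, 10, covariates=None)

    def test_six_point_lambda2_grid_default(self):
        assert len(DEFAULT_LAMBDA2_GRID) == 6
        assert DEFAULT_LAMBDA2_GRID[0] < 0.1 and DEFAULT_LAMBDA2_GRID[-1] >= 100

    def test_solver_matches_sklearn_elastic_net(self):
        # independent oracle for the coordinate-descent solver
        from sklearn.linear_model import ElasticNet

        rng = np.random.default_rng(4)
        n, p = 60, 6
        x = rng.normal(size=(n, p))
        y = x @ rng.normal(size=(p, 3)) + rng.normal(size=(n, 3))
        lam1 = np.array([0.5, 2.0, 10.0])
        lam2 = 3.0
        w = _cd_elastic_net(x, y, lam1, lam2)
        for j in range(3):
            alpha = (lam1[j] + lam2) / n
            l1r = lam1[j] / (lam1[j] + lam2)
            sk = ElasticNet(alpha=alpha, l1_ratio=l1r, fit_intercept=False,
                            tol=1e-12, max_iter=200_000).fit(x, y[:, j])
            np.testing.assert_allclose(w[:, j], sk.coef_, atol=1e-8)
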