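import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from eqtnatlas.mapping import (
    CisScanner,
    MonomorphicError,
    best_snp_weights,
    cis_window_snps,
    empirical_fdr_threshold,
    map_cis_qtls,
)
from eqtnatlas.mapping import test_association as assoc
from eqtnatlas.preprocess import center_by_population, quantile_normalize
from eqtnatlas.pipeline import _gene_level_matrix
from eqtnatlas.synthetic import (
    SimulationConfig,
    place_eqtns,
    render_platform,
    simulate_expression,
    simulate_gene_models,
    simulate_genotypes,
)

from conftest import toy_expression, toy_genotypes


class TestCisWindow:
    def test_gene_window_100kb(self):
        geno = toy_genotypes(
            [899_999, 900_000, 1_000_000, 1_149_999, 1_150_000],
            np.tile([0, 1, 2, 1], (5, 1)),
        )
        idx = cis_window_snps("chr1", 1_000_000, 1_050_000, geno, "gene")
        assert list(geno.positions[idx]) == [900_000, 1_000_000, 1_149_999]

    def test_exon_window_10kb_floored_at_zero(self):
        geno = toy_genotypes([0, 100, 15_199, 15_200],
                             np.tile([0, 1, 2, 1], (4, 1)))
        idx = cis_window_snps("chr1", 5_000, 5_200, geno, "exon")
        assert list(geno.positions[idx]) == [0, 100, 15_199]

    def test_unknown_level(self):
        geno = toy_genotypes([1], [[0, 1, 2]])
        with pytest.raises(ValueError, match="level"):
            cis_window_snps("chr1", 0, 10, geno, "transcript")


class TestAssociation:
    def test_perfect_fit_flagged(self):
        g = np.array([0, 0, 1, 1, 2, 2], float)
        res = assoc(g.copy(), g)
        assert res.slope == pytest.approx(1.0)
        assert res.p == 0.0 and res.perfect_fit

    def test_monomorphic_rejected(self):
        with pytest.raises(MonomorphicError):
            assoc(np.random.default_rng(0).normal(size=5),
                             np.ones(5))

    def test_too_few_observations(self):
        with pytest.raises(ValueError, match="at least 3"):
            assoc([1.0, 2.0], [0.0, 1.0])

    def test_missing_pairs_dropped(self):
        y = np.array([1.0, np.nan, 2.0, 3.0, 4.0, 0.0])
        g = np.array([0, 1, 1, 2, np.nan, 0], float)
        res = assoc(y, g)
        assert res.n == 4

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_p_matches_correlation_closed_form(self, seed):
        rng = np.random.default_rng(seed)
        n = 50
        y = rng.normal(size=n)
        g = rng.binomial(2, 0.3, size=n).astype(float)
        if g.std() == 0:
            return
        res = assoc(y, g)
        r = np.corrcoef(y, g)[0, 1]
        t = r * np.sqrt((n - 2) / (1 - r * r))
        p = 2 * stats.t.sf(abs(t), n - 2)
        assert abs(res.p - p) <= 1e-12 * p


class TestBestSnpWeights:
    def test_exact_tie_shares_probability(self):
        w = best_snp_weights(["a", "b", "c"], [1e-8, 1e-8, 0.01])
        np.testing.assert_allclose(w.to_numpy(), [0.5, 0.5, 0.0])

    def test_unique_minimum(self):
        w = best_snp_weights(["a", "b"], [0.3, 0.001])
        np.testing.assert_allclose(w.to_numpy(), [0.0, 1.0])

    def test_near_ties_rounded_to_12_digits(self):
        w = best_snp_weights(["a", "b"], [1e-8, 1e-8 * (1 + 1e-13)])
        np.testing.assert_allclose(w.to_numpy(), [0.5, 0.5])

    @given(st.lists(st.floats(1e-20, 1.0), min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_weights_sum_to_one(self, pvals):
        w = best_snp_weights([f"s{i}" for i in range(len(pvals))], pvals)
        assert w.sum() == pytest.approx(1.0)
        assert (w.to_numpy() >= 0).all()


def _mapped_study(beta=2.5, n_genes=150, seed=17, prop_qtl=1.0):
    cfg = SimulationConfig(
        n_genes=n_genes, prop_qtl=prop_qtl, prop_exon_specific=0.0,
        beta_gene=beta, n_factors=0, snp_density=0.5, seed=seed,
    )
    genes = simulate_gene_models(cfg)
    geno = simulate_genotypes(cfg, genes)
    truth = place_eqtns(genes, geno, cfg)
    exons = simulate_expression(genes, geno, truth, cfg)
    expr = render_platform(exons, "three_prime_probe", cfg)
    expr = center_by_population(quantile_normalize(expr))
    gmodels = {g.gene_id: g for g in genes}
    gl = _gene_level_matrix(expr, gmodels)
    return cfg, gmodels, geno, truth, gl


class TestMapCisQtls:
    def test_planted_eqtn_recovered_as_min_p(self):
        _, gmodels, geno, truth, gl = _mapped_study()
        res = map_cis_qtls(gl, geno, gmodels)
        hits = 0
        planted = truth[truth.snp_id.notna()]
        for _, row in planted.iterrows():
            ties = res.best.loc[row.gene_id, "tied_snps"]
            hits += row.snp_id in ties
        assert hits / len(planted) >= 0.95

    def test_reported_p_matches_oracle_on_full_table(self):
        _, gmodels, geno, _, gl = _mapped_study(n_genes=5)
        res = map_cis_qtls(gl, geno, gmodels, return_full=True)
        n = gl.n_samples
        for _, row in res.full.sample(50, random_state=0).iterrows():
            y = gl.values.loc[row.feature_id].to_numpy()
            g = geno.dosages[geno.index_of(row.snp_id)].astype(float)
            r = np.corrcoef(y, g)[0, 1]
            p = 2 * stats.t.sf(abs(r) * np.sqrt((n - 2) / (1 - r * r)), n - 2)
            assert row.p == pytest.approx(p, rel=1e-10, abs=1e-300)

    def test_feature_without_candidates_absent_and_logged(self, caplog):
        expr = toy_expression(np.random.default_rng(0).normal(size=(1, 6)),
                              starts=[10_000_000], ends=[10_000_050])
        geno = toy_genotypes([100], np.tile([0, 1, 2], (1, 2)))
        with caplog.at_level(logging.INFO):
            res = map_cis_qtls(expr, geno, level="exon")
        assert len(res.best) == 0
        assert "empty candidate set" in caplog.text

    def test_exon_level_windows_are_independent_per_exon(self):
        # two exons of one gene get different candidate sets from their own
        # 10 kb windows
        vals = np.random.default_rng(1).normal(size=(2, 8))
        expr = toy_expression(vals, gene_ids=["g0", "g0"], exon_index=[0, 1],
                              starts=[1_000, 60_000], ends=[1_200, 60_300])
        geno = toy_genotypes([500, 55_000, 65_000],
                             np.tile([0, 1, 2, 1], (3, 2)))
        scanner = CisScanner(expr, geno, level="exon")
        assert [len(scanner._cand[i]) for i in range(2)] == [1, 2]


class TestEmpiricalFdr:
    def test_default_target(self):
        import inspect

        assert inspect.signature(empirical_fdr_threshold).parameters["target"].default == 0.05

    def test_strong_signal_found_null_not(self):
        _, gmodels, geno, truth, gl = _mapped_study(n_genes=60, prop_qtl=0.5)
        res = map_cis_qtls(gl, geno, gmodels)
        fdr = empirical_fdr_threshold(res.best, gl, geno, gmodels,
                                      n_perm=5, seed=3)
        planted = set(truth.loc[truth.snp_id.notna(), "gene_id"])
        sig = set(fdr.significant)
        assert len(sig) > 0
        # most planted strong QTLs are recovered ...
        assert len(sig & planted) / len(planted) > 0.8
        # ... and false discoveries stay in the vicinity of the 5% target
        assert len(sig - planted) / len(sig) <= 0.15

    def test_all_observed_above_null_gives_empty_set(self):
        rng = np.random.default_rng(0)
        obs = pd.DataFrame({"min_p": [0.5, 0.9]},
                           index=pd.Index(["a", "b"], name="feature_id"))
        expr = toy_expression(rng.normal(size=(2, 10)),
                              gene_ids=["a", "b"], starts=[0, 5_000],
                              ends=[100, 5_100])
        geno = toy_genotypes([50, 5_050], rng.integers(0, 3, size=(2, 10)))
        fdr = empirical_fdr_threshold(obs, expr, geno, level="exon",
                                      n_perm=3, seed=1)
        assert fdr.cutoff is None and len(fdr.significant) == 0

    def test_cutoff_monotone_in_target(self):
        _, gmodels, geno, _, gl = _mapped_study(n_genes=40, prop_qtl=0.5)
        res = map_cis_qtls(gl, geno, gmodels)
        scanner = CisScanner(gl, geno, gmodels)
        cuts = []
        for target in (0.05, 0.10, 0.25):
            f = empirical_fdr_threshold(res.best, gl, geno, gmodels,
                                        n_perm=5, target=target, seed=9,
                                        scanner=scanner)
            cuts.append(-np.inf if f.cutoff is None else f.cutoff)
        assert cuts == sorted(cuts)

    def test_permutation_preserves_population_means(self):
        # permuting within population must leave each population's sample
        # set, hence its mean, untouched
        pops = np.array(["A"] * 4 + ["B"] * 4)
        rng = np.random.default_rng(2)
        n = len(pops)
        perm = np.arange(n)
        for pop in np.unique(pops):
            block = np.flatnonzero(pops == pop)
            perm[block] = block[rng.permutation(len(block))]
        assert set(perm[:4]) == {0, 1, 2, 3}
        assert set(perm[4:]) == {4, 5, 6, 7}

    def test_population_structure_not_mistaken_for_signal(self):
        # two populations with large feature mean shifts; after
        # within-population normalization the type-I error is nominal for
        # ordinary SNPs and never inflated for structure-confounded SNPs
        rng = np.random.default_rng(4)
        n_feat, n = 100, 80
        shift = rng.normal(0, 2, size=n_feat)
        pops = ["A"] * 40 + ["B"] * 40
        pop_ind = np.r_[np.zeros(40), np.ones(40)]
        vals = rng.normal(size=(n_feat, n)) + shift[:, None] * pop_ind
        expr = toy_expression(vals, populations=pops)
        expr = center_by_population(quantile_normalize(expr))
        y = expr.values.to_numpy()
        hits = total = c_hits = c_total = 0
        for i in range(n_feat):
            for _ in range(50):
                g = rng.binomial(2, 0.3, size=n).astype(float)
                if g.std() > 0:
                    hits += assoc(y[i], g).p < 0.01
                    total += 1
                gc = np.array([rng.binomial(2, 0.1 if p == "A" else 0.45)
                               for p in pops], float)
                if gc.std() > 0:
                    c_hits += assoc(y[i], gc).p < 0.01
                    c_total += 1
        assert 0.005 <= hits / total <= 0.02
        assert c_hits / c_total <= 0.02  # confounded SNPs only conservative
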