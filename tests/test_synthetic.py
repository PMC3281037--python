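import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eqtnatlas.synthetic import (
    SimulationConfig,
    place_eqtns,
    render_platform,
    simulate_expression,
    simulate_gene_models,
    simulate_genotypes,
)


def cfg(**kw):
    base = dict(n_genes=20, n_samples={"CEU": 20, "YRI": 20}, seed=7)
    base.update(kw)
    return SimulationConfig(**base)


class TestGeneModels:
    def test_single_exon_degenerate(self):
        genes = simulate_gene_models(cfg(exon_count_range=(1, 1)))
        for g in genes:
            assert g.n_exons == 1
            assert g.first_exon == g.last_exon

    def test_fixed_lengths_give_fixed_span(self):
        genes = simulate_gene_models(
            cfg(
                exon_count_range=(5, 5),
                exon_length_range=(200, 200),
                last_exon_length_range=(200, 200),
                intron_length_range=(1000, 1000),
            )
        )
        for g in genes:
            assert g.span_end - g.span_start == 5 * 200 + 4 * 1000

    def test_seed_determinism(self):
        a = simulate_gene_models(cfg(seed=1))
        b = simulate_gene_models(cfg(seed=1))
        c = simulate_gene_models(cfg(seed=2))
        assert [g.exons for g in a] == [g.exons for g in b]
        assert [g.exons for g in a] != [g.exons for g in c]

    def test_both_strands_and_no_overlap(self):
        genes = simulate_gene_models(cfg(n_genes=30))
        assert {g.strand for g in genes} == {"+", "-"}
        spans = sorted((g.span_start, g.span_end) for g in genes)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2

    def test_zero_length_exon_support_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            simulate_gene_models(cfg(exon_length_range=(0, 100)))


class TestGenotypes:
    def test_half_maf_gives_mean_dosage_one(self):
        c = cfg(maf_range=(0.5, 0.5), n_samples={"CEU": 2000})
        geno = simulate_genotypes(c, simulate_gene_models(c))
        assert abs(geno.dosages.mean() - 1.0) < 0.05

    def test_hardy_weinberg_class_frequencies(self):
        # maf fixed at 0.2: expected genotype frequencies 0.64/0.32/0.04,
        # pooled over SNPs and checked within 3 binomial standard deviations
        c = cfg(n_genes=2, maf_range=(0.2, 0.2), snp_density=0.05,
                n_samples={"CEU": 10_000})
        geno = simulate_genotypes(c, simulate_gene_models(c))
        n = geno.dosages.size
        assert n > 0
        for k, p in [(0, 0.64), (1, 0.32), (2, 0.04)]:
            obs = (geno.dosages == k).sum() / n
            assert abs(obs - p) <= 3 * np.sqrt(p * (1 - p) / n)

    def test_maf_floor(self):
        c = cfg(maf_range=(0.005, 0.005))
        with pytest.warns(UserWarning):
            geno = simulate_genotypes(c, simulate_gene_models(c))
        assert geno.n_snps == 0

    def test_zero_density_warns_empty(self):
        c = cfg(snp_density=0.0)
        with pytest.warns(UserWarning, match="no SNPs"):
            geno = simulate_genotypes(c, simulate_gene_models(c))
        assert geno.n_snps == 0

    def test_stored_maf_matches_dosages(self, small_study):
        geno = small_study["genotypes"]
        freq = geno.dosages.mean(axis=1) / 2
        realized = np.minimum(freq, 1 - freq)
        assert np.all(np.abs(realized - geno.maf) <= 1 / (2 * geno.n_samples) + 1e-12)


def _flat_cfg(**kw):
    """Placement prior with no positional preference at all."""
    base = dict(
        lambda_distance=(0.0,) * 14, lambda_intron=0.0, lambda_exon=0.0,
        lambda_last_exon=0.0, prop_qtl=1.0, prop_exon_specific=0.0,
        snp_density=0.5, seed=13,
    )
    base.update(kw)
    return cfg(**base)


class TestPlaceEqtns:
    def test_zero_coefficients_place_uniformly(self):
        c = _flat_cfg(n_genes=300)
        genes = simulate_gene_models(c)
        geno = simulate_genotypes(c, genes)
        truth = place_eqtns(genes, geno, c)
        gmap = {g.gene_id: g for g in genes}
        # relative rank of the chosen SNP among its candidates ~ uniform
        fracs = []
        for _, row in truth[truth.snp_id.notna()].iterrows():
            g = gmap[row.gene_id]
            idx = geno.snps_in(g.chrom, max(0, g.span_start - c.cis_flank),
                               g.span_end + c.cis_flank)
            rank = int(np.flatnonzero(geno.snp_ids[idx] == row.snp_id)[0])
            fracs.append((rank + 0.5) / len(idx))
        counts, _ = np.histogram(fracs, bins=10, range=(0, 1))
        assert stats.chisquare(counts).pvalue > 0.01

    def test_exon_intron_placement_odds(self):
        # flat distance profile; exon/intron log-odds = log 12 by construction
        c = _flat_cfg(n_genes=1500, lambda_exon=float(np.log(12)),
                      lambda_last_exon=float(np.log(12)))
        genes = simulate_gene_models(c)
        geno = simulate_genotypes(c, genes)
        truth = place_eqtns(genes, geno, c)
        gmap = {g.gene_id: g for g in genes}
        drawn = {"exon": 0, "intron": 0}
        cand = {"exon": 0, "intron": 0}
        for _, row in truth[truth.snp_id.notna()].iterrows():
            g = gmap[row.gene_id]
            idx = geno.snps_in(g.chrom, max(0, g.span_start - c.cis_flank),
                               g.span_end + c.cis_flank)
            pos = geno.positions[idx]
            in_exon = np.array([g.exon_index_at(p) is not None for p in pos])
            in_gene = (pos >= g.span_start) & (pos < g.span_end)
            cand["exon"] += int(in_exon.sum())
            cand["intron"] += int((in_gene & ~in_exon).sum())
            p = int(geno.positions[geno.index_of(row.snp_id)])
            if g.exon_index_at(p) is not None:
                drawn["exon"] += 1
            elif g.contains(p):
                drawn["intron"] += 1
        odds = (drawn["exon"] / cand["exon"]) / (drawn["intron"] / cand["intron"])
        assert 8.0 < odds < 17.0

    def test_degenerate_probabilities_target_last_exon(self):
        c = cfg(prop_qtl=1.0, prop_exon_specific=1.0, last_exon_bias=1.0)
        genes = simulate_gene_models(c)
        geno = simulate_genotypes(c, genes)
        truth = place_eqtns(genes, geno, c)
        planted = truth[truth.snp_id.notna()]
        assert len(planted) > 0
        assert (planted.effect_type == "exon_specific").all()
        gmap = {g.gene_id: g for g in genes}
        for _, row in planted.iterrows():
            assert int(row.target_exon) == gmap[row.gene_id].n_exons - 1

    def test_planted_snp_in_candidate_region(self, small_study):
        geno = small_study["genotypes"]
        c = small_study["config"]
        for _, row in small_study["truth"].iterrows():
            if row.snp_id is None:
                continue
            g = small_study["gene_models"][row.gene_id]
            pos = int(geno.positions[geno.index_of(row.snp_id)])
            assert g.span_start - c.cis_flank <= pos < g.span_end + c.cis_flank


class TestExpression:
    def test_no_variance_sources_gives_constants(self):
        c = cfg(n_factors=0, noise_sd=0.0, exon_offset_sd=0.0, prop_qtl=0.0)
        genes = simulate_gene_models(c)
        geno = simulate_genotypes(c, genes)
        truth = place_eqtns(genes, geno, c)
        expr = simulate_expression(genes, geno, truth, c)
        vals = expr.values.to_numpy()
        assert np.allclose(vals, vals[:, :1])
        # all exons of a gene share the same baseline
        for gid, grp in expr.features.groupby("gene_id"):
            sub = expr.values.loc[grp.index].to_numpy()
            assert np.allclose(sub, sub[0, 0])

    def test_gene_level_qtl_shifts_all_exons(self):
        c = cfg(n_factors=0, noise_sd=0.0, exon_offset_sd=0.0,
                prop_qtl=1.0, prop_exon_specific=0.0)
        genes = simulate_gene_models(c)
        geno = simulate_genotypes(c, genes)
        truth = place_eqtns(genes, geno, c)
        expr = simulate_expression(genes, geno, truth, c)
        row = truth[truth.effect_type == "gene_level"].iloc[0]
        d = geno.dosages[geno.index_of(row.snp_id)].astype(float)
        sub = expr.for_gene(row.gene_id).values.to_numpy()
        expected = sub[0, 0] - row.effect_size * d[0] + row.effect_size * d
        for exon_row in sub:
            np.testing.assert_allclose(exon_row, expected)

    def test_exon_specific_qtl_only_target_varies(self):
        c = cfg(n_factors=0, noise_sd=0.0, exon_offset_sd=0.0,
                prop_qtl=1.0, prop_exon_specific=1.0, exon_count_range=(4, 8))
        genes = simulate_gene_models(c)
        geno = simulate_genotypes(c, genes)
        truth = place_eqtns(genes, geno, c)
        expr = simulate_expression(genes, geno, truth, c)
        row = truth[truth.effect_type == "exon_specific"].iloc[0]
        sub = expr.for_gene(row.gene_id)
        for fid, frow in sub.features.iterrows():
            v = sub.values.loc[fid].to_numpy()
            if int(frow.exon_index) == int(row.target_exon):
                assert v.std() > 0
            else:
                assert v.std() == 0


class TestRenderPlatform:
    def test_probe_last_exon_fraction(self):
        c = cfg(n_genes=1000, snp_density=0.0, prop_qtl=0.0, n_factors=0)
        genes = simulate_gene_models(c)
        with pytest.warns(UserWarning):
            geno = simulate_genotypes(c, genes)
        truth = place_eqtns(genes, geno, c)
        exons = simulate_expression(genes, geno, truth, c)
        probes = render_platform(exons, "three_prime_probe", c)
        n_ex = {g.gene_id: g.n_exons for g in genes}
        in_last = sum(
            int(r.exon_index) == n_ex[r.gene_id] - 1
            for _, r in probes.features.iterrows()
        )
        # 850 direct hits plus uniform picks that land on the last exon
        assert 820 <= in_last <= 920

    def test_exon_array_one_probe_per_exon(self, small_study):
        arr = render_platform(small_study["exons"], "exon_array",
                              small_study["config"])
        g = small_study["genes"][0]
        assert (arr.features["gene_id"] == g.gene_id).sum() == g.n_exons

    def test_zero_probe_noise_reproduces_truth(self, small_study):
        c = dataclasses.replace(small_study["config"], probe_noise_sd=0.0)
        arr = render_platform(small_study["exons"], "exon_array", c)
        np.testing.assert_allclose(
            arr.values.to_numpy(), small_study["exons"].values.to_numpy()
        )

    def test_counts_nonnegative_and_poisson_scaled(self, small_study):
        cnt = render_platform(small_study["exons"], "exon_counts",
                              small_study["config"])
        v = cnt.values.to_numpy()
        assert (v >= 0).all() and np.allclose(v, np.round(v))

    def test_unknown_platform_rejected(self, small_study):
        with pytest.raises(ValueError, match="unknown platform"):
            render_platform(small_study["exons"], "nanostring",
                            small_study["config"])

    def test_rendering_is_seed_deterministic(self, small_study):
        a = render_platform(small_study["exons"], "three_prime_probe",
                            small_study["config"])
        b = render_platform(small_study["exons"], "three_prime_probe",
                            small_study["config"])
        pd.testing.assert_frame_equal(a.values, b.values)
        pd.testing.assert_frame_equal(a.features, b.features)


def test_invalid_probabilities_rejected():
    with pytest.raises(ValueError, match="prop_qtl"):
        SimulationConfig(prop_qtl=1.5).validate()
    with pytest.raises(ValueError, match="lambda_distance"):
        SimulationConfig(lambda_distance=(0.0, 1.0)).validate()
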