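"""Self-contained validation experiments on synthetic data.

Each function simulates a study under stated conditions, runs the
relevant pipeline stages, and returns summary numbers. They back both the
acceptance test suite and ``scripts/acceptance.py``; problem sizes are
chosen so the full battery runs on a single CPU in minutes (see
docs/methods.md for the rationale behind each size).
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .mapping import CisScanner, empirical_fdr_threshold, map_cis_qtls, test_association
from .models import ExpressionMatrix
from .pipeline import PipelineConfig, _gene_level_matrix, analyze_platform, preprocess_platform
from .positional import PositionalData, compare_models, fit_positional_model
from .preprocess import quantile_normalize, regress_out_factors, select_num_pcs
from .replication import cross_platform_test
from .summarize import exon_residual_matrix
from .synthetic import (
    SimulationConfig,
    place_eqtns,
    render_platform,
    sample_table,
    simulate_expression,
    simulate_gene_models,
    simulate_genotypes,
)

__all__ = [
    "regression_oracle_error",
    "pc_selection_rates",
    "factor_correction_type1",
    "fdr_calibration",
    "or_recovery",
    "model_selection",
    "platform_artifact",
    "replication_pattern",
]


def _seed(base: int, k: int) -> int:
    return int(np.random.SeedSequence([base, k]).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# 1. regression oracle
# ---------------------------------------------------------------------------

def regression_oracle_error(n_pairs: int = 10_000, n: int = 50, seed: int = 0) -> dict:
    """Max relative error of OLS p-values vs the correlation-test closed form.

    The oracle is the textbook identity t = r sqrt((n-2)/(1-r^2)) with p
    from the t distribution, computed independently of the regression path.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_pairs):
        y = rng.normal(size=n)
        g = rng.binomial(2, rng.uniform(0.05, 0.5), size=n).astype(float)
        if g.std() == 0:
            continue
        res = test_association(y, g)
        r = np.corrcoef(y, g)[0, 1]
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p_oracle = 2.0 * stats.t.sf(abs(t), n - 2)
        worst = max(worst, abs(res.p - p_oracle) / p_oracle)
    return {"max_rel_err": worst, "n": n_pairs}


# ---------------------------------------------------------------------------
# 4. permutation-calibrated PC selection
# ---------------------------------------------------------------------------

def pc_selection_rates(
    n_runs: int = 100,
    n_features: int = 50,
    n_samples: int = 40,
    n_perm: int = 100,
    seed: int = 0,
) -> dict:
    """Monte-Carlo rates of selecting K=0 on iid noise and K=3 with 3 factors."""
    k0 = k3 = 0
    for b in range(n_runs):
        rng = np.random.default_rng(_seed(seed, b))
        noise = rng.normal(size=(n_features, n_samples))
        sel = select_num_pcs(noise, n_perm=n_perm, seed=_seed(seed, 10_000 + b))
        k0 += sel.n_pcs == 0
        load = rng.normal(0.0, 2.0, size=(n_features, 3))
        fac = rng.normal(size=(3, n_samples))
        planted = load @ fac + rng.normal(size=(n_features, n_samples))
        sel = select_num_pcs(planted, n_perm=n_perm, seed=_seed(seed, 20_000 + b))
        k3 += sel.n_pcs == 3
    return {"rate_k0_on_noise": k0 / n_runs, "rate_k3_planted": k3 / n_runs,
            "n": n_runs}


# ---------------------------------------------------------------------------
# 5. type-I error after factor removal
# ---------------------------------------------------------------------------

def factor_correction_type1(
    n_features: int = 250,
    n_snps_per_feature: int = 40,
    seed: int = 0,
    alpha: float = 0.01,
) -> dict:
    """Type-I error of association tests on null genes after correction.

    Expression has 3 planted hidden factors plus population mean shifts but
    no genetic effects; after quantile normalization, centering,
    permutation-calibrated PC selection and elastic-net residualization,
    every feature is tested against independent null SNPs.
    """
    cfg = SimulationConfig(n_samples={"CEU": 50, "YRI": 50}, seed=seed)
    samples = sample_table(cfg)
    n = len(samples)
    rng = np.random.default_rng(_seed(seed, 1))
    fac = rng.normal(size=(3, n))
    load = rng.normal(0.0, 1.0, size=(n_features, 3))
    shift = rng.normal(0.0, 1.0, size=n_features)
    pop_ind = (samples["population"] == "YRI").to_numpy(float)
    vals = load @ fac + shift[:, None] * pop_ind[None, :] + rng.normal(size=(n_features, n))
    features = pd.DataFrame(
        {
            "gene_id": [f"G{i}" for i in range(n_features)],
            "exon_index": 0,
            "chrom": "chr1",
            "start": np.arange(n_features) * 1000,
            "end": np.arange(n_features) * 1000 + 100,
            "platform": "exon_array",
        },
        index=pd.Index([f"F{i}" for i in range(n_features)], name="feature_id"),
    )
    expr = ExpressionMatrix(
        pd.DataFrame(vals, index=features.index, columns=samples.index),
        features, samples,
    )
    from .preprocess import center_by_population

    expr = center_by_population(quantile_normalize(expr))
    sel = select_num_pcs(expr, n_perm=100, seed=_seed(seed, 2))
    resid, _ = regress_out_factors(expr, sel, covariates="auto")
    y = resid.values.to_numpy()
    hits = total = 0
    for i in range(n_features):
        maf = rng.uniform(0.05, 0.5, size=n_snps_per_feature)
        g = rng.binomial(2, maf[:, None], size=(n_snps_per_feature, n)).astype(float)
        gc = g - g.mean(axis=1, keepdims=True)
        norm = np.sqrt(np.einsum("ij,ij->i", gc, gc))
        ok = norm > 0
        yc = y[i] - y[i].mean()
        r = (gc[ok] @ yc) / (norm[ok] * np.sqrt(yc @ yc))
        t = r * np.sqrt((n - 2) / np.maximum(1 - r**2, 1e-300))
        p = 2 * stats.t.sf(np.abs(t), n - 2)
        hits += int((p < alpha).sum())
        total += int(ok.sum())
    return {"type1_error": hits / total, "n": total, "k_selected": sel.n_pcs}


# ---------------------------------------------------------------------------
# 6. empirical FDR calibration on fully null data
# ---------------------------------------------------------------------------

def fdr_calibration(
    n_seeds: int = 20,
    n_genes: int = 500,
    n_perm: int = 10,
    target: float = 0.05,
    seed: int = 0,
) -> dict:
    """Mean realized false-discovery proportion on simulations without QTLs.

    Every discovery on null data is false: FDP per seed is V/max(R,1).
    """
    fdps = []
    for b in range(n_seeds):
        cfg = SimulationConfig(
            n_genes=n_genes,
            n_samples={"CEU": 40, "YRI": 40},
            prop_qtl=0.0,
            n_factors=0,
            snp_density=0.5,
            seed=_seed(seed, b),
        )
        genes = simulate_gene_models(cfg)
        geno = simulate_genotypes(cfg, genes)
        truth = place_eqtns(genes, geno, cfg)
        exons = simulate_expression(genes, geno, truth, cfg)
        expr = render_platform(exons, "three_prime_probe", cfg)
        expr = quantile_normalize(expr)
        from .preprocess import center_by_population

        expr = center_by_population(expr)
        gmodels = {g.gene_id: g for g in genes}
        gl = _gene_level_matrix(expr, gmodels)
        scanner = CisScanner(gl, geno, gmodels, level="gene")
        res = map_cis_qtls(gl, geno, gmodels, scanner=scanner)
        fdr = empirical_fdr_threshold(
            res.best, gl, geno, gmodels, n_perm=n_perm, target=target,
            seed=_seed(seed, 500 + b), scanner=scanner,
        )
        v = len(fdr.significant)
        fdps.append(v / max(v, 1))
    return {"mean_fdp": float(np.mean(fdps)), "fdps": fdps, "n": n_seeds}


# ---------------------------------------------------------------------------
# 7/8. positional-model recovery and selection
# ---------------------------------------------------------------------------

class _PlacementStudy:
    """Fixed gene/SNP layout with a cached softmax placement sampler.

    Candidate sets, annotations and the per-gene eQTN placement
    probabilities (the same softmax prior that ``place_eqtns`` uses) are
    computed once; each replicate only redraws one eQTN per gene and
    refits the positional models.
    """

    def __init__(self, n_genes: int, seed: int, **config_kwargs) -> None:
        from .positional import annotate_positions
        from .synthetic import _prior_scores

        cfg = SimulationConfig(
            n_genes=n_genes, snp_density=0.5, prop_qtl=1.0,
            prop_exon_specific=0.0, seed=seed, **config_kwargs,
        )
        genes = simulate_gene_models(cfg)
        geno = simulate_genotypes(cfg, genes)
        gene_ids, frames, probs = [], [], []
        for gene in genes:
            idx = geno.snps_in(
                gene.chrom, max(0, gene.span_start - cfg.cis_flank),
                gene.span_end + cfg.cis_flank,
            )
            if len(idx) == 0:
                continue
            ann = annotate_positions(gene, geno.positions[idx])
            s = _prior_scores(cfg, ann)
            p = np.exp(s - s.max())
            probs.append(p / p.sum())
            gene_ids.append(gene.gene_id)
            frames.append(ann)
        dummy = [np.full(len(p), 1.0 / len(p)) for p in probs]
        self.data = PositionalData(gene_ids, frames, dummy)
        self.probs = probs

    def fit_replicate(self, rep_seed: int, models: list[str]) -> dict:
        rng = np.random.default_rng(rep_seed)
        logw = np.full(self.data.ptr[-1], -np.inf)
        for g, p in enumerate(self.probs):
            j = rng.choice(len(p), p=p)
            logw[self.data.ptr[g] + j] = 0.0
        self.data.logw = logw
        return {m: fit_positional_model(self.data, m) for m in models}


def or_recovery(
    n_reps: int = 100, n_genes: int = 2000, true_or: float = 12.0, seed: int = 0
) -> dict:
    """Exon/intron odds-ratio recovery when eQTNs are placed under Model 2.

    The generator's default prior has exon/intron enrichment exactly
    ``true_or`` and no special last-exon effect; every gene is a
    "significant" gene with its true eQTN known. Reports the distribution
    of the Model-2 OR estimate and the Wald 95% CI coverage of the truth.
    """
    study = _PlacementStudy(n_genes, _seed(seed, 0))
    est, cover = [], 0
    for b in range(n_reps):
        fits = study.fit_replicate(_seed(seed, 1 + b), ["M2"])
        row = fits["M2"].odds_ratios.iloc[0]
        est.append(row["odds_ratio"])
        cover += row["ci_low"] <= true_or <= row["ci_high"]
    return {
        "median_or": float(np.median(est)),
        "or_estimates": est,
        "coverage": cover / n_reps,
        "true_or": true_or,
        "n": n_reps,
    }


def model_selection(
    n_reps: int = 100, n_genes: int = 1000, last_exon_or: float = 4.0, seed: int = 0
) -> dict:
    """AIC model selection under M3 truth (strong last-exon effect) and M2 truth.

    Under M3 truth the last-exon enrichment is ``last_exon_or`` times the
    other-exon enrichment; under M2 truth the extra M3 parameter is wasted
    and its expected AIC penalty is 2 - E[chi2_1] = 1 (at most ~2).
    """
    lam_last = SimulationConfig().lambda_exon + float(np.log(last_exon_or))
    study3 = _PlacementStudy(n_genes, _seed(seed, 100_000),
                             lambda_last_exon=lam_last)
    m3_wins = 0
    for b in range(n_reps):
        fits = study3.fit_replicate(_seed(seed, 200_000 + b),
                                    ["M0", "M1", "M2", "M3"])
        tab = compare_models(list(fits.values()))
        m3_wins += tab.loc[tab["best"], "model"].iloc[0] == "M3"

    study2 = _PlacementStudy(n_genes, _seed(seed, 300_000))
    penalties = []
    for b in range(n_reps):
        fits = study2.fit_replicate(_seed(seed, 400_000 + b), ["M2", "M3"])
        penalties.append(fits["M3"].aic - fits["M2"].aic)
    return {
        "m3_selection_rate": m3_wins / n_reps,
        "mean_m3_penalty_under_m2": float(np.mean(penalties)),
        "n": n_reps,
    }


# ---------------------------------------------------------------------------
# 9/10. headline platform-artifact experiment
# ---------------------------------------------------------------------------

def platform_artifact(n_genes: int = 2400, seed: int = 0) -> dict:
    """Full-pipeline comparison of the 3'-probe and exon-count platforms.

    Gene-level QTLs are placed with no last-exon preference; exon-specific
    QTLs are biased to last exons. Both observation layers of the same
    underlying study are preprocessed, summarized to gene level, mapped,
    and fit with models M0-M3. Returns the AIC tables and odds ratios per
    platform plus the intermediate objects for the replication analysis.
    """
    cfg = SimulationConfig(n_genes=n_genes, seed=_seed(seed, 0))
    genes = simulate_gene_models(cfg)
    geno = simulate_genotypes(cfg, genes)
    truth = place_eqtns(genes, geno, cfg)
    exons = simulate_expression(genes, geno, truth, cfg)
    gmodels = {g.gene_id: g for g in genes}
    pipe = PipelineConfig(seed=_seed(seed, 1), simulation=cfg)
    out: dict = {"truth": truth, "gene_models": gmodels, "genotypes": geno}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for platform in ("three_prime_probe", "exon_counts"):
            rendered = render_platform(exons, platform, cfg)
            corrected, info = preprocess_platform(rendered, seed=pipe.seed)
            ana = analyze_platform(corrected, gmodels, geno, pipe)
            ana["corrected"] = corrected
            ana["preprocess_info"] = info
            out[platform] = ana
    a3 = out["three_prime_probe"]["aic_table"].set_index("model")
    ac = out["exon_counts"]["aic_table"].set_index("model")
    or3 = out["three_prime_probe"]["fits"]["M3"].odds_ratios.set_index("contrast")
    out["summary"] = {
        "three_prime_m2_minus_m3_aic": float(a3.loc["M2", "aic"] - a3.loc["M3", "aic"]),
        "three_prime_best_model": a3["delta_aic"].idxmin(),
        "counts_m3_delta_aic": float(ac.loc["M3", "delta_aic"]),
        "counts_m2_delta_aic": float(ac.loc["M2", "delta_aic"]),
        "last_exon_or": float(or3.loc["last exon/intron", "odds_ratio"]),
        "exon_nonlast_or": float(or3.loc["exon (except last)/intron", "odds_ratio"]),
        "n_significant_three_prime": int(len(out["three_prime_probe"]["fdr"].significant)),
        "n_significant_counts": int(len(out["exon_counts"]["fdr"].significant)),
    }
    return out


def replication_pattern(artifact: Mapping) -> dict:
    """Fig-3-style cross-platform replication of the 3'-platform eQTNs.

    Tests each 3' eQTN in the exon-count platform at gene level and against
    exon residuals within 10 kb; returns median replication p per
    positional category and level.
    """
    gmodels = artifact["gene_models"]
    geno = artifact["genotypes"]
    eqtns = artifact["three_prime_probe"]["eqtns"].drop_duplicates(
        subset=["gene_id", "snp_id"]
    )
    tgt = artifact["exon_counts"]
    glm = _gene_level_matrix(tgt["corrected"], gmodels)
    gene_levels = pd.DataFrame(
        glm.values.to_numpy(), index=glm.features["gene_id"].to_numpy(),
        columns=glm.sample_ids,
    )
    exon_res = exon_residual_matrix(tgt["corrected"], gmodels)
    rep = cross_platform_test(eqtns, gene_levels, exon_res, geno, gmodels)
    medians = (
        rep[rep["p"].notna()]
        .groupby(["level", "category"])["p"]
        .agg(["median", "size"])
    )
    return {"table": rep, "medians": medians}
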