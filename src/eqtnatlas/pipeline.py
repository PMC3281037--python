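"""End-to-end workflows tying the stages together.

The synthetic workflow generates a study with known ground truth, renders
it through each platform's observation model, and runs the full analysis:
preprocessing, gene-level summarization, cis-QTL mapping with empirical
FDR, positional-model comparison, and cross-platform replication of the
3'-platform eQTNs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import io as eio
from .mapping import CisScanner, empirical_fdr_threshold, map_cis_qtls
from .models import ExpressionMatrix, GeneModel, GenotypeMatrix
from .positional import (
    MODELS,
    PositionalData,
    compare_models,
    fit_positional_model,
    position_histogram,
)
from .preprocess import (
    center_by_population,
    filter_non_expressed,
    filter_probes_overlapping_variants,
    quantile_normalize,
    regress_out_factors,
    select_num_pcs,
)
from .replication import cross_platform_test, qq_summary
from .summarize import exon_residual_matrix, summarize_gene_levels
from .synthetic import (
    PLATFORMS,
    SimulationConfig,
    place_eqtns,
    render_platform,
    simulate_expression,
    simulate_gene_models,
    simulate_genotypes,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "preprocess_platform", "analyze_platform", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Analysis constants (paper-standard defaults) plus simulation settings."""

    seed: int = 0
    gene_window: int = 100_000
    exon_window: int = 10_000
    maf_floor: float = 0.01
    fdr_target: float = 0.05
    n_perm_fdr: int = 10
    n_perm_pca: int = 100
    pca_quantile: float = 0.975
    models: tuple[str, ...] = MODELS
    platforms: tuple[str, ...] = PLATFORMS
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    # real-data inputs (optional; used instead of simulation when all set)
    gene_models_path: str | None = None
    genotypes_path: str | None = None
    expression_prefix: str | None = None

    def __post_init__(self) -> None:
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig(**self.simulation)
        self.simulation.seed = self.seed
        for name, val in (("fdr_target", self.fdr_target),):
            if not 0 < val < 1:
                raise ValueError(f"{name} must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def preprocess_platform(
    expr: ExpressionMatrix,
    variants: pd.DataFrame | None = None,
    n_perm: int = 100,
    upper_quantile: float = 0.975,
    seed: int = 0,
    correct_factors: bool = True,
) -> tuple[ExpressionMatrix, dict]:
    """Standard per-platform preprocessing of a feature-level matrix.

    Probe/SNP overlap filter (if a variant table is given), non-expressed
    filter (zero-median for counts, low-MAD otherwise), quantile
    normalization within population, population centering, then
    permutation-calibrated PC selection and elastic-net residualization.
    """
    info: dict = {}
    if variants is not None:
        keep = filter_probes_overlapping_variants(expr.features, variants)
        info["n_probe_variant_dropped"] = expr.n_features - len(keep)
        expr = expr.subset_features(keep)
    platform = expr.features["platform"].iloc[0]
    method = "zero_median_count" if platform == "exon_counts" else "mad"
    keep = filter_non_expressed(expr, method=method)
    info["n_non_expressed_dropped"] = expr.n_features - len(keep)
    expr = expr.subset_features(keep)
    expr = quantile_normalize(expr)
    expr = center_by_population(expr)
    if correct_factors:
        correction = select_num_pcs(
            expr, n_perm=n_perm, upper_quantile=upper_quantile, seed=seed
        )
        info["n_pcs"] = correction.n_pcs
        expr, report = regress_out_factors(expr, correction, covariates="auto")
        info["lambda_report"] = report
    return expr, info


def _gene_level_matrix(
    expr: ExpressionMatrix, gene_models: Mapping[str, GeneModel]
) -> ExpressionMatrix:
    """One gene-level feature per gene (median polish unless single-probe)."""
    per_gene_counts = expr.features.groupby("gene_id").size()
    if (per_gene_counts == 1).all():
        gene_levels = expr.values.copy()
        gene_levels.index = expr.features["gene_id"].to_numpy()
    else:
        gene_levels = summarize_gene_levels(expr)
    rows = []
    for gid in gene_levels.index:
        g = gene_models[gid]
        rows.append(
            {
                "feature_id": gid,
                "gene_id": gid,
                "exon_index": pd.NA,
                "chrom": g.chrom,
                "start": g.span_start,
                "end": g.span_end,
                "platform": "gene_level",
            }
        )
    features = pd.DataFrame(rows).set_index("feature_id")
    vals = pd.DataFrame(
        gene_levels.to_numpy(), index=features.index, columns=expr.sample_ids
    )
    return ExpressionMatrix(vals, features, expr.samples)


def analyze_platform(
    expr: ExpressionMatrix,
    gene_models: Mapping[str, GeneModel],
    genotypes: GenotypeMatrix,
    config: PipelineConfig,
    fit_models: bool = True,
) -> dict:
    """Gene-level cis-eQTL analysis of one corrected feature matrix.

    Summarizes to gene level, maps cis QTLs, calibrates the empirical FDR,
    forms tie-shared eQTN weights for significant genes and (optionally)
    fits and compares the positional models M0-M3.
    """
    gene_expr = _gene_level_matrix(expr, gene_models)
    scanner = CisScanner(gene_expr, genotypes, gene_models, level="gene")
    res = map_cis_qtls(gene_expr, genotypes, gene_models, level="gene", scanner=scanner)
    fdr = empirical_fdr_threshold(
        res.best, gene_expr, genotypes, gene_models,
        level="gene", n_perm=config.n_perm_fdr, target=config.fdr_target,
        seed=config.seed, scanner=scanner,
    )
    out = {
        "gene_expr": gene_expr,
        "map": res,
        "fdr": fdr,
        "eqtns": res.eqtn_weights(fdr.significant) if len(fdr.significant) else
            pd.DataFrame(columns=["feature_id", "gene_id", "snp_id", "weight", "min_p"]),
    }
    if fit_models and len(fdr.significant):
        data = PositionalData.from_mapping(
            out["eqtns"], gene_models, genotypes, flank=config.gene_window
        )
        fits = {m: fit_positional_model(data, m) for m in config.models}
        out["fits"] = fits
        out["aic_table"] = compare_models(list(fits.values()))
        out["histogram"] = position_histogram(out["eqtns"], gene_models, genotypes)
    return out


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the full synthetic (or file-based) workflow into a run directory.

    Deterministic given ``config.seed``; every stage writes TSV outputs with
    provenance headers. Returns the in-memory stage results.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = (config.gene_models_path, config.genotypes_path, config.expression_prefix)
    real_mode = all(p is not None for p in paths)
    if any(p is not None for p in paths) and not real_mode:
        raise ValueError(
            "real mode needs gene_models_path, genotypes_path and "
            "expression_prefix all set"
        )
    if real_mode:
        for p in (config.gene_models_path, config.genotypes_path):
            if not Path(p).exists():
                raise FileNotFoundError(f"input path does not exist: {p}")
    results: dict = {}
    if real_mode:
        genes = eio.read_gene_models(config.gene_models_path)
        genotypes = eio.read_genotypes(config.genotypes_path)
        rendered = {"input": eio.read_expression(config.expression_prefix)}
        truth = None
    else:
        sim = config.simulation
        genes = simulate_gene_models(sim)
        genotypes = simulate_genotypes(sim, genes)
        truth = place_eqtns(genes, genotypes, sim)
        true_exons = simulate_expression(genes, genotypes, truth, sim)
        rendered = {p: render_platform(true_exons, p, sim) for p in config.platforms}
        eio.write_gene_models(genes, out / "gene_models.bed")
        eio.write_genotypes_tsv(genotypes, out / "genotypes.tsv")
        eio.write_tsv(truth.set_index("gene_id"), out / "truth.tsv", stage="simulate",
                      seed=config.seed)
    gmodels = {g.gene_id: g for g in genes}
    results.update(genes=genes, genotypes=genotypes, truth=truth, gene_models=gmodels)

    per_platform: dict[str, dict] = {}
    for name, expr in rendered.items():
        corrected, info = preprocess_platform(
            expr, n_perm=config.n_perm_pca, upper_quantile=config.pca_quantile,
            seed=config.seed,
        )
        eio.write_expression(corrected, out / f"{name}.corrected", stage="preprocess",
                             n_pcs=info.get("n_pcs"))
        ana = analyze_platform(corrected, gmodels, genotypes, config)
        ana["preprocess_info"] = info
        ana["corrected"] = corrected
        eio.write_tsv(ana["map"].best.drop(columns=["tied_snps"]),
                      out / f"{name}.cis_map.tsv", stage="map",
                      level="gene", fdr=config.fdr_target)
        eio.write_tsv(ana["eqtns"].set_index("gene_id"), out / f"{name}.eqtns.tsv",
                      stage="map", fdr=config.fdr_target)
        if "aic_table" in ana:
            eio.write_tsv(ana["aic_table"].set_index("model"),
                          out / f"{name}.aic.tsv", stage="fit")
            ors = pd.concat(
                [f.odds_ratios.assign(model=m) for m, f in ana["fits"].items()],
                ignore_index=True,
            )
            eio.write_tsv(ors.set_index("model"), out / f"{name}.odds_ratios.tsv",
                          stage="fit")
            eio.write_tsv(ana["histogram"], out / f"{name}.histogram.tsv",
                          stage="fit", index=False)
        per_platform[name] = ana
    results["platforms"] = per_platform

    # cross-platform replication: 3' eQTNs tested in the exon platforms
    src = per_platform.get("three_prime_probe")
    if src is not None and len(src["eqtns"]):
        eqtns = src["eqtns"].drop_duplicates(subset=["gene_id", "snp_id"])
        for target in ("exon_array", "exon_counts"):
            tgt = per_platform.get(target)
            if tgt is None:
                continue
            gene_levels = pd.DataFrame(
                tgt["gene_expr"].values.to_numpy(),
                index=tgt["gene_expr"].features["gene_id"].to_numpy(),
                columns=tgt["gene_expr"].sample_ids,
            )
            exon_res = exon_residual_matrix(tgt["corrected"], gmodels)
            rep = cross_platform_test(
                eqtns, gene_levels, exon_res, genotypes, gmodels,
                window=config.exon_window,
            )
            qq = qq_summary(rep["p"], rep["category"] + ":" + rep["level"])
            eio.write_tsv(rep, out / f"replication.{target}.tsv",
                          stage="replicate", index=False)
            eio.write_tsv(qq, out / f"replication.{target}.qq.tsv",
                          stage="replicate", index=False)
            results.setdefault("replication", {})[target] = rep
    return results
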