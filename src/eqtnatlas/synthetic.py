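"""Synthetic eQTL study generator with known ground truth.

Generates multi-exon gene models on a synthetic chromosome, unlinked cis
genotypes with a realistic MAF spectrum, true exon-level expression with
planted gene-level and exon-specific QTLs placed under a known positional
prior, low-rank hidden confounding, and three platform observation layers:

* ``three_prime_probe`` — a single probe per gene, biased to the last exon
  (as on 3' gene expression arrays);
* ``exon_array`` — one probe per exon;
* ``exon_counts`` — Poisson read counts per exon.

Every operation is deterministic given ``SimulationConfig.seed``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .models import ExpressionMatrix, GeneModel, GenotypeMatrix
from .positional import annotate_positions

__all__ = [
    "SimulationConfig",
    "PLATFORMS",
    "simulate_gene_models",
    "sample_table",
    "simulate_genotypes",
    "place_eqtns",
    "simulate_expression",
    "render_platform",
]

logger = logging.getLogger(__name__)

PLATFORMS = ("three_prime_probe", "exon_array", "exon_counts")

# Default distance-bin log-enrichments of the placement prior (one value per
# signed TSS-distance bin, most-upstream first): a smooth peak at the TSS.
_DEFAULT_LAMBDA_DISTANCE = (
    0.0, 0.6, 1.0, 1.5, 2.0, 2.6, 3.2,
    3.2, 2.6, 2.0, 1.5, 1.0, 0.6, 0.0,
)

_LOG12 = float(np.log(12.0))
_LOG2 = float(np.log(2.0))


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Length/count distributions are uniform over inclusive integer ranges;
    a degenerate range ``(k, k)`` fixes the value. Effect sizes are in
    units of the residual noise standard deviation.
    """

    # cohort
    n_samples: Mapping[str, int] = field(
        default_factory=lambda: {"CEU": 60, "YRI": 60}
    )
    # gene models
    n_genes: int = 300
    exon_count_range: tuple[int, int] = (1, 14)
    exon_length_range: tuple[int, int] = (50, 400)
    last_exon_length_range: tuple[int, int] = (500, 2500)
    intron_length_range: tuple[int, int] = (200, 5000)
    gene_spacing_range: tuple[int, int] = (250_000, 400_000)
    chrom: str = "chr1"
    # genotypes
    snp_density: float = 1.0  # SNPs per kb over transcript +/- cis_flank
    maf_range: tuple[float, float] = (0.01, 0.5)
    cis_flank: int = 100_000
    # placement prior (ground truth; coefficients on the M3 annotation basis,
    # intergenic baseline 0)
    lambda_distance: tuple[float, ...] = _DEFAULT_LAMBDA_DISTANCE
    lambda_intron: float = _LOG2
    lambda_exon: float = _LOG2 + _LOG12
    lambda_last_exon: float | None = None  # None -> same as lambda_exon
    # QTL architecture
    prop_qtl: float = 0.5
    prop_exon_specific: float = 0.4
    last_exon_bias: float = 0.85
    beta_gene: float = 1.0
    beta_exon: float = 1.5
    sqtn_window: int = 10_000
    # extra log-odds that an exon-specific QTL's causal SNP lies inside the
    # target exon itself (splice/UTR regulatory elements are exon-proximal)
    sqtn_target_exon_boost: float = float(np.log(4.0))
    # expression model
    baseline_mean: float = 2.0
    baseline_sd: float = 0.5
    exon_offset_sd: float = 0.5
    n_factors: int = 5
    factor_sd: float = 1.0
    loading_sd: float = 0.5
    noise_sd: float = 1.0
    # observation layers
    probe_last_exon_frac: float = 0.85
    probe_noise_sd: float = 0.3
    count_scale: float = 20.0
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "prop_qtl", "prop_exon_specific", "last_exon_bias",
            "probe_last_exon_frac",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "exon_count_range", "exon_length_range", "last_exon_length_range",
            "intron_length_range", "gene_spacing_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: lower bound exceeds upper bound")
        if self.exon_length_range[0] < 1 or self.last_exon_length_range[0] < 1:
            raise ValueError("exon length distribution must exclude zero-length exons")
        if self.exon_count_range[0] < 1:
            raise ValueError("genes need at least one exon")
        if self.maf_range[0] > self.maf_range[1] or self.maf_range[1] > 0.5:
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.snp_density < 0:
            raise ValueError("snp_density must be nonnegative")
        if len(self.lambda_distance) != 14:
            raise ValueError("lambda_distance must have one value per distance bin (14)")
        if any(n < 1 for n in self.n_samples.values()):
            raise ValueError("population sample sizes must be positive")

    @property
    def lambda_last(self) -> float:
        return self.lambda_exon if self.lambda_last_exon is None else self.lambda_last_exon

    @property
    def total_samples(self) -> int:
        return sum(self.n_samples.values())


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    # one independent, reproducible stream per stage
    return np.random.default_rng([stage, config.seed])


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

def simulate_gene_models(config: SimulationConfig) -> list[GeneModel]:
    """Draw non-overlapping gene models along one synthetic chromosome.

    Exon counts and exon/intron lengths are uniform over the configured
    ranges; the last exon has its own (longer) length range, mirroring the
    long 3' UTRs of real genes. Strands are random but both are guaranteed
    present whenever two or more genes are drawn.
    """
    config.validate()
    rng = _rng(config, 1)
    genes: list[GeneModel] = []
    cursor = 1_000_000
    strands = (rng.random(config.n_genes) < 0.5).astype(int)
    if config.n_genes >= 2 and len(set(strands)) == 1:
        strands[-1] = 1 - strands[-1]
    for i in range(config.n_genes):
        cursor += int(rng.integers(*_incl(config.gene_spacing_range)))
        n_ex = int(rng.integers(*_incl(config.exon_count_range)))
        exon_lens = rng.integers(*_incl(config.exon_length_range), size=n_ex)
        intron_lens = (
            rng.integers(*_incl(config.intron_length_range), size=n_ex - 1)
            if n_ex > 1 else np.array([], dtype=int)
        )
        strand = "+" if strands[i] == 0 else "-"
        # genomic layout left-to-right; transcription-order last exon gets the
        # long length (leftmost block on the minus strand)
        lens = list(exon_lens)
        last_t = n_ex - 1 if strand == "+" else 0
        lens[last_t] = int(rng.integers(*_incl(config.last_exon_length_range)))
        blocks = []
        p = cursor
        for j in range(n_ex):
            blocks.append((p, p + int(lens[j])))
            p += int(lens[j])
            if j < n_ex - 1:
                p += int(intron_lens[j])
        cursor = p
        exons = tuple(blocks) if strand == "+" else tuple(blocks[::-1])
        genes.append(
            GeneModel(gene_id=f"G{i:04d}", chrom=config.chrom, strand=strand, exons=exons)
        )
    return genes


def _incl(rng_pair: tuple[int, int]) -> tuple[int, int]:
    lo, hi = rng_pair
    return int(lo), int(hi) + 1


# ---------------------------------------------------------------------------
# samples and genotypes
# ---------------------------------------------------------------------------

def sample_table(config: SimulationConfig) -> pd.DataFrame:
    """Sample metadata: ids, population labels and sex, deterministic per seed."""
    rng = _rng(config, 0)
    ids, pops = [], []
    for pop in sorted(config.n_samples):
        n = config.n_samples[pop]
        ids.extend(f"{pop}{i:03d}" for i in range(n))
        pops.extend([pop] * n)
    sex = rng.choice(["F", "M"], size=len(ids))
    return pd.DataFrame({"population": pops, "sex": sex}, index=pd.Index(ids, name="sample_id"))


def simulate_genotypes(
    config: SimulationConfig, genes: Sequence[GeneModel]
) -> GenotypeMatrix:
    """Place unlinked SNPs over each gene's transcript plus cis flanks.

    SNP counts per gene are Poisson at ``snp_density`` per kb; positions are
    uniform over the window; dosages are Binomial(2, MAF) per sample. SNPs
    whose drawn or realized MAF is at or below 1% are discarded, matching
    the analysis-side MAF floor.
    """
    if not genes:
        raise ValueError("no gene models supplied")
    config.validate()
    rng = _rng(config, 2)
    samples = sample_table(config)
    n = len(samples)
    ids, chroms, positions, mafs = [], [], [], []
    dosage_blocks = []
    counter = 0
    for gene in genes:
        lo = max(0, gene.span_start - config.cis_flank)
        hi = gene.span_end + config.cis_flank
        n_snps = rng.poisson(config.snp_density * (hi - lo) / 1000.0)
        if n_snps == 0:
            continue
        pos = np.sort(rng.integers(lo, hi, size=n_snps))
        maf = rng.uniform(*config.maf_range, size=n_snps)
        keep = maf > GenotypeMatrix.MAF_FLOOR
        pos, maf = pos[keep], maf[keep]
        if len(pos) == 0:
            continue
        dose = rng.binomial(2, maf[:, None], size=(len(pos), n)).astype(np.int8)
        ids.extend(f"snp{counter + k:07d}" for k in range(len(pos)))
        counter += len(pos)
        chroms.extend([gene.chrom] * len(pos))
        positions.append(pos)
        mafs.append(maf)
        dosage_blocks.append(dose)
    if not positions:
        warnings.warn("snp density yielded no SNPs; returning empty genotype matrix")
        return GenotypeMatrix(
            [], [], [], np.zeros((0, n), dtype=np.int8), list(samples.index)
        )
    return GenotypeMatrix(
        ids,
        chroms,
        np.concatenate(positions),
        np.concatenate(dosage_blocks),
        list(samples.index),
    )


# ---------------------------------------------------------------------------
# truth: QTL placement
# ---------------------------------------------------------------------------

def _prior_scores(config: SimulationConfig, ann: pd.DataFrame) -> np.ndarray:
    lam_d = np.asarray(config.lambda_distance, dtype=float)
    s = lam_d[np.asarray(ann["bin"], dtype=np.intp)]
    exon = np.asarray(ann["exon"])
    last = np.asarray(ann["last_exon"])
    s = s + config.lambda_intron * np.asarray(ann["intron"])
    s = s + config.lambda_exon * (exon & ~last)
    s = s + config.lambda_last * last
    return s


def place_eqtns(
    genes: Sequence[GeneModel],
    genotypes: GenotypeMatrix,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Plant gene-level and exon-specific QTLs under the true positional prior.

    Each gene carries a QTL with probability ``prop_qtl``; a QTL is
    exon-specific with probability ``prop_exon_specific`` and then targets
    the last exon with probability ``last_exon_bias`` (otherwise a uniformly
    chosen other exon). Gene-level eQTNs are drawn from the softmax prior
    ``pi_j ~ exp(lambda' a_j)`` over the gene's cis-window SNPs;
    exon-specific eQTNs are drawn from the same prior restricted to SNPs
    within ``sqtn_window`` of the target exon, with an extra in-exon boost.
    A single-exon gene's "exon-specific" QTL is physically indistinguishable
    from a gene-level one (the exon is the transcript), so its eQTN follows
    the ordinary gene-level prior over the full cis window.

    Returns the truth table: one row per gene with columns ``gene_id``,
    ``snp_id``, ``effect_type`` ({gene_level, exon_specific, none}),
    ``target_exon`` and ``effect_size``.
    """
    config.validate()
    rng = _rng(config, 3)
    rows = []
    for gene in genes:
        row = {
            "gene_id": gene.gene_id,
            "snp_id": None,
            "effect_type": "none",
            "target_exon": pd.NA,
            "effect_size": 0.0,
        }
        if rng.random() < config.prop_qtl:
            exon_specific = rng.random() < config.prop_exon_specific
            exon_proximal = exon_specific and gene.n_exons > 1
            if exon_specific:
                if gene.n_exons == 1:
                    target = 0
                elif rng.random() < config.last_exon_bias:
                    target = gene.n_exons - 1
                else:
                    target = int(rng.integers(0, gene.n_exons - 1))
            else:
                target = None
            if exon_proximal:
                s, e = gene.exons[target]
                lo = max(0, s - config.sqtn_window)
                hi = e + config.sqtn_window
            else:
                lo = max(0, gene.span_start - config.cis_flank)
                hi = gene.span_end + config.cis_flank
            idx = genotypes.snps_in(gene.chrom, lo, hi)
            if len(idx) == 0:
                logger.info("gene %s: no candidate SNPs, QTL not planted", gene.gene_id)
                rows.append(row)
                continue
            pos = genotypes.positions[idx]
            ann = annotate_positions(gene, pos)
            scores = _prior_scores(config, ann)
            if exon_proximal:
                ts, te = gene.exons[target]
                scores = scores + config.sqtn_target_exon_boost * (
                    (pos >= ts) & (pos < te)
                )
            p = np.exp(scores - scores.max())
            p /= p.sum()
            snp = int(rng.choice(len(idx), p=p))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            row["snp_id"] = genotypes.snp_ids[idx[snp]]
            if exon_specific:
                row["effect_type"] = "exon_specific"
                row["target_exon"] = target
                row["effect_size"] = sign * config.beta_exon
            else:
                row["effect_type"] = "gene_level"
                row["effect_size"] = sign * config.beta_gene
        rows.append(row)
    truth = pd.DataFrame(rows)
    truth["target_exon"] = truth["target_exon"].astype("Int64")
    return truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(
    genes: Sequence[GeneModel],
    genotypes: GenotypeMatrix,
    truth: pd.DataFrame,
    config: SimulationConfig,
) -> ExpressionMatrix:
    """True exon-level expression with confounding and planted QTLs.

    exon value = gene baseline + exon offset + sum_k loading_gk factor_ks
    + genetic term + N(0, noise_sd^2). A gene-level QTL adds
    beta * dosage to every exon of its gene; an exon-specific QTL adds it
    to the target exon only.
    """
    config.validate()
    rng = _rng(config, 4)
    samples = sample_table(config)
    n = len(samples)
    truth_by_gene = truth.set_index("gene_id")

    factors = rng.normal(0.0, config.factor_sd, size=(config.n_factors, n))
    feat_rows, values = [], []
    for gene in genes:
        base = rng.normal(config.baseline_mean, config.baseline_sd)
        loadings = rng.normal(0.0, config.loading_sd, size=config.n_factors)
        confound = loadings @ factors if config.n_factors else np.zeros(n)
        genetic_gene = np.zeros(n)
        genetic_exon: tuple[int, np.ndarray] | None = None
        if gene.gene_id in truth_by_gene.index:
            t = truth_by_gene.loc[gene.gene_id]
            if t["effect_type"] == "gene_level":
                d = genotypes.dosages[genotypes.index_of(t["snp_id"])]
                genetic_gene = t["effect_size"] * d.astype(float)
            elif t["effect_type"] == "exon_specific":
                d = genotypes.dosages[genotypes.index_of(t["snp_id"])]
                genetic_exon = (int(t["target_exon"]), t["effect_size"] * d.astype(float))
        for k, (s, e) in enumerate(gene.exons):
            off = rng.normal(0.0, config.exon_offset_sd) if config.exon_offset_sd else 0.0
            noise = (
                rng.normal(0.0, config.noise_sd, size=n)
                if config.noise_sd else np.zeros(n)
            )
            v = base + off + confound + genetic_gene + noise
            if genetic_exon is not None and genetic_exon[0] == k:
                v = v + genetic_exon[1]
            feat_rows.append(
                {
                    "feature_id": f"{gene.gene_id}:e{k:02d}",
                    "gene_id": gene.gene_id,
                    "exon_index": k,
                    "chrom": gene.chrom,
                    "start": s,
                    "end": e,
                    "platform": "true_exon",
                }
            )
            values.append(v)
    features = pd.DataFrame(feat_rows).set_index("feature_id")
    vals = pd.DataFrame(
        np.asarray(values), index=features.index, columns=samples.index
    )
    return ExpressionMatrix(vals, features, samples)


# ---------------------------------------------------------------------------
# observation layers
# ---------------------------------------------------------------------------

def render_platform(
    true_exons: ExpressionMatrix,
    platform: str,
    config: SimulationConfig,
) -> ExpressionMatrix:
    """Render true exon levels through one platform's observation model.

    ``three_prime_probe``: one probe per gene, sitting in the last exon with
    probability ``probe_last_exon_frac`` (else a uniformly chosen exon), with
    Gaussian probe noise. ``exon_array``: one noisy probe per exon.
    ``exon_counts``: Poisson counts with rate
    ``exp(level) * exon_length/1kb * count_scale``.
    """
    if platform not in PLATFORMS:
        raise ValueError(f"unknown platform {platform!r}; expected one of {PLATFORMS}")
    config.validate()
    rng = _rng(config, 5 + PLATFORMS.index(platform))
    feats = true_exons.features
    vals = true_exons.values.to_numpy()
    n = true_exons.n_samples

    if platform == "three_prime_probe":
        feat_rows, out = [], []
        for gene_id, grp in feats.groupby("gene_id", sort=False):
            grp = grp.sort_values("exon_index")
            if rng.random() < config.probe_last_exon_frac:
                which = len(grp) - 1
            else:
                which = int(rng.integers(0, len(grp)))
            frow = grp.iloc[which]
            row_i = true_exons.values.index.get_loc(grp.index[which])
            probe_len = min(50, int(frow["end"]) - int(frow["start"]))
            pstart = int(rng.integers(frow["start"], frow["end"] - probe_len + 1))
            noise = rng.normal(0.0, config.probe_noise_sd, size=n) if config.probe_noise_sd else 0.0
            out.append(vals[row_i] + noise)
            feat_rows.append(
                {
                    "feature_id": f"{gene_id}:p3",
                    "gene_id": gene_id,
                    "exon_index": int(frow["exon_index"]),
                    "chrom": frow["chrom"],
                    "start": pstart,
                    "end": pstart + probe_len,
                    "platform": platform,
                }
            )
        features = pd.DataFrame(feat_rows).set_index("feature_id")
        values = pd.DataFrame(np.asarray(out), index=features.index,
                              columns=true_exons.sample_ids)
        return ExpressionMatrix(values, features, true_exons.samples)

    if platform == "exon_array":
        probe_len = 25
        starts = feats["start"].to_numpy()
        ends = feats["end"].to_numpy()
        plen = np.minimum(probe_len, ends - starts)
        pstart = starts + rng.integers(0, np.maximum(ends - starts - plen + 1, 1))
        noise = (
            rng.normal(0.0, config.probe_noise_sd, size=vals.shape)
            if config.probe_noise_sd else 0.0
        )
        features = feats.copy()
        features.index = pd.Index(
            [f"{i}:arr" for i in feats.index], name="feature_id"
        )
        features["start"] = pstart
        features["end"] = pstart + plen
        features["platform"] = platform
        values = pd.DataFrame(vals + noise, index=features.index,
                              columns=true_exons.sample_ids)
        return ExpressionMatrix(values, features, true_exons.samples)

    # exon_counts
    lengths = (feats["end"] - feats["start"]).to_numpy()
    if np.any(lengths <= 0):
        raise ValueError("zero-length exon cannot be rendered as counts")
    rate = np.exp(np.clip(vals, -30.0, 30.0))
    rate = rate * (lengths[:, None] / 1000.0) * config.count_scale
    counts = rng.poisson(rate).astype(float)
    features = feats.copy()
    features.index = pd.Index([f"{i}:cnt" for i in feats.index], name="feature_id")
    features["platform"] = platform
    values = pd.DataFrame(counts, index=features.index, columns=true_exons.sample_ids)
    return ExpressionMatrix(values, features, true_exons.samples)
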