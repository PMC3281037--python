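# eqtnatlas

Where do cis-regulatory variants fall relative to the genes they
control — and how much of the answer is an artifact of the expression
platform? `eqtnatlas` is a toolkit for cis-eQTL/sQTL mapping and for
modelling the *positional* distribution of eQTNs (the putatively causal
nucleotides) across gene annotations, built for regulatory genomicists
who want to compare that distribution across measurement technologies:
single-probe 3' arrays, per-exon arrays, and per-exon read counts.

The scientific core is a weighted-multinomial positional prior. For a
gene *g* with candidate cis SNPs *j* carrying annotation vectors
*a<sub>gj</sub>* (signed TSS-distance bin; intragenic, intron, exon,
last-exon flags), the prior probability that SNP *j* is the eQTN is

&nbsp;&nbsp;&nbsp;&nbsp;π<sub>gj</sub> = exp(λᵀa<sub>gj</sub>) / Σ<sub>k</sub> exp(λᵀa<sub>gk</sub>),

and the log-likelihood of the observed tie-shared best-SNP assignments
*w<sub>g</sub>* is Σ<sub>g</sub> log Σ<sub>j</sub> w<sub>gj</sub>π<sub>gj</sub>.
Four nested parameterizations — M0 (TSS distance), M1 (+intragenic),
M2 (intron/exon), M3 (+last exon) — are fit by maximum likelihood and
compared by AIC; exp of coefficient contrasts gives annotation odds
ratios (e.g. exon/intron) with Wald 95% CIs. Around that core the
package provides the full study pipeline: a synthetic-data generator
with known ground truth (gene models, unlinked cis genotypes, planted
gene-level and exon-specific QTLs, hidden confounders, three platform
observation models), preprocessing (within-population quantile
normalization, permutation-calibrated PC selection, elastic-net
residualization), median-polish gene summarization with exon-specific
residuals, cis-window association mapping with a permutation-based
empirical FDR, and cross-platform replication of eQTNs by positional
category.

The motivating phenomenon: on a platform with a single probe per gene
sitting in the last exon ~85% of the time, QTLs that affect only the
last exon are indistinguishable from whole-gene eQTLs, so the inferred
eQTN distribution acquires a spurious peak at the transcription end
site. Per-exon platforms summarized to gene level (median polish
absorbs single-exon effects) do not show the peak — and the same
last-exon eQTNs replicate at the exon level but not the gene level.

## Worked example

```python
from eqtnatlas import PipelineConfig, SimulationConfig, run_pipeline

cfg = PipelineConfig(
    seed=5, n_perm_pca=20, n_perm_fdr=5,
    simulation=SimulationConfig(n_genes=50, snp_density=0.5,
                                n_samples={"CEU": 25, "YRI": 25}),
)
results = run_pipeline(cfg, "run_dir")
print(results["platforms"]["three_prime_probe"]["aic_table"]
      [["model", "k", "aic", "delta_aic", "best"]].to_string(index=False))
```

prints (3'-probe platform, 5 significant genes at the 5% empirical FDR):

```
model  k       aic  delta_aic  best
   M0 13 55.078847  20.296987 False
   M1 14 41.665663   6.883803 False
   M2 15 35.984997   1.203137 False
   M3 16 34.781860   0.000000  True
```

Each row is one parameterization of the positional prior fit to the
same eQTN assignments; `delta_aic` is the AIC distance from the best
model, so at this toy scale the single-probe platform already leans
toward the last-exon model (M3). At study scale (~2400 genes, below)
the pattern is decisive. The run directory contains all stage outputs
as TSVs — eQTN weights, per-model odds ratios with CIs, the location
histogram, and the cross-platform replication table. The same stages
are scriptable from the shell via `eqtn-atlas simulate | preprocess |
summarize | map | fit | replicate | run`.

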