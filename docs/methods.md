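# Methods

This note documents the models, algorithms, numerical choices, and the
synthetic-data generator behind `eqtnatlas`, in the order the pipeline
runs them.

## Scientific setting

A cis-eQTL study tests, for every gene, all SNPs in a window around the
gene for association with the gene's expression. Beyond finding eQTLs,
one can ask *where* the putatively causal variants (eQTNs) fall relative
to the gene model — upstream of the TSS, in exons, in introns, in the
final exon — and whether annotation enrichments are genuine biology or
artifacts of how expression was measured. Platforms differ in what they
see: a single-probe 3' array measures one exon (usually the last, in the
3' UTR) per gene and cannot distinguish whole-gene effects from effects
on that exon alone; per-exon platforms (exon arrays, RNA-seq exon counts)
can separate the two once exon-specific expression is derived. The
package implements that comparison end to end with a generator whose
ground truth is known.

## Synthetic-data generator (`synthetic`)

The generator emulates the statistical structure of a two-population
LCL-style expression study. All coordinates are 0-based half-open;
strand affects only transcription-order semantics. All draws are keyed
to `SimulationConfig.seed` through per-stage seed sequences, so every
operation is reproducible bit for bit and independent of call order.

**Gene models.** Genes are laid end to end on one synthetic chromosome
with 250–400 kb spacing (cis windows rarely overlap, so the no-LD
assumption of the recovery tests holds). Exon counts are uniform on
1–14; internal exons 50–400 bp; introns 0.2–5 kb; the *last* exon is
drawn from 500–2500 bp, mirroring real 3' UTRs, which are several-fold
longer than internal exons. Both strands always appear.

**Genotypes.** SNPs are unlinked: Poisson-placed at 1 SNP/kb over each
transcript ± 100 kb, MAF uniform on (0.01, 0.5], dosages Binomial(2,
MAF) per sample. SNPs whose drawn *or realized* MAF is ≤ 1% are
discarded, matching the analysis-side MAF floor. LD is deliberately
absent by default: the mapping treats the best SNP as the eQTN proxy,
and placement-recovery tests require the planted SNP to be identifiable.

**QTL placement.** Each gene carries a QTL with probability
`prop_qtl = 0.5`; a QTL is exon-specific with probability
`prop_exon_specific = 0.4` and then targets the last exon with
probability `last_exon_bias = 0.85` (otherwise a uniformly chosen other
exon). Gene-level eQTNs are drawn from the softmax prior
`pi_j ∝ exp(lambda' a_j)` over the cis-window SNPs, with true
coefficients: a smooth distance profile peaking at the TSS,
intron/intergenic log-odds `log 2`, exon/intron log-odds `log 12`
(the order of the enrichment reported for exon arrays), and **no**
special last-exon coefficient — the generating process for gene-level
QTLs is exactly Model 2. Exon-specific eQTNs use the same prior
restricted to the 10 kb window around the target exon, plus an extra
`log 4` in-target-exon boost reflecting that splice/UTR regulatory
variants sit in or at the edges of the affected exon. Effect sizes are
±1.0 sd (gene level) and ±1.5 sd (exon specific) of the residual noise.

**Expression and confounding.** exon value = gene baseline + per-exon
offset + Σ_k loading_gk·factor_ks + genetic term + N(0, 1). Five
Gaussian hidden factors with Gaussian loadings (sd 0.5) produce the
low-rank structure that the PCA-based correction is designed to remove;
this matches the correction model exactly, which is the point — passing
tests show the correction machinery works, not that real confounders are
Gaussian.

**Observation layers.** `three_prime_probe`: one probe per gene, in the
last exon with probability 0.85 (the probe distribution reported for the
3' platform), Gaussian probe noise sd 0.3. `exon_array`: one 25-bp probe
per exon, same noise. `exon_counts`: Poisson with rate
`exp(level)·len/1kb·20` (no overdispersion; a negative-binomial layer
would only add noise to a qualitative comparison). What the generator
does **not** emulate: LD, sequence content, probe cross-hybridization,
GC effects, population structure beyond labeled groups, trans effects —
so green tests say nothing about those failure modes on real data.

## Preprocessing (`preprocess`)

* **Probe/variant overlap filter** drops any feature whose half-open
  interval contains a variant position or overlaps a variant interval.
* **Non-expressed filters**: low-MAD for array features (default
  threshold: the 25th percentile of feature MADs — the original choice
  was made by visual inspection, which is not reproducible, so a
  quartile rule is exposed and overridable); zero within-population
  median in *every* population for counts; an explicit
  `median_level` threshold variant for platforms that need one.
* **Quantile normalization** replaces values by Φ⁻¹(rank/(n+1)) within
  each population; ties get the mean of the normal scores of the ranks
  they span (hence an all-tied vector maps to 0). The k/(n+1) plotting
  position keeps scores bounded.
* **Population centering** subtracts each feature's population mean.
* **PC selection**: eigenvalues of the centered matrix are compared with
  a null built by permuting each feature independently across samples
  (100 permutations; this preserves marginals and destroys inter-feature
  correlation, i.e. assumes independent probes under the null). K is the
  leading run of observed eigenvalues above the per-rank 97.5% envelope;
  stopping at the first failure prevents isolated deep-rank exceedances
  from inflating K.
* **Elastic-net residualization**: per feature, values are regressed on
  the top-K sample-space PCs plus population and sex covariates. The
  ridge penalty λ₂ runs over the six-point grid {1e-2, 1e-1, 1, 10, 1e2,
  1e3} (near-lasso to near-ridge); the lasso penalty is tried at
  {0, 0.01, 0.1} of each feature's λ₁max. The pair minimizing the exact
  leave-one-out residual sum of squares wins. λ₁ = 0 (pure ridge) uses
  the closed-form LOO identity; λ₁ > 0 uses coordinate descent on Gram
  statistics with rank-one leave-one-out downdates and warm starts
  (cross-checked against scikit-learn's `ElasticNet` to ~1e-12).
  Standardization of the design is computed once on the full sample and
  held fixed across LOO folds. With an empty design (K = 0, no
  covariates) the output is the centered input. Because every grid
  penalty is strictly positive, a feature lying exactly in the span of
  the PCs leaves a residual of order λ₂/n rather than exact zero.

## Summarization (`summarize`)

Gene expression is the `overall + sample effect` of Tukey's median
polish on the samples × probes matrix; exon-specific expression is the
residual of that same fit (combined by median when an exon has several
probes), available only for genes with ≥ 2 measured exons. Column
(probe) medians are swept before row (sample) medians: this makes the
gene level *exactly* invariant to a constant offset of any single probe
(a probe-affinity effect), which rows-first sweeping does not guarantee.
Convergence: max absolute change of fitted values < 1e-6, cap 100
iterations; the decomposition identity input = overall + row + column +
residual holds exactly at every iteration by construction. The
alternative two-stage scheme (polish probes within exon to exon levels,
then polish exons) is available behind `strategy="exon_first"`, default
off. Counts are polished on the normalized (rank-normal) scale produced
by preprocessing, not on raw counts. With very few exons (2–3) a
single-exon effect partially leaks into the sample effect — an intrinsic
property of the median at small n; the separation guarantees are
meaningful in the many-exon regime where exon-level analysis applies.

## cis-QTL mapping (`qtl_mapping` = `mapping`)

Candidates: gene level — SNPs inside the transcript or within 100 kb of
either end; exon level — within 10 kb of either exon end, each exon an
independent test. Association is OLS of corrected expression on dosage;
p from t with n−2 df (verified against the correlation-test closed form
t = r√((n−2)/(1−r²)) to 1e-12). Monomorphic dosages are excluded and
counted; exact zero-residual fits are reported as p = 0 with a
`perfect_fit` flag. The per-feature minimum p defines the eQTN; p-values
tied after rounding to 12 significant digits share the assignment weight
equally. The covariates (population, sex, hidden factors) are assumed
already removed by preprocessing, so the association model is plain
`y ~ g`.

**Empirical FDR.** Null minimum-p distributions come from permuting
sample labels within population, jointly across features (preserving the
correlation of features under the null and protecting population means).
FDR(t) = mean null count(≤ t)/observed count(≤ t) with the add-one
convention (observed data counted as one more permutation), which keeps
the estimator valid at the extreme tail when only ~10 permutations are
affordable; the cutoff is the largest observed min-p with FDR ≤ target
(default 5%).

## Positional model (`positional`)

Candidate SNPs of each significant gene are annotated with a signed
transcription-oriented TSS distance binned at ±{0, 1, 5, 10, 25, 50,
100} kb plus open ends (14 bins; the most-upstream bin is the reference,
fixing the softmax's flat direction) and exclusive structure flags. The
prior over a gene's candidates is `softmax(lambda' a)`; the likelihood of
the tie-shared assignment weights is `Σ_g log Σ_j w_gj π_gj`. Models M0
(distance only), M1 (+intragenic), M2 (intron/exon split), M3 (+last
exon) are fit by L-BFGS-B from λ = 0 with analytic gradient; the
analytic observed information (difference of posterior and prior
annotation covariances) gives Wald covariance, delta-method contrasts,
and 95% CIs; coefficients are capped at ±15 and flagged when a bound is
hit (separation). AIC = 2k − 2logL, compared as ΔAIC from the best
model. The likelihood deliberately uses best-SNP tie-shared weights
rather than per-SNP Bayes factors — the best-SNP variant of the
hierarchical model; with unlinked synthetic genotypes the best SNP is
the planted eQTN in ≥ 95% of strong-effect genes, so little is lost.
"Not selected" in the model-comparison sense is operationalized as
ΔAIC(M3) ≥ ΔAIC(M2) − 2, i.e. M3 gains no more than its extra parameter.

The location histogram assigns eQTN weight mass to physical-distance
bins outside the transcript (from the TSS upstream, from the TES
downstream) and fractional-position bins inside, rendered at the average
gene length.

## Replication (`replication`)

Each platform-A eQTN is classified into one of five exclusive
categories — first/internal/last exon, intron, intergenic; the single
exon of a 1-exon gene counts as "last" (it ends at the TES). It is then
tested in platform B against the gene-level summary and against each
exon residual within 10 kb (distance from either exon end, half-open),
on the intersection of the sample sets. QQ summaries use plotting
positions (i − 0.5)/n per category.

## Problem sizes and experiment design (`experiments`)

The validation battery sizes were fixed at design time so the whole
suite runs on one CPU in minutes: 10 000 oracle pairs; 100 Monte-Carlo
runs of 50 × 40 PC selection with 100 permutations; 10 000
post-correction null tests (250 features × 40 SNPs, 100 samples);
20 fully-null FDR seeds of 500 genes × 10 permutations; 100 replicates
of 2000-gene (recovery) and 1000-gene (selection) placement studies at
0.5 SNP/kb; and a single 2400-gene two-platform study for the headline
artifact and replication patterns. Placement replicates reuse a fixed
gene/SNP layout and redraw only the eQTN per gene from the (fixed)
softmax prior — the estimator is conditional on the candidate design, so
coverage statements are unaffected — and the AIC selection experiment
under M2 truth checks the mean extra-parameter penalty 2 − E[χ²₁] ≈ 1.

## Known limitations

* No LD: real best-SNP assignments smear over LD blocks; annotation
  odds ratios on real data are attenuated relative to the causal-variant
  enrichment. The optional copy-process LD is off by default.
* Poisson counts without overdispersion understate RNA-seq noise.
* The elastic-net LOO holds design standardization fixed across folds.
* The hierarchical model uses best-SNP assignments, not SNP-level Bayes
  factors; with strong LD the two can differ materially.
* Gene-level summaries of 1–2-exon genes genuinely absorb exon-specific
  effects; on count data this leaves a small residual last-exon
  enrichment at the gene level, which is a property of the biology-plus-
  summarization, not a bug.
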