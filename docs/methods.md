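# Methods

This note documents the models behind `immunosig`, the choices made where
the design was genuinely open, and what the synthetic studies do and do not
demonstrate.

## Permutation classifier

Each tumor sample is reduced to one statistic: the Pearson correlation
between its (per-dataset standardized) expression over the measured
signature genes and a fixed reference vector. The null distribution is
generated per sample by drawing B random gene subsets of the same size from
that sample's full transcriptome — without replacement within a draw,
independently across draws, signature genes not excluded from the pool —
and correlating each subset, in draw order, against the same reference
vector. The p-value is the add-one rank estimator
p = (1 + #{ρ_b ≥ ρ_obs})/(B + 1). Ties count toward the numerator
(conservative); p is therefore strictly positive and exactly uniform on the
grid {k/(B+1) : k = 1..B+1} under the null, which is what the calibration
study measures (fraction rich ≈ α at the α = 0.05 cut).

Choices that were open and how they were resolved:

* **Reference vector.** The per-gene mean of the signature profiles across
  cell types (`reference_mode="row_mean"`). The construction is isolated
  behind an enum so alternatives (single cell-type columns, weighted
  compositions) can be substituted without touching the test machinery.
* **Standardize first.** Expression is z-scored per gene within each
  dataset before classification; standardization is idempotent, so passing
  already-standardized data is harmless.
* **Degenerate samples.** A constant expression vector has no defined
  correlation; such samples get p = 1 / immune-poor with a warning, on the
  view that a flat transcriptome carries no immune signal.
* **Per-sample RNG streams.** Each sample's generator is seeded from
  (base seed, CRC-32 of the sample id), so cohort results do not depend on
  sample order and classifying a subset reproduces the full-cohort calls.
* **Defaults.** B = 1000 and α = 0.05, the conventional settings for this
  test; both are exposed everywhere (API, CLI, pipeline config).

## Synthetic studies

The generator emulates a three-cohort bulk breast-tumor study: two
continuous (array-like, log2-scale Normal noise) cohorts and one count
(RNA-seq-like, negative binomial with dispersion φ and sampled library
sizes) cohort, each with its own gene universe covering only a fraction of
the signature, so cross-platform signature intersection is exercised.

Latent structure per sample: receptor subtype (Luminal/HER2/TNBC, defaults
0.68/0.12/0.20), an immune-rich flag with subtype-dependent prevalence
(defaults 0.30/0.45/0.55 — Luminal tumors mostly immune-poor, TNBC most
often immune-rich), and nodal status independent of richness by default
(an optional log-odds knob introduces dependence for power studies). Small
fractions of subtype (3%) and nodal (2%) records are masked as `missing`.

Planted effects, all on the log2 scale:

* **Signature shift.** Immune-rich samples gain expression on the measured
  signature genes. The mean gain is `signature_effect` in within-gene-sd
  units (default 1.5), distributed across genes **proportionally to the
  per-gene mean reference profile**. A uniform shift would be invisible to
  a correlation statistic (corr(x + c, r) = corr(x, r)); biologically,
  infiltration adds immune RNA in proportion to how strongly immune cells
  express each gene, which is exactly the heterogeneity the classifier
  detects.
* **Signature profiles.** Synthetic profiles are marker-structured: a low
  Gamma(2, 0.25) baseline across the 22 cell types plus a Gamma(2, 10)
  boost at each gene's marker cell type. Real leukocyte signature genes are
  cell-type markers — high in one or two cell types, near-zero elsewhere —
  and this cross-gene spread of the reference vector is what gives the
  correlation test its power. Flat i.i.d. profiles (row-mean CV ≈ 0.15)
  demonstrably starve the classifier of signal.
* **Differential expression.** `de_gene_count` genes shifted by
  `de_effect` log2 units in rich samples of *all* cohorts (consensus
  positives), plus single-cohort shifted genes and sign-flipped genes
  (consensus-negative controls), plus subtype-restricted effects (default:
  a few TNBC up/down and Luminal down genes, echoing the structure of
  subtype-stratified findings in breast cohorts).

All randomness flows from one integer seed through `SeedSequence`; the same
config is bit-reproducible.

What the generator does **not** model: gene–gene correlation (beyond the
planted group structure), platform probe effects, batch effects,
copy-number/mutation signal, or missing expression values. Passing the
recovery tests therefore shows the pipeline's statistics behave as designed
under clean generative assumptions — not that real cohorts, with correlated
genes and technical structure, would yield the same operating
characteristics.

## Differential expression engine

One moderated-t engine serves all cohorts.

* **Model.** Per gene, a linear model on an intercept + group indicator
  (optionally + additive indicator covariates for subtype/nodal; samples
  with a `missing` category are dropped listwise). logFC is the group
  coefficient (a − b), in log2 units.
* **Shrinkage.** The prior (d0, s0²) is estimated by matching the mean and
  variance of log s²_g to the scaled-F model (digamma/trigamma equations);
  the trigamma inverse is solved by Newton iteration to 1e-8. When the
  spread of log-variances does not exceed sampling noise, d0 is infinite
  and s0² is the arithmetic mean of the variances; d0 above 1e6 is treated
  as infinite. Total df for the t reference is d0 + d_g, capped at the
  pooled residual df of all genes. The engine reproduces limma::eBayes on
  shared fixtures to ~1e-9 (see the R oracle tests), and its two limits
  (ordinary t as d0 → 0, common-variance t as d0 → ∞) are exercised
  numerically.
* **Degenerate genes.** Genes with zero variance in both groups, or with
  numerically zero residual variance, are dropped with a warning; a
  single-gene input falls back to d0 = ∞.
* **Counts bridge.** Count cohorts are normalized by TMM (reference column
  = upper-quartile closest to the mean; 30%/5% two-sided trims on M/A;
  precision-weighted mean of retained M; factors rescaled to multiply
  to 1 — matches edgeR::calcNormFactors to ~1e-14) and transformed to
  log2-CPM with a fixed prior count of 0.5:
  log2((c + 0.5)/(lib·f + 1)·1e6). This replaces a negative-binomial GLM
  for count data: the trade is one engine with identical
  moderation-and-BH semantics across platforms, at the cost of ignoring
  the NB mean–variance relation at low counts. Note the fixed prior makes
  log-CPM only asymptotically depth-invariant (the deviation at count 10
  is ~0.03 log2 units and shrinks as counts grow).
* **Multiple testing.** Benjamini–Hochberg step-up (statsmodels), applied
  within each cohort's full tested gene set before any cross-cohort
  intersection.

## Consensus and over-representation

Consensus requires: measured in every cohort (intersection universe — a
cohort cannot validate a gene it never measured), FDR below threshold in
every cohort, identical logFC sign everywhere. The output ordering
(descending minimum |logFC| across cohorts, then gene name) is a display
convention. A relaxed mode (`require_all_cohorts=False`) accepts
significance in ≥ 2 cohorts with sign agreement among the significant ones.

Over-representation uses the hypergeometric upper tail with the universe
defined as the genes tested in that cohort's DE table, one-sided
(over-representation only), BH across sets. Cross-cohort pathway consensus
intersects the per-cohort significant sets and reports Venn-style exact
overlap counts. The tail computation matches exhaustive enumeration over
all draws (N ≤ 25) to 1e-12.

## Association testing

Pearson chi-square without continuity correction (the target tables are
large-count); `missing` categories are excluded from the table but counted
in the result. The published cohort count tables bundled in
`published_counts` reproduce the expected verdicts: subtype association
p < 0.001 in all three cohorts, nodal association non-significant in all
three. For 2×2 tables, Fisher's exact test reaches the same verdicts at
these sample sizes (tested).

## Problem sizes and tolerances used in the test suite

The calibration study uses 2000 null samples × 5000 genes with a 500-gene
signature at B = 1000 (rich fraction within 0.05 ± 0.01); classifier
recovery uses one cohort of 200 samples × 4000 genes with the full 547-gene
signature at `signature_effect` 1.5 (sensitivity and specificity ≥ 0.9);
consensus recovery uses three cohorts of 120 samples × 3000 genes
(≥ 90% of planted all-cohort genes, 100% exclusion of controls); the
global-null DE check averages 20 seeds of 1000 genes × 40 samples
(≤ 5% of genes at FDR < 0.05). These sizes keep each property measurable
with comfortable statistical margin while the whole suite runs in a few
minutes on one CPU.

## Known limitations

* The classifier's reference-vector construction is a declared convention;
  the underlying published description of the test leaves it open.
* The counts pathway approximates an NB GLM by TMM + log-CPM + moderated t;
  at very low counts or extreme dispersion the NB route would differ.
* No meta-analytic pooling: consensus intersects verdicts, so one
  underpowered cohort vetoes a gene regardless of the others' evidence.
* Gene identifiers are case-sensitive symbols; no alias/probe mapping is
  attempted, and duplicate symbols are collapsed by a highest-mean-row
  rule that stands in for platform-specific probe collapsing.
* Missing values in expression matrices are rejected rather than imputed.
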