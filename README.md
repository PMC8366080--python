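# immunosig

Immune-rich / immune-poor phenotyping of bulk breast tumors from a leukocyte
gene-signature correlation test, with cross-cohort consensus differential
expression and pathway over-representation.

## The problem

Bulk tumor expression profiles mix tumor cells with infiltrating immune
cells. Given a leukocyte signature matrix (LM22-style: genes × immune cell
types), each tumor can be scored for overall immune content without
estimating individual cell-type fractions: correlate the tumor's expression
over the measured signature genes with a reference immune profile, and ask
whether that correlation exceeds what random gene sets of the same size
achieve. Tumors passing the test are *immune-rich*, the rest *immune-poor*.
The binary phenotype is then related to receptor subtype (Luminal / HER2 /
TNBC) and nodal status, and used as the grouping variable for gene-wise
differential expression, validated across independent cohorts.

The package is aimed at computational biologists who want a tested,
reproducible implementation of this multi-stage analysis, together with a
synthetic multi-cohort generator that provides ground truth for every stage.

## The statistics at the core

**Permutation classifier.** For sample *s* with standardized expression
*x*, signature genes *G* (|G| = m after intersecting with the cohort's
universe) and reference vector *r* (per-gene mean of the signature
profiles),

- observed statistic: ρ_obs = corr(x<sub>G</sub>, r) (Pearson);
- null: ρ_b = corr(x<sub>G_b</sub>, r) for B random m-gene subsets G_b
  drawn without replacement from the full transcriptome (B = 1000);
- p = (1 + #{ρ_b ≥ ρ_obs}) / (B + 1); *immune-rich* iff p < 0.05.

**Association.** Pearson chi-square (no continuity correction) on
label × subtype and label × nodal tables, missing categories excluded
listwise.

**Differential expression.** Per-gene two-group linear model; empirical-
Bayes moderation shrinks residual variances s²_g (df d_g) toward a prior
(d₀, s₀²) estimated by moment-matching on log s²_g, giving
s²_post = (d₀s₀² + d_g s²_g)/(d₀ + d_g) and a moderated t on d₀ + d_g df;
Benjamini–Hochberg FDR. Count cohorts enter through TMM scaling factors and
log₂-CPM, so all cohorts share one engine (verified against limma/edgeR in
the test suite).

**Consensus.** A gene validates when it is measured in every cohort,
FDR < 0.05 in every cohort, and its log₂ fold change has the same sign
everywhere. Signature and non-signature genes are reported separately.

**Over-representation.** For n up- (or down-) regulated genes in a
universe of N tested genes, overlap k with a K-gene set is scored by the
hypergeometric upper tail P(X ≥ k), BH-adjusted across sets, with gene
ratio k/K; pathways significant in every cohort form the pathway consensus.

## Worked example

```python
import immunosig as im

cfg = im.SimulationConfig(
    seed=7,
    cohorts=(
        im.CohortSpec("arrayA", 150, "continuous", 3000, 0.96),
        im.CohortSpec("arrayB", 150, "continuous", 3000, 0.94),
        im.CohortSpec("rnaseqC", 150, "counts", 3000, 0.98),
    ),
    n_signature_genes=300, de_gene_count=50,
    cohort_specific_de_count=6, sign_flip_de_count=6,
)
datasets, metadata, signature, truth = im.simulate_study(cfg)

tables = {}
for ds in datasets:
    expr = ds if ds.value_kind == "continuous" else im.log_cpm(ds, im.tmm_factors(ds))
    calls = im.classify_cohort(im.standardize(expr), signature,
                               im.ClassifierConfig(n_permutations=1000, alpha=0.05, seed=7))
    n_rich = (calls["label"] == "rich").sum()
    assoc = im.association_test(calls, metadata[ds.cohort_id], "subtype")
    print(f"{ds.cohort_id}: {n_rich}/{len(calls)} immune-rich; "
          f"subtype association chi2={assoc.chi2:.1f}, p={assoc.p_value:.2e}")
    contrast = im.build_contrast(calls, metadata[ds.cohort_id], "rich_vs_poor")
    _, tables[ds.cohort_id] = im.fit_ebayes(expr, contrast.group_a, contrast.group_b)

consensus = im.consensus_filter(tables)
planted = set(truth.genes_of_kind("consensus_de"))
print(f"consensus genes: {len(consensus)} "
      f"({len(set(consensus.index) & planted)}/{len(planted)} planted recovered)")
```

prints

```
arrayA: 55/150 immune-rich; subtype association chi2=10.9, p=4.23e-03
arrayB: 48/150 immune-rich; subtype association chi2=4.1, p=1.30e-01
rnaseqC: 57/150 immune-rich; subtype association chi2=14.0, p=9.14e-04
consensus genes: 307 (49/50 planted recovered)
```

About a third of samples are called immune-rich (the generator plants a
1.5-sd signature shift with subtype-dependent prevalence, so Luminal-heavy
cohorts lean immune-poor); the subtype association reaches p < 0.01 in two
of three cohorts at this modest n = 150. The consensus list recovers 49 of
the 50 effects planted in all cohorts while excluding every sign-flipped
and single-cohort control; most of the remaining consensus genes are
signature genes themselves, which is why the pipeline also reports the
signature / non-signature partition (`im.partition_by_signature`).

The same analysis is available from the shell:

```bash
immunosig simulate --outdir study --seed 7
immunosig classify --expression study/expression_arrayA.tsv \
    --signature study/signature.tsv --seed 7 --out calls_arrayA.tsv
immunosig run-all --config pipeline.yaml
```

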