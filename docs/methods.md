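# Methods

## Study model

The pipeline assumes a two-group observational design: one cohort
profiled with reduced representation bisulfite sequencing (per-CpG
methylated/unmethylated read counts, supplied as Bismark-dialect
coverage files) and RNA-seq (a gene-level read-count matrix), plus a
clinical covariate table. The groups are not taken from the metadata:
they are recovered from the expression data by unsupervised clustering,
and the two clusters at the extremes of a chosen clinical covariate
(an HbA1c-like glycemic marker by default; "group 1" = highest mean)
become the analysis groups. All stage thresholds default to the values
of the analysis the package re-implements and all inequalities are
strict: coverage > 10 reads, site present in ≥ 10 samples per group,
|Δmethylation| > 15 points, q < 0.01, DEG adjusted p < 0.01, enrichment
cutoff 0.05, kappa > 0.5 with ≥ 5 terms, interaction score > 0.9,
promoter window 5 kb, shore width 2 kb.

## Differential methylation

The methylation level of a site in a sample is #C/(#C + #T); a sample
with zero coverage at a site is treated as missing there. The group
difference is the difference of per-sample mean percentages (group 1 −
group 2), which is robust to coverage imbalance between samples; the
alternative pooled-read percentage would let one deep sample dominate.

The per-site test is a binomial logistic regression of (#C, #T) on the
group indicator, the convention of standard RRBS toolkits. With only an
intercept and one binary covariate, the maximum-likelihood group
probabilities are the pooled group proportions, so the likelihood-ratio
statistic has a closed form in the pooled 2×2 counts and is computed
vectorised (p from χ², 1 df); the test suite cross-checks it against an
iteratively fitted statsmodels GLM, and a pooled Fisher's exact option
is provided for small-count cross-checks. Multiple testing uses
Benjamini–Hochberg step-up, implemented directly (q_(i) =
min_{j≥i} p_(j)·m/j, capped at 1) and oracle-checked against
statsmodels. The binomial model ignores the between-sample
overdispersion that real bisulfite data carry; at the default generator
settings this leaves the test mildly anti-conservative (null fraction
of p < 0.05 around 0.06–0.08), which the strict 15-point effect-size
filter renders harmless for DMC calling — null sites essentially never
reach a 15-point empirical difference at n = 20/20.

A read-level "quality score > 20" filter belongs upstream of coverage
files (base/alignment quality during methylation extraction); it cannot
be applied to count data and is recorded in the filter config for
provenance only.

## Differential expression

Size factors are median-of-ratios (median over genes with a positive
geometric mean of count/geomean), re-implemented here because the
reference implementation's surrounding machinery is out of scope.
Sample clustering runs on log2(normalised count + 1) with
1 − Pearson-correlation distance and average linkage — the
distance/linkage are not dictated by the design and are exposed as
arguments. The DE test is a deliberately simplified per-gene
negative-binomial Wald test: group means on the normalised scale,
dispersion α by method of moments on the within-group residual variance
(α = max((s² − ȳ)/ȳ², 1e-8)), and a Wald statistic for the log fold
change with variance from var = μ + αμ² propagated through the
size factors. This replaces a shrunken-dispersion estimator on purpose:
the acceptance of this artifact is property-based (calibration and
power on synthetic data), not list-reproduction, and the simple
estimator is transparent and fast. A test cross-checks its fold
changes against pydeseq2 on a small matrix (log2FC correlation > 0.99).
A pseudo-count of 0.5 stabilises log fold changes of low-count genes.
Genes with zero counts in every sample are removed before testing.

Covariate association reports, per covariate, a two-sample pooled-
variance Student's t (Welch optional) for continuous covariates and
Fisher's exact test for binary ones, plus a joint logistic regression
of group membership on all covariates with per-covariate Wald p.
Because the synthetic covariate *defines* the groups by threshold, it
separates them perfectly and the joint logistic fit does not converge
there (perfect separation); the pipeline warns and reports NaN for the
joint model in that case, while the marginal tests remain valid.

## Annotation and integration

Internally all coordinates are 0-based half-open; GTF (1-based
inclusive), Bismark coverage positions (1-based) and BED (0-based) are
converted at the I/O boundary. One TSS per gene: the strand-appropriate
end of the (single-transcript) gene model; multi-isoform resolution is
out of scope. Each DMC maps to the gene minimizing |TSS − position| on
its chromosome, ties broken by lexicographically smallest gene id so
the assignment is order-independent. Feature classification has
precedence promoter > exon > intron > intergenic, with promoter defined
as ≤ 5 kb strictly upstream of the TSS and outside the gene body; a
downstream promoter window is deliberately not used. Shores are within
2 kb of an island boundary (community convention; configurable).
Gene-level DMG records take the union of their DMCs' directions, so a
gene can be both hyper- and hypomethylated; genes without a valid
official symbol are excluded from the overlap. Concordance is
classified per (gene, methylation-direction) pair — the only
granularity whose category counts are internally consistent when genes
carry both directions — so the four category counts sum to pairs, not
unique genes.

## Enrichment, kappa clustering, network

Enrichment is the upper-tail hypergeometric probability P(X ≥ k) for k
hits of a K-member term in an n-gene query within an N-gene universe.
The universe is a required, explicit choice: for DEG-style runs, all
genes tested for differential expression; for DMG-style runs, all
annotated genes in scope. Significance uses the BH-adjusted p for
DEG-style runs and the nominal p for DMG-style runs, both at 0.05.
Cohen's kappa between two terms is computed on their 2×2 membership
agreement over the query gene list; the degenerate case of identical
all-in/all-out memberships is defined as 1.0. Term clusters are the
connected components of the kappa > 0.5 graph with ≥ 5 members —
a deterministic, testable replacement for fuzzy-seeded clustering
heuristics whose exact seeding parameters are not specifiable. Note
kappa degenerates toward 0 when both terms contain nearly the whole
reference list (chance agreement approaches observed agreement), so
term families that blanket the query do not cluster; this is a property
of the statistic, not a bug.

The interaction network is built from a user-supplied STRING-export
style edge table (scores auto-detected as 0–1 or 0–1000), not a live
API, keeping runs self-contained and versioned. The DEG-induced
subgraph keeps edges with score strictly > 0.9, drops singletons
(idempotently), and orders connected components by size; components
with ≥ 3 nodes are "major" subnetworks and are re-enriched.

## Synthetic-data generator

The generator defines the study conditions for all recovery and
calibration tests. Defaults: two groups of 21 and 32 samples (the
re-implemented study's design), 200 genes and 2,000 CpGs on a two-
chromosome toy genome, mean coverage 30 with negative-binomial
dispersion 0.3, beta-binomial precision 150 (mild between-sample
overdispersion of methylation levels), 10% DM CpGs at ±30 points, 10%
DE genes at |log2FC| = 2 with NB dispersion 0.1, log-normal(0, 0.2)
size factors so normalisation is non-trivial, and an HbA1c-like
covariate with group means 8.7% and 7.8%.

The covariate drives group membership deterministically: values are
drawn from group normals truncated on either side of the midpoint
threshold (8.25%), with the truncated-normal locations solved so the
realised group means still equal the configured 8.7/7.8. A consequence
is that the within-group SDs are compressed below the nominal
`covariate_sd` (≈0.3–0.5 instead of 1.5) — a perfectly separating
covariate cannot also have heavily overlapping group distributions.
Real cohorts overlap; the synthetic design trades that realism for an
exactly defined cluster-recovery truth.

Other simplifications relative to real data: CpG positions are uniform
on the genome (no island/promoter density bias), there is no read-level
error model or bisulfite-conversion failure, gene counts have a single
dispersion parameter rather than a mean-dispersion trend, and gene-set
and interaction inputs are toy collections with planted structure
(term families sharing gene cores; high-confidence communities among
planted DE genes). Passing tests therefore demonstrate correctness of
the statistical machinery under the assumed model, not performance on
real cohort data — in particular, cluster recovery and DMC/DEG recovery
rates on real data will be lower than the near-perfect values seen
here, because the planted effects are large and clean by design.

## Problem sizes and determinism

The test suite and the acceptance script use 2,000 sites/genes with
20 samples per group for calibration and recovery runs, and an
~50-sample demo for end-to-end checks; these sizes give stable
Monte-Carlo estimates (binomial SE on a 0.05 rate at 2,000 draws is
≈0.005) while keeping full runs in seconds. All randomness flows from a
single master seed through `numpy.random.SeedSequence` spawning, so
identical configs produce byte-identical output files; every file
writer emits rows in a deterministic order to keep hashes stable.

## Known limitations

* The binomial LRT does not model methylation overdispersion (no
  beta-binomial likelihood); its nominal error control relies on the
  effect-size filter.
* Single-transcript gene models; no isoform-aware TSS choice.
* The joint logistic covariate model fails (with a warning) under
  perfect separation.
* No batch/surrogate-variable correction, no region-level (tiling)
  methylation analysis, no CHH/CHG contexts.
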