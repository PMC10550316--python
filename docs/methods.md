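# Methods

This note documents the statistical procedures implemented in `somarna`,
the design of the synthetic-data generator, the numerical choices made
where the design was genuinely open, and known limitations.

## Candidate selection and the filter cascade

A site enters the candidate set when exactly two bases are observed, one
of them the reference, raw coverage is at least 40 reads, and the minor
allele is supported by at least 6 reads with base quality Phred ≥ 30.
Sites with three or more observed alleles are dropped and logged. The
binomial filters then consume the quality-passing allele counts:

- **Sequencing error**: a candidate is flagged when the inclusive upper
  binomial tail P(X ≥ k | n = coverage, p = 0.001) is at least 1e-4 —
  the alternate count is too probable under pure sequencing error at the
  Phred-30 error rate.
- **VAF**: flagged when the lower tail P(K ≤ k | n = ref+alt, p = 0.5)
  exceeds 0.05 — the counts cannot exclude a true variant-allele
  frequency of one half or more, the signature of a missed germline
  heterozygote. In RNA-seq, allele-specific expression distorts the
  observed VAF in both directions; this filter is deliberately
  conservative about high-VAF candidates only.

Five per-read bias tests compare alternate-supporting against
reference-supporting reads with a two-sided Mann–Whitney test at level
0.05: read position, mapping quality, base quality, strand (encoded
0/1), and variant distance. The asymptotic normal form with tie and
continuity correction is used, switching to exact enumeration for
tie-free groups of at most eight reads; completely tied inputs carry no
evidence and return p = 1. For the variant-distance test, each read's
value is its mean absolute distance to all *other* reads at the site
(pooled over both groups). Pooling is essential: if distances are
computed within each group, the per-read values become mutually
dependent and the rank test's type-I error rises to roughly 40%
(measured), while pooled values are exchangeable between groups under
the null, restoring the nominal level.

Distance conventions are literal: splice-edge candidates are flagged at
distance strictly less than 7 bases from a terminal exonic base (both
boundaries of every UTR/exon interval count as exon ends); homopolymer
candidates are flagged at base distance up to and including 20 from a
maximal run of at least 7 identical bases (distance 0 inside the run).

The recurrence and outlier filters are order-dependent and consume only
candidates surviving everything upstream. A locus mutated in two or more
surviving accessions is flagged recurrent; a locus reaching
ceil(0.04 × accessions) surviving accessions is flagged by the 4% rule.
The ceiling is floored at two accessions — for cohorts of ≤ 25
accessions the raw ceiling would equal one and flag every locus, and a
repetition filter is by definition a property of at least two samples.
Outlier accessions are found by partitioning accessions into four
equal-width bins of total depth and flagging, within each bin, mutation
counts outside [Q25 − 1.5·IQR, Q75 + 1.5·IQR] (linearly interpolated
quartiles, the numpy default); an accession alone in its bin is flagged.
Equal-width depth bins (not equal-count quartiles) implement the
"evenly spaced groups" reading. Finally, candidates outside unambiguous
UTR/exonic intervals — intervals overlapping no other gene's intervals —
are flagged, because a read from an overlap cannot be attributed to one
gene.

## Genewise features and offsets

All genewise aggregation runs over the gene's unambiguous UTR/exonic
intervals, the same support on which mutations are callable, and l_g is
their summed length (using the full annotated span would mix supports
between numerator and denominator). Effective gene length b is base- and
strand-aware: for mutation type with pyrimidine P and strand class s,
b counts positions whose reference base *read on the strand implied by
(gene strand, s)* equals P and which pass the site-level coverage filter
in at least one accession; the normalized depth d\* divides the summed
passing depth (across accessions) by b, so d\*·b recovers the total
depth exactly. Replication timing is
log2( Σ_r (L_r/E_r)·o_{r,g} / l_g ) over bedGraph regions r with overlap
o_{r,g}; chromatin marks are Σ_{f,r} s_{f,r}·o_{f,r,g} / l_g summed over
replicate files f (two identical replicates double the value, by
construction). Genes without track coverage are excluded from the
affected model rather than zero-filled — zero is a meaningful signal
value. Covariates are standardized to zero mean and unit variance per
mutation-type table, after row exclusions.

## The mutation-rate model

Counts per (gene, strand class) row are Poisson with offset log b and
linear predictor alpha + kappa·log d\* + gamma·1[template] + X·beta.
kappa, gamma and beta are L1-penalized; alpha is not. log d\* and the
strand indicator are left unstandardized so gamma stays interpretable as
a strand contrast. The solver is penalized IRLS with cyclic
coordinate-descent soft-threshold updates, iterating on the active set
between full sweeps, warm-started along a 100-point log-spaced penalty
path from lambda_max (the smallest penalty zeroing every penalized
coefficient, from the KKT conditions at the intercept-only fit).
Numerical choices:

- Penalized columns are centered before fitting (the intercept absorbs
  the shift and is recovered exactly afterwards); without centering the
  near-collinearity of the intercept with high-mean, low-variance
  columns such as log d\* stalls coordinate descent.
- The working response increment (y − mu)/mu is clipped at ±1e4 and the
  linear predictor at ±30 to keep near-zero fitted means from
  destabilizing updates.
- The path floor is lambda_max·1e-4, raised to lambda_max·1e-2 when
  rows < 5 × features (the glmnet `lambda.min.ratio` convention): on
  near-saturated tables the deep end of the path is a degenerate overfit
  region that cross-validation can never select.
- The path stops early once the training deviance saturates (below
  0.1% of the null deviance), plateaus for three consecutive grid
  points, or the active set reaches 90% of the row count; later grid
  points inherit the last solution.
- Convergence tolerance is 1e-6 on the maximum coefficient update —
  two orders below any effect size of interest here; against an
  unpenalized IRLS fit the lambda→0 solution agrees to ~1e-6.

The penalty minimizing the mean held-out Poisson deviance over 10
seeded folds is selected (no one-standard-error rule), and the model is
refit on all rows at that penalty.

Partial correlations condition y = m/b and each covariate on
z = log d\* via the first-order formula
r = (r_xy − r_xz·r_yz)/√((1−r_xz²)(1−r_yz²)), t = r·√(n−3)/√(1−r²);
covariates collinear with z return 0 with a warning. The locus
recurrence model is an ordinary Poisson GLM (statsmodels) of the
cross-accession mutation count with offset log c_l on log(d_l/c_l).
Alternate-allele entropy uses the natural logarithm (so the uniform
three-allele value is ln 3 ≈ 1.10) with 0·log 0 = 0. Signature
extraction is a deterministic stand-in for Bayesian multinomial
decomposition: multiplicative-update NMF under the Kullback–Leibler
objective (scikit-learn, seeded random initialization), signatures
renormalized to probability vectors; comparison against an external
reference signature table is supported but none is bundled.

## The synthetic-data generator

The generator emits pileup-level site observations, not reads: every
filter in the cascade consumes pileup-level quantities, and alignment is
upstream of the package's scope. One master seed feeds independent,
purpose-labeled random streams (genome, tracks, masks, pileup, truth),
so regenerating one output leaves the others untouched.

Genomes default to 20 genes on 2 chromosomes with UTR–exon–UTR block
structure, 42% GC (the transcriptome-typical value for the target
organism), planted homopolymer runs, and at least one overlapping gene
pair so ambiguous intervals exist. Track signals are drawn from a
multivariate Gaussian across 18 latent dimensions with a configurable
correlation matrix (default: identity except a +0.6 between H3K4me1 and
H3K36me3, a correlation seen in real chromatin); chromatin tracks are
clipped to [0, 1], replication timing is parameterized by the latent
log2 late/early ratio.

Coverage is negative binomial (mean 60, dispersion 8) with lognormal
per-accession and per-gene multipliers; background errors occur per read
at 0.001 (the Phred-30 rate). Planted truths are placed at "plantable"
positions — unambiguous exonic sites away from interval boundaries,
homopolymer runs and masks — at coverage conditioned to at least 45
reads with alternate counts conditioned to at least 6, i.e. at sites
where the mutation is detectable in principle; recovery rates therefore
measure the stochastic filters, not placement luck. True somatic
mutations are private to one accession at VAF 0.25. The default load of
10 true mutations per accession matches the per-accession mutation count
realized in large multi-accession studies (~12); much sparser loads make
the per-accession counts so discrete that the groupwise IQR rule flags
ordinary accessions off collapsed quartiles. Artifact classes: germline
leaks recur in ≥ 2 accessions at binomial VAF 0.5; annotated germline
variants additionally appear in the emitted VCF across half the
accessions; splice-edge and polynucleotide errors sit at the positions
their filters target; high-VAF variants are planted at VAF 0.9;
read-bias variants draw alternate read positions from [0, 15) and
mapping quality 40 (reference reads: positions uniform on [0, 95),
mapping quality constant 60, base quality a rounded Normal(36, 2)
truncated to [2, 41], strand fair-coin — the per-read attribute
distributions are stated modeling choices, not inferences from data);
outlier accessions receive a 10× private mutation load.

What the generator does *not* emulate: realistic sequence-context
mutation spectra (planted alternates are uniform over non-reference
bases, so extracted signatures reflect trinucleotide availability, not
biology), read-level alignment artifacts, allele-specific expression,
population structure among accessions, and correlation between
expression level and chromatin state. Passing tests therefore show the
pipeline's filters and estimators behave correctly on data obeying the
stated generative assumptions — not that those assumptions hold in any
real cohort.

## Problem sizes

The test suite exercises the full pipeline at 20 genes × 50 accessions
(about 420k pileup rows per cohort) over 10 seeded replicates, model
recovery at 2,000 rows × 21 predictors over 20 replicates, and the
recurrence model at 10,000 loci — sizes at which every Monte-Carlo
tolerance stated in the tests is comfortably resolved on one CPU.

## Known limitations

- With five rank-based bias tests each at level 0.05, a perfectly clean
  candidate passes all five with probability ≈ 0.81 (three of the tests
  act on effectively continuous attributes, so their levels sit near
  nominal and the tests are nearly independent; measured jointly).
  End-to-end retention of planted true mutations is therefore ≈ 0.78,
  an irreducible cost of the published thresholds rather than an
  implementation artifact; raising retention would require lowering the
  per-test level below its published 0.05.
- The outlier IQR rule is scale-sensitive: with few accessions or few
  mutations per accession the within-bin quartiles are degenerate and
  the rule over-flags; this is faithful to the procedure, not mitigated.
- Germline matching is by position only (any alternate allele), so a
  somatic mutation at an annotated germline position is always lost.
- SNVs only; indels are out of scope throughout.
- The recurrence model conditions on loci with nonzero depth; it does
  not model zero-inflation from mappability.
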