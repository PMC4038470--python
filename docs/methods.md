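# Methods

This note records the statistical models behind `cnvfam`, the defaults and
why they were chosen, what the synthetic-cohort generator does and does not
emulate, and the numerical conventions that make results reproducible.

## Data model

Intensities are two-channel aCGH measurements: a test channel R per sample
and a common reference channel G hybridized from a fixed pool of male
genomic DNA. Internally matrices are samples x probes; genomic coordinates
are 0-based half-open (BED) throughout; pedigree sex coding on disk is
PED-style (1 = M, 2 = F, 0 = unknown). Missing ages are empty fields/NaN,
never 0 (age 0 is a legal simulated offspring age at the boundary). A
"transmission" is one affected offspring with both parents present — it
carries two parental meioses. Families lacking a parent are excluded from
family tests rather than imputed, and families mixing DNA sources
(blood/cell line) are excluded from association because within-family
technical homogeneity is the design's central assumption.

## Normalization

Six schemes combine the log channel ratio with quantile normalization:
log(R/G), log(QNorm(R)/QNorm(G)), QNorm(log(R/G)),
QNorm(log(QNorm(R)/QNorm(G))), log(R/G + 0.5), log(QNorm(R)/QNorm(G) + 0.5).
Two conventions had to be fixed:

- **Log base 2.** The aCGH convention; association P-values are invariant
  to the base, only reported scales change.
- **QNorm axis: across samples.** Each sample's value vector is mapped to
  the cohort-mean order-statistic vector by within-sample rank (ties
  receive the mean of the tied targets; samples with missing entries are
  aligned on a common quantile grid by linear interpolation). This equalizes
  array-to-array distributional differences, which is what array-level
  quantile normalization exists to do. Per-probe normalization would
  instead erase the copy-number signal itself.

Entries undefined under a scheme become NaN and propagate as missing:
schemes 1–4 mask entries where either raw channel is zero (masking is
decided on the raw channels — quantile normalization would silently remap
true zeros onto positive reference values); schemes 5–6 are defined at
ratio zero by the 0.5 pseudo-count and mask only zero denominators.

## Summarization and pipeline selection

Probes of one CNV are collapsed by PCA of the mean-centered, *unscaled*
probe block (unit-variance scaling would up-weight noisy probes).
Covariance uses pairwise-complete entries; probes with more than 20%
missing are dropped; missing entries are mean-imputed only for scoring.
Sign conventions: PC1 is oriented to correlate nonnegatively with the
across-probe mean signal; higher components get their largest-magnitude
loading made positive. The orientation is arbitrary for testing (the
family test's P-value is sign-invariant) but required for reproducible
output.

The family design supplies an internal data-quality criterion:
**heritability**, the Pearson correlation between affected-offspring and
mid-parental summary scores across complete trios (the same trios the
association test uses). Heritability probe scaling (HPS) computes this
correlation per probe, clips negatives to zero (a "proportional" weight
cannot be negative; an anti-heritable probe is noise), rescales probe
columns, and repeats PCA; if every weight clips to zero the unweighted PCA
is used with a logged warning. Pipeline selection evaluates all 12
candidates (6 normalizations x {PCA, HPS-PCA}), computes heritability of
each PC1, and keeps the maximum; exact ties break to the lowest (scheme
index, summary method) pair so selection is deterministic.

## Genotype calling

Per-locus summary scores are clustered with a univariate Gaussian mixture
fitted by EM. Restart 0 seeds component means at evenly spaced data
quantiles, further restarts at jittered quantiles (10 restarts by
default); the EM log-likelihood is asserted non-decreasing at every
iteration; components whose SD collapses below 1e-6 of the data SD are
pruned and the fit continues. The number of classes K is chosen by minimum
BIC over K = 1..6 — the standard, testable surrogate for mixture model
selection. Components are reported sorted by ascending mean, so class
indices are ordinal in intensity; mapping to integer copy number, when
needed, goes through the locus type (deletion: 0/1/2-like, duplication:
2/3/4-like). Hard calls require a posterior above 0.95; a locus is
"clusterable" when K >= 2 and at least 95% of samples are confidently
assigned. Unclusterable loci remain fully testable by the intensity-based
family test — that is the point of the workflow.

## Association tests

FBAT-CNV: per affected offspring, d = y_offspring − midparent; family sums
D_f; T = ΣD_f, V = ΣD_f², Z = T/√V, two-sided normal P. The empirical
family-clustered variance is used because it is assumption-light: under
the no-association null the deviations have mean zero whatever the
intensity-to-copy-number calibration, family structure, or shared batch
effects. Fewer than 2 usable families yields no result; below 10 families
a warning marks the normal approximation unreliable. The test is invariant
to per-family score shifts and global affine rescaling (verified by
property tests).

FBAT-X compares affected daughters with their mothers only (hemizygous
sons against a one-X-copy male reference are not comparable to a
mid-parent), with the same family-clustered statistic.

The linear TDT on discrete dosage calls uses the Mendelian null variance
(1/4 per heterozygous parent per offspring). Conditional FBAT removes
every family in which either parent is heterozygous at the conditioning
SNP and reruns FBAT-CNV on the remainder: any association driven by
alleles tagged by that SNP disappears by construction, so residual signal
indicates a secondary effect. Per-component tests for multi-PC (VNTR)
summaries are marginal, one FBAT per component — matching the way
per-component results are usually quoted; no joint test is provided.

Genome-wide calibration uses q = −2 ln p, which is chi-square with 2
degrees of freedom under the null. The over-dispersion slope regresses
sorted q through the origin on the chi-square(2) order-statistic medians
(exact beta-median plotting positions), after excluding the top 1% as
potential true signals; 1.0 means calibrated. Multiple testing uses a
Bonferroni threshold alpha/m only — no FDR machinery, matching the
scan-style use case.

## Sample QC

- **DLRS**: robust SD (IQR/1.349) of consecutive-probe log-ratio
  differences divided by √2, estimating per-probe noise. Array-vendor
  Excellent/Good/Poor cut-points are proprietary; the DLRS threshold is
  exposed as configuration (default: flag > 0.30). On a targeted array
  whose probes all sit in CNV regions, consecutive probes of *different*
  regions differ by genuine copy-number signal; a within-locus mode pools
  first differences only within each region and is what the CLI uses.
- **Swap scan**: squared Pearson correlation across clusterable-CNV scores
  for all sample pairs; flag at r² >= 0.7 (the squared-correlation form of
  the cutoff — the stricter reading — with the exponent configurable),
  with a whitelist for expected duplicates.
- **Parentage**: per pair, log-likelihood of the child's calls under true
  parentage (Mendelian transmission from both stated parents) versus
  non-parentage (tested parent's transmitted allele drawn from founder
  population frequencies), over biallelic clusterable loci with MAF > 0.3.
  A genotyping-error mixture (ε = 0.01, configurable) is applied to the
  child's observed genotype — correct with probability 1 − ε, else uniform
  over the other classes — so a single Mendelian impossibility cannot veto
  a true relationship; parents are taken at face value (mixing error into
  all three genotypes changes BFs negligibly at this ε but triples the
  state space). Bayes factor > 100 flags the pair.
- **Heterozygosity**: per-sample heterozygote fraction among called
  autosomal clusterable loci, z-scored against the cohort; flagged iff
  (z < −5 and call rate < 98%) or (z > 2 and call rate < 92%) — both
  branches conjunctive, exactly as stated.
- **Sex inference**: mean log2 ratio over chromosome-X CNV-free control
  regions against the male (one-X) reference pool puts males near 0 and
  females near +1. A two-means split classifies; if the centers are closer
  than 0.5 (single-sex cohort) a fixed 0.5 threshold is the fallback.
- **Tracking**: concordance of mapped CNV classes with external tag-SNP
  genotypes at well-tagged loci; below 80% flags; a cross-plate
  concordance matrix (samples matched by well position) recovers full
  plate swaps as symmetric off-diagonal maxima.
- **Plate effects**: Kruskal–Wallis tests of per-sample median raw test
  channel intensity across plate rows and across columns.
- **Report**: Table-style retention accounting. Each step's row applies
  that step alone to the pre-QC cohort; the final row applies the
  intersection. A transmission is retained iff offspring and both parents
  pass; percentages are rounded to 2 decimals.

## Artifact scanning

Somatically rearranging loci (T-cell receptor, immunoglobulin heavy chain)
can masquerade as associated: blood cell-type composition drifts with age,
offspring are younger than their parents, so offspring-vs-midparent
deviations acquire a systematic shift with no transmission distortion. The
scan computes, per locus, the Pearson correlation between age at sampling
and summary score within blood-derived samples (and again within offspring
only, ruling out a generation confound), fits a natural cubic spline with
4 interior knots at within-source age quintiles per DNA source for
reporting, and Bonferroni-flags across scanned loci. The blood-vs-cell-line
mean difference is reported with a Welch test; it is diagnostic only,
since DNA source is constant within families. Flagging is advisory —
artifact loci are annotated, not auto-removed.

## TDT power

Under a multiplicative per-allele odds ratio ψ, a heterozygous parent
transmits the risk allele to an affected offspring with probability
τ = ψ/(1+ψ). With n affected offspring each contributing two parental
meioses, the expected informative meioses are m = 2·n·h, with
h = P(parent heterozygous | offspring affected) computed exactly by
enumerating the nine Hardy–Weinberg parental mating types weighted by
offspring affection probability ψ^(risk-allele count) (rare-disease
scaling cancels). Power is the two-sided normal tail beyond z_{1−α/2}
under noncentral mean √m·(2τ−1). "Transmissions" counts affected
offspring (each bringing two meioses): this reading reproduces the 80%
worked example (the package computes 84.2% at n = 3,610, p = 0.40,
ψ = 1.22, α = 10⁻⁶), whereas counting single meioses does not. The
Monte-Carlo cross-check is deliberately mechanistic — Hardy–Weinberg
parents, Mendelian transmission, rejection-sampling ascertainment, the
discrete TDT statistic per replicate — sharing no formula with the
analytic path. `detectable_or` inverts the analytic power by root finding.
Power is symmetric under relabeling the risk allele, (p, ψ) ↔ (1−p, 1/ψ).

## Synthetic cohorts

The generator's defaults encode the emulated study design: 2,160 nuclear
families — 76.9% with two affected offspring and 23.1% with one (the
1,661/499 split), 15.5% of families on cell-line DNA, one DNA source per
family, 96-well plates filled family-by-family, parent sampling ages
N(40, 6²) clipped to 22–75 and offspring N(12, 5²) clipped to 1–35, and a
male reference pool (autosomal reference copy 2, chromosome X copy 1).
Founders are Hardy–Weinberg; offspring are Mendelian; ascertainment on all
offspring affected is whole-family rejection sampling with acceptance
ψ^(risk count)/ψ²_max per offspring — exact under the multiplicative
model, and factorizing across independent loci, so each locus is rejected
independently. The rejection loop errors out rather than spinning when
acceptance collapses (extreme ψ with a vanishing risk allele).

Intensities: R = 1000 · a_s · max(β_p·dosage + ε, 0.01) · 2^δ, G = 1000 ·
a_s · ref_copy · lognormal(0, 0.05), with a_s a shared lognormal(0, 0.1)
array effect (cancelling in ratio schemes — the reason schemes differ),
β_p per-probe slopes, ε ~ N(0, σ_p), and δ the age/source artifact shift.
Artifacts (built-in or injected) act multiplicatively as 2^δ on the test
channel, i.e. exactly δ on the log2-ratio scale — the scale on which
age-trend artifacts present in real data — rather than additively inside
the signal bracket. Clusterability is controlled by β_p/σ_p; VNTRs are
allele-length classes whose summed length drives the signal, producing
multimodal but potentially unclusterable distributions. Loci can emit a
perfectly linked biallelic tag SNP (risk-allele count) for conditional and
tracking analyses.

Not emulated: genomic waves and GC dependence of log-ratios, probe
cross-hybridization, linkage disequilibrium between loci, population
structure/HWE departures in founders (a known inflater of the family test
at non-linear loci), non-linear intensity response, cell-line artifacts
beyond a mean shift, and genotyping-error processes other than the
independent-error model. Passing tests therefore demonstrate correctness
of the statistical machinery under the stated generative model, not
robustness to every failure mode of real arrays.

## Problem sizes in the validation suite

The test suite validates the cohort-dependent claims at reduced but
adequately powered scales, chosen once: null calibration on 1,000 null
loci x 250 quad families (500 transmissions); FBAT-vs-TDT rank agreement
on 50 clusterable loci x 150 families; VNTR recovery and conditioning on
250 families with 12 conditional replicates; the age-artifact diagnostic
on 250 families; parentage at 318 loci x 150 true and 150 substituted
trios; HPS-vs-PCA across 100 replicates of 80 trios; the power worked
example at full scale (3,610 offspring, 10,000 Monte-Carlo replicates).

## Known limitations

- Single-parent families are excluded, not imputed; the offspring-minus-
  midparent deviation has no stated single-parent analogue.
- The FBAT-CNV variance is the empirical family-clustered form; with very
  few families the normal approximation is poor (warned below 10).
- The non-parentage likelihood replaces only the tested parent's
  transmitted allele with a population draw; other mis-relationship models
  (sibling-as-parent) are not distinguished.
- BIC-based K selection can merge heavily overlapping components; such
  loci are simply (and correctly) reported unclusterable.
- The over-dispersion slope assumes the P-values come from a two-sided
  normal statistic; it is not meaningful for discrete-statistic tests at
  tiny sample sizes.
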