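# Methods

This note documents the models and procedures implemented in methworks,
the defaults and why they were chosen, what the synthetic cohorts do and
do not emulate, and the numerical choices that affect results.

## Data model and coordinate conventions

A dataset holds per-CpG beta values (methylation level in [0, 1]) and
read coverage for a sample cohort. Internally every site is a 1-based
cytosine position on the + strand ('*' marks unknown strand and is
treated as '+' when merging across platforms); bedGraph export and all
BED/region handling use 0-based half-open intervals, the native dialect
of each format. Bismark coverage files are read as 1-based with
start == end. Beta is always recomputed as methylated/(methylated +
unmethylated); the file's percentage column is only checked for
consistency (a disagreement beyond 0.5 percentage points warns, and the
counts win) because counts are the primary data and percentages are
rounded downstream artifacts. A zero-coverage cell has no defensible
methylation estimate, so its beta is missing by construction and the
container enforces this invariant. An optional `merge_strands` flag
collapses a −strand record at p+1 onto the + strand CpG at p by summing
counts; it is off by default since most callers emit merged calls
already.

Cross-platform merging keys sites by (chrom, pos, strand) — never by row
order — and copies betas unchanged from their source, recording each
sample's source platform; intersect mode mirrors the common
"CpGs covered by all platforms" meta-analysis design.

## Filtering and imputation

The sequencing QC rule "at least k reads in more than f of the samples"
uses a non-strict depth comparison (>= k, "at least") and a strict
fraction comparison (> f, "more than"); the wording is followed exactly
because at typical cohort sizes the boundary case (exactly half the
samples) genuinely changes the retained set. Annotation-based rules (sex
chromosomes, SNP-overlapping sites) run before the coverage rule, and
the filter report accounts for every removal in order. Array-derived
datasets have no coverage matrix; the coverage rule is then skipped with
a logged notice rather than an error, so one configuration can serve
mixed-platform studies.

Missing betas can be imputed by sample-wise or CpG-wise means/medians,
by random draws from the same CpG's observed values (explicit seed
required; there is no hidden global randomness), or by k-nearest
neighbours over **site rows**: distances are Euclidean over
pairwise-complete columns scaled by 1/sqrt(shared-column count), and a
missing cell takes the unweighted mean of the k nearest rows observed in
that column, skipping donor rows that are missing there. Rows are the
natural unit because methylation is far more similar across neighbouring
CpGs within a sample set than across samples within a CpG; the 1/sqrt(m)
scaling makes distances comparable between pairs with different overlap.
Ties in distance are broken by row order (stable sort), which makes
imputation deterministic. After imputation the coverage matrix is
dropped: an imputed beta at a zero-coverage cell would otherwise violate
the container invariant, and post-imputation analyses operate on betas
only.

## Region aggregation

A CpG at position p belongs to region [s, e) iff s <= p−1 < e (point
membership; strand ignored). Overlapping regions are scored
independently — a CpG may contribute to several. `mean` averages
observed member betas per sample; `coverage_weighted` weights by
per-cell read depth, which down-weights unreliable calls in sequencing
data; the two coincide exactly under equal coverage. `n_cpgs` counts
member sites regardless of missingness, and regions with fewer than
`min_cpgs` members are reported all-missing. Default `min_cpgs` is 3 for
sequencing platforms (1–2-CpG regions are unstable under RRBS coverage
fluctuations) and 1 for arrays, where probe placement already implies
curation.

## Covariate inference

**Age.** Elastic net of chronological age on single-CpG betas
(`l1_ratio` = 0.5 by default), with the penalty chosen by K-fold
cross-validated MSE over a log-spaced grid (1e-4..1 by default). Fold
assignment hashes each sample_id, so the selected penalty and
coefficients are invariant under sample reordering. The model stores
only nonzero coefficients plus each model CpG's training mean; at
prediction time, CpGs absent from the dataset (or missing in a sample)
are substituted by their training mean and the substitution count is
reported — the prediction degrades gracefully toward the training-set
mean prediction as overlap shrinks, and an overlap below 50% (default)
is refused.

**Sex.** Features are fX = log2((mean chrX signal + ε)/(mean autosomal
signal + ε)) and fY likewise for chrY, with ε = 0.01 as a pseudo-count
guarding empty chromosomes; the signal is read coverage for sequencing
data and a caller-supplied intensity matrix for arrays. Males show
fX ≈ −1 (one X) and clear Y signal; females fX ≈ 0 and fY strongly
negative. Because both features are ratios, a global coverage rescale
cancels. A logistic regression on (fX, fY) yields class probabilities;
predictions below a confidence threshold (default 0.8) are reported
"unknown" rather than guessed.

**Genetic noise.** Mean over autosomal genotyping-probe CpGs of
min(|b|, |b−0.5|, |b−1|): the distance of each probe's beta from the
nearest diploid genotype. The score lies in [0, 0.25], is 0 for an ideal
diploid sample, and is invariant under b → 1−b by symmetry of the target
set. Elevated values indicate cross-individual contamination or
aneuploidy.

**LUMP purity.** purity = min(1, mean beta over present LUMP CpGs /
scale) with scale = 0.85, the convention of the published algorithm,
exposed as a parameter; immune_fraction = 1 − purity exactly. The CpG
list is user-supplied (one site_id per line); no list ships with the
package.

**Deconvolution.** Per sample, minimise ||b − R·w||² over the CpGs
shared with the reference, subject to w ≥ 0 and Σw ≤ 1 (or = 1). The
quadratic program is solved by SLSQP on the precomputed normal equations
with ftol 1e-14, which recovers simplex-interior truth to ~1e-9 in the
noiseless case. Identical reference columns make weights unidentifiable
and are rejected by name.

## Differential methylation and variability

The moderated two-sample t shrinks per-unit pooled variances toward a
prior: s²_post = (d₀·s²₀ + d_g·s²_g)/(d₀ + d_g), with (d₀, s²₀) fitted
by moment-matching a scaled-F model on log variances — e_g = log s²_g −
digamma(d_g/2) + log(d_g/2) has variance trigamma(d_g/2) +
trigamma(d₀/2), and the excess of the empirical variance of e over
trigamma(d_g/2) determines d₀ through a Newton inversion of the
trigamma function; non-positive excess means no detectable between-unit
dispersion and d₀ = ∞ (all units share s²₀). The statistic uses
d₀ + d_g degrees of freedom. With the prior off (d₀ = 0) the statistic
equals the classical pooled Student t exactly; the test suite also
verifies numerical agreement with limma (rtol 1e-6) on a shared matrix.

diffVar transforms observations to absolute deviations from their group
median and applies the same machinery; its statistic's sign follows
group1 − group0 mean deviation, consistent with `diff = mean1 − mean0`
everywhere in the tables. On bounded beta-distributed data this
median-based test runs slightly conservative (empirical false-positive
rate ≈ 0.042 at p < 0.05 with n = 20 per group), a known property of
deviation-based variability tests. iEVORA computes the closed-form
two-group Bartlett statistic, BH-adjusts to q-values, and selects units
with q < 0.001 whose plain t-test p is below 0.05 (defaults from the
cited algorithm, both configurable), ordering selections by the t-test
p-value; the t filter intentionally discards pure variance changes with
no accompanying mean shift.

Both differential methylation and differential variability tables share
one worst-rank code path: each criterion is ranked 1-based with ties
sharing the minimal rank — smaller adjusted p better, larger |effect|
and |log-quotient| better (criteria: mean difference and log2 mean
quotient for methylation; variance difference and log2 variance ratio
for variability, each with a 0.01 pseudo-count inside the quotient) —
and the combined rank is the maximum of the three. Output is ordered by
combined rank, ties broken by adjusted p, then input order. Units with
missing criteria rank last and are counted. The automatic rank cutoff is
the number of units with BH-adjusted p below the FDR level (0.05
default); the selected set is that many best units by combined rank.
This cutoff rule is a documented design choice — it ties the selection
size to a quantity with a direct error-rate interpretation. BH
adjustment itself is the step-up min-over-suffix form, monotone and
capped at 1. (It is *not* idempotent — re-adjusting adjusted p-values
changes them whenever first-pass ties re-rank — so no such property is
claimed or tested.)

Units containing missing values are dropped from testing by default
(with counts reported) rather than imputed silently; imputation is an
explicit upstream step.

## Exploration and enrichment

PCA centres each unit and decomposes the sample x unit matrix by SVD;
components are ordered by explained variance and signed so that the
largest-magnitude unit loading is positive (a deterministic convention —
SVD signs are otherwise arbitrary). Component–annotation association
uses a Pearson correlation test for numeric annotations and
Kruskal–Wallis across levels for categorical ones (robust to the
non-normal coordinate distributions typical of methylation PCs);
annotations with one populated level are skipped with a notice, and the
significance mask defaults to p < 0.01.

Region-set enrichment counts **universe regions** (any-base-pair
overlap defines membership in the query and in each catalogue entry),
builds the 2x2 table, and computes the one-sided Fisher exact p — the
upper hypergeometric tail — plus an odds ratio with the Haldane 0.5
correction when any cell is zero. Query regions that overlap no universe
region are dropped with a count. Entries are ordered by the worst of
three ranks (p, odds ratio, overlap support), the same worst-rank idiom
as the differential tables. Base-pair-level counting is out of scope.

## The synthetic cohorts

The generator emulates a two-group sequencing cohort: per-cell betas are
Beta(m·κ, (1−m)·κ) draws around planted site means (baseline κ = 50,
i.e. per-site sd ≈ 0.07 at m = 0.5, typical of deep RRBS), with a
bimodal baseline mean distribution; coverage is negative binomial (mean
30, dispersion 10); zero-coverage cells are missing. Planted effects:
DMCs shift group-1 means by δ = 0.3 in blocks of 5 consecutive CpGs
(the blocks are emitted as BED DMRs); DVCs divide κ so the group-1
variance is inflated by ρ = 4; ten age-informative CpGs define age =
20 + 100 × (their mean beta) + N(0, 2) years; males halve chrX coverage
and gain chrY coverage; LUMP-site means track a planted purity drawn
U(0.3, 1); genotyping probes draw genotypes from {0, ½, 1} with tight
noise; optional mixture CpGs combine uniform reference profiles with
Dirichlet weights. All truths are emitted in ground-truth tables and
everything derives from one seed (byte-identical regeneration is
tested).

What the fixtures do **not** emulate: spatial correlation between
neighbouring CpGs beyond shared block means, batch and position
effects, array probe chemistry (type I/II bias), bisulfite conversion
failure, and realistic linkage between covariates (age, sex, purity and
cell composition are independent by construction). Passing tests
therefore demonstrate correctness of the algorithms under their own
model assumptions and calibrated behaviour on clean data — not
robustness to the technical artifacts of production cohorts.

Study sizes used by the tests and the acceptance script, chosen once on
power grounds: null calibration pools three 5,000-unit cohorts at
n = 20 per group (Monte-Carlo se ≈ 0.0018 on a 0.05 rate); the
differential-methylation power study uses n = 20 per group (a mean
shift of 0.3 against sd ≈ 0.07 is a very large effect); the
differential-*variability* power study uses n = 60 per group, because a
variance ratio of 4 gives the deviation-based t a noncentrality of only
≈ 0.84·sqrt(n/2) — undetectable at n = 20 (≈ 2.6) but comfortably
detectable at n = 60 (≈ 4.6), matching the field's experience that
variability analyses need substantially larger cohorts than mean
analyses. The age study uses 300 samples over 2,000 CpGs (10 causal),
split 200 train / 100 test.

## Numerical choices and degenerate inputs

- p-values are floored at the smallest positive double and capped at 1;
  zero pooled variance with the prior off yields the floor with a
  warning (with the prior on, shrinkage handles it).
- The trigamma inversion runs damped Newton from x = 0.5 + 1/y with a
  1e-8 lower bound; 50 iterations far exceed what convergence needs.
- Bartlett statistics are undefined when a group variance is 0; such
  units get NaN p and are never selected, and their count is visible in
  the table.
- Ranks use competition ("min") ranking so ties share the best rank.
- All exported floats print with `repr` (shortest round-trip form) and
  are re-read with correctly-rounded parsing, making export/import
  cycles lossless; pandas' default fast float path is avoided where it
  would truncate.
- Elastic-net fits use coordinate descent with tol 1e-6 and up to 5·10⁴
  iterations; the λ grid is log-spaced and the CV tie-break takes the
  first minimiser (smallest λ).
- The pipeline is strictly serial and seed-driven; optional stages
  (inference, exploration, enrichment) record failures and continue,
  import/preprocessing failures abort. Resource profiles gate nothing
  numeric.

## Known limitations

- Two-group comparisons only; no covariate-adjusted or paired designs.
- No array normalisation (the package ingests already-normalised beta
  tables) and no IDAT parsing.
- The enrichment universe must be supplied (or generated); no region
  catalogues ship with the package.
- No pre-trained age/sex models or LUMP site lists are shipped; users
  train their own or import coefficient tables.
- iEVORA's t-filter makes it blind to symmetric variance changes; use
  diffVar when such effects matter.
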