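# Methods

## The burden permutation null

For one gene and one variant class, let the qualifying set be the variants
of that class with combined-cohort alternate-allele frequency below the
rarity threshold (default 1%). Each sample's weight is its total count of
qualifying alternate alleles (heterozygote 1 per variant, homozygote 2,
missing calls 0); the K samples with positive weight are the carriers and
the statistic is S = Σ weights over case samples.

Under the null that case/control status is exchangeable, the case group is
a uniform draw of n_case of the N samples without replacement. Only
carriers matter, so the number M of carriers landing in the case group is
Hypergeometric(N, K, n_case), and given M = m the carrier subset is uniform
over the C(K, m) subsets. The package computes Pr(S = s) exactly:

* all weights 1 (the common case): S = M, closed-form hypergeometric;
* general integer weights: a subset-sum convolution counts m-subsets of
  the weights by their sum, then mixes over m with the hypergeometric
  probabilities. Counts are held in floats (exact for the magnitudes
  involved); the resulting pmf is renormalised and must sum to 1 within
  1e-12.

The exact path is used up to 500 carriers; beyond that a seeded Monte-Carlo
path resamples labels (hypergeometric draw of m, then a multivariate-
hypergeometric draw across weight groups), with the binomial standard
error reported.

**P-value convention.** The default is the one-sided mid-P,
Pr(S > S_obs) + ½·Pr(S = S_obs). The plain tail Pr(S ≥ S_obs) is roughly
twice as large for the carrier configurations typical of rare-variant
genes and is available via `convention="tail"`; mid-P is the default
because it removes most of the conservatism that the discreteness of S
otherwise imposes, making the test's null distribution close to uniform
(the type-I rate at 0.05 is then near-nominal, which the test suite
checks). With mid-P the test reproduces published values for this class of
analysis; with the plain tail it does not.

**Gene admission.** A gene is tested only if its Class 3 (widest class)
carrier count is at least 10; all three class tests are then computed,
including classes with fewer carriers. The multiple-testing denominator is
the number of (gene, class) tests actually computed with at least one
carrier, because the composition of conducted tests is data-dependent.
Output rows are ordered by per-gene minimum P, ties broken by gene symbol
for determinism.

## Single-variant scan

The association unit is the allele: each called diploid genotype
contributes two alleles to its group's margin, missing genotypes none. The
minor allele is whichever of reference/alternate is rarer in the combined
cohort. The test is the two-sided Fisher exact test under the
probability-mass rule (sum the probabilities of all tables, at fixed
margins, with probability not exceeding the observed table's, relative
tolerance 1e-7 — the convention of the standard R/scipy implementations).
It is computed by direct hypergeometric enumeration via log-gamma, which
also yields a mid-P variant (the observed probability class at half
weight); `scipy.stats.fisher_exact` serves as an independent cross-check
in the test suite, not as the implementation.

**Minimum-possible-P pruning.** A variant with m observed minor alleles
can never beat the P of the table that puts all m in cases. Variants whose
best-case P exceeds the Bonferroni threshold implied by the retained count
are dropped, and the threshold alpha/|retained| is recomputed until the
retained set is self-consistent (R = {v : p_min ≤ alpha/|R|}). Because the
retained count is non-increasing in the threshold the fixed point is
unique when it exists; a two-cycle (possible only when no exact fixed
point exists) resolves toward the larger set.

**Trimmed inflation factor.** The smallest `trim` fraction (default 10%)
of P-values — the candidate true signals — is discarded; the remainder are
converted to 1-df chi-square quantiles and the median is divided by the
median of the correspondingly truncated null. For uniform P restricted to
(trim, 1] the median P is (1+trim)/2, so the reference at trim = 0.10 is
the 45th percentile of chi-square with 1 df. The diagnostic is computed
from the mid-P column of the scan rather than the plain exact P: exact-test
discreteness biases the plain-P quantiles upward and reads as spurious
deflation (lambda ≈ 0.84 on a perfect simulated null, versus ≈ 0.95 with
mid-P), which would mask genuine inflation. Inference P-values are never
mid-P-corrected.

## Quality control

Genotype support: a non-reference call stands only if GQ ≥ 30 and
alternate depth > 3 (strict) and the site's truth-tranche sensitivity is
below 99.5 (SNVs) / 99.0 (indels); failing calls become missing.

Sample QC runs on the designated common-SNV subset. Missingness and
heterozygosity outliers are flagged above mean + 3 SD, with the SD taken
as the population (n-denominator) SD over all samples including
candidates, in a single pass — the simplest reproducible reading of a
3-SD rule; only the high side is flagged. Sex is inferred from the
X-chromosome inbreeding-style statistic F = 1 − h_obs/h_exp (h_exp from
pooled X allele frequencies): F > 0.8 infers male, F < 0.2 female,
otherwise undetermined and never excluded; samples with no reported sex
are never flagged. Duplicates are pairs exceeding 0.95 genotype
concordance over at least 200 mutually called common SNVs — simulated
unrelated pairs sit near 0.55–0.75 concordance, so the margin is wide —
and the member with higher missingness is marked. Ancestry exclusions are
consumed as an input list (no PCA is performed). A sample is excluded if
any flag is set; the summary counts each of the five categories and a
deduplicated total.

Variant QC has two tracks. Both require alignability = 1 and distance to
the nearest simple repeat > 10 bp (inclusive: distance ≤ 10 fails, 0
meaning inside the repeat). The single-variant track additionally tests
Hardy-Weinberg equilibrium separately in cases and in controls (exact
conditional test, fail if either P < 1e-5), differential no-call between
groups (two-sided Fisher, fail below 1e-5), and a 3% no-call cap per
group. The gene-centric track first removes individual heterozygous calls
with unbalanced read support (χ² against 50:50, P < 1e-4, zero-depth
heterozygotes likewise), then tests HWE on cases+controls combined at 1e-8
and caps the per-group no-call rate at 25% (inclusive). The HWE test is
the exact conditional test (probabilities of heterozygote counts no more
probable than observed, given allele counts); a χ² variant is provided but
the exact test is the default everywhere.

## Power simulation

Control frequency p₀ maps to case frequency via the per-allele
relative-risk model p₁ = RR·p₀/(1 − p₀ + RR·p₀) (rare-disease
approximation; the mapping is isolated in one function so an alternative
can be substituted). Single-variant power draws case/control minor-allele
counts binomially over 2n alleles per group and applies the two-sided
Fisher test; burden power draws carrier-sample counts binomially and
applies the exact mid-P burden test with unit weights. Power is the
fraction of B replicates (default 10,000) at or below the supplied
threshold, with binomial standard error. Note the mapping can never
produce p₁ ≥ 1 for finite RR, so the corresponding input guard is purely
defensive. At the reference design (MAF 0.01, RR 4.0, n = 513/1,569,
alpha = 2.02e-6) the exact rejection probability of the two-sided Fisher
test is 0.80 — substantial but not overwhelming power for that allele
class.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes, at
the reference study conditions by default (513 cases, 1,569 controls, a
6,100-site high-confidence common-SNV subset):

* rare exonic variants: 80% of sites with population MAF below 1%
  (log-uniform on [5e-4, 0.01]), the rest uniform on (1%, 5%]; genotypes
  in Hardy-Weinberg proportions, drawn identically for cases and controls
  at null genes;
* consequence labels drawn from a fixed distribution (50% missense, of
  which 40% CONDEL-damaging, 25% synonymous, 10% disruptive, the rest
  splice/in-frame/other);
* the common-SNV subset at MAF 0.2–0.5 for sample QC, and a 200-site X
  block for sex inference (males hemizygous, coded homozygous);
* per-genotype metadata: total depth negative-binomial (mean 60, size 10,
  floor 8), GQ with 3% mass below 30, heterozygote alternate reads
  Binomial(depth, ½); 0.5% baseline no-call rate;
* planted gene signals: `exact_counts` mode places exactly the requested
  case/control carriers (default one allele each; weights of 2 create
  homozygotes), `relative_risk` mode draws carriers at c₀ and the
  RR-mapped c₁. Planted genes generate only synonymous background
  variants, and planted sites are exempt from baseline missingness and
  carry guaranteed-supported metadata, so the requested configuration is
  realised exactly end-to-end;
* injected QC failures, each logged in a truth object: missingness
  outliers (10× baseline no-call), heterozygosity outliers (hets forced to
  80% of the common subset), duplicate pairs (genotype copies), reported-
  sex flips, HWE-violating sites (all carriers homozygous alternate),
  repeat-proximal sites (distance ≤ 10), low-GQ genotypes, and
  allele-imbalanced heterozygotes (alternate fraction 0.1).

Everything is deterministic given the config seed (failure injection uses
a child seed, so it is reproducible whether run inside or after cohort
generation).

**What the generator does not model** — linkage disequilibrium, population
stratification, capture-kit differences between groups, sequencing-read
error processes, and transcript-level annotation. Passing tests therefore
demonstrate the statistical machinery (calibration, recovery of planted
signals and injected failures, threshold arithmetic) and not robustness to
those real-data complications; the differential-missingness filter, in
particular, is exercised by injected missingness rather than by a
capture-difference model.

## Problem sizes and numerical choices

Validation runs use a 500-gene cohort at full sample size (513/1,569; about
10,000 variants) for null calibration — large enough for a stable KS test
of burden-P uniformity and a stable trimmed lambda — and reduced cohorts
elsewhere. The Monte-Carlo permutation default is B = 1e6 with the exact
path preferred up to 500 carriers, so Monte-Carlo is rarely exercised in
practice. Degenerate inputs are defined rather than erroneous wherever a
definition exists: zero genotypes give HWE P = 1, an all-zero Fisher table
gives P = 1 with missing odds ratio, S_obs = 0 gives mid-P = 1 − ½·Pr(S=0),
and empty qualifying sets simply produce no result row. Exact-path pmf
round-off is clipped so reported P stays within (0, 1].

## Known limitations

* In-frame insertions/deletions sit above missense in the severity
  hierarchy but are assigned to Class 3 (they are non-synonymous yet not
  splice/CONDEL-damaging); the class definitions do not name them, and
  this placement is the conservative reading.
* The combined-cohort MAF filter treats the alternate allele as the rare
  allele; sites where the reference allele is the minor one do not qualify
  for collapsing (they are effectively common) — consistent with counting
  alternate alleles as the burden unit.
* Two published weight-1 rows with identical carrier configurations imply
  a P that differs from the exact mid-P value in the third significant
  figure; whether those reflect Monte-Carlo estimation or unprinted
  homozygous carriers cannot be determined, so regression checks use the
  configurations whose printed values the exact computation reproduces.
* The duplicate-concordance threshold (0.95) and the sex-inference F cuts
  (0.8/0.2) are conventional rather than published values.
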