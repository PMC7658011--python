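# Methods

## The trend statistic and its null

A gene observed in ordered generation groups of sizes (n₁,…,n_k) is called
monotone-declining when, for every adjacent pair of groups, the maximum
replicate value of the later group lies strictly below the minimum of the
earlier one; "up" mirrors this. Equality at any boundary defeats the call and
is flagged as a tie. The statistic depends only on within-gene ranks, so it
is invariant under any strictly increasing transform of the expression
values — RPM scaling, a log, or a pseudocount shift applied uniformly cannot
change a call.

Under the null that a gene's values are exchangeable and continuous, full
separation in a fixed direction has probability ∏nⱼ!/N!, and the up/down
events are disjoint, so both directions together have twice that: 1/840 for
the 3×3 design. This is exact; `permutation_null` re-derives it by
label-shuffling as an independent check. Real counts are discrete, so ties
make the analytic probability a slight over-estimate of the empirical
separation rate; tied genes are logged, and the false-positive calibration
test shows the deflation is a few percent at bulk library depths.

With m genes tested, the chance expectation is E = m·(1/840). m defaults to
genes with nonzero total count across samples and is exposed as an override,
since results are reported relative to an explicit gene universe. The excess
O − E is tested with z = (O − E)/√E: a normal approximation with Poisson
variance, appropriate for a count of rare independent events. The one-sided
upper tail is used because the question is an excess over chance. The
observed count gets an exact two-sided CI via chi-square quantiles
(low = ½χ²(α/2, 2c), high = ½χ²(1−α/2, 2c+2)); the Clopper–Pearson binomial
interval on c/m scaled back to counts agrees to well under one count when
c ≪ m, and both are reported unrounded, with an option to round to the
nearest ten for display.

The test runs on RPM rather than log-median-centered values. For the log2
step this is immaterial (monotone transform); median-centering, however,
shifts each sample by its own median, which is not a within-gene monotone
transform and can in principle flip a borderline call when per-sample
medians differ. Detection therefore precedes centering, and the pseudocount
defaults to 0 for detection.

## Normalization chain

RPM uses the column sum over all genes of both organisms as the library
size, so host and symbiont shares are complementary fractions of the same
library. TMM factors follow the published algorithm: log2 ratios (M) and
average log2 abundances (A) against a reference sample (the one whose
upper-quartile count fraction is closest to the mean), genes with a zero in
either member of a pair excluded, the most extreme 30% of M and 5% of A
trimmed by rank, remaining M-values averaged with inverse delta-method
variances as weights, and the factors renormalized to geometric mean 1. The
implementation is checked against edgeR's `calcNormFactors` to ~1e-8
relative error in the test suite. Differential-expression calling itself is
out of scope: the pipeline consumes an externally produced significant-gene
id list and intersects it with the monotone calls.

## Colonization morphometry

Hyphae are modelled as circular in cross section (the diameter is the only
measured shape parameter). Per-hypha areas π(d/2)² are averaged first and
then multiplied by the section's hyphal count to give the biovolume index
(μm²·hyphae); averaging diameters before squaring is available as a switch,
since the two differ by Jensen's inequality whenever diameters vary, but
per-hypha areas are the default because the index is meant to track total
cross-sectional area. Sections with no hyphae contribute biovolume 0 and a
missing diameter; genotype summaries are unweighted means over the
genotype's sections, with diameter means skipping empty sections.

Generation comparisons use the tie-corrected Kruskal–Wallis test applied to
per-genotype means (one value per plant, the sampling unit), with
all-identical inputs returning H = 0, p = 1 rather than an error. The
chi-square approximation to the permutation distribution of H is good in the
moderate-p regime and anticonservative in the extreme tails at these group
sizes (8–10 per group); the test suite checks agreement with a label
permutation in the informative regime. Vascular-bundle colonization pools
hyphal counts within a generation and uses Pearson's chi-square without
continuity correction on the k×2 table, warning when an expected cell is
below 5 — at the observed frequencies (a few hyphae per thousand) the test
is approximate by nature. Percent declines are computed on generation means
of genotype means, consistent with the Kruskal–Wallis unit.

## Synthetic data generators

`simulate_counts` emulates pooled-replicate dual RNA-seq: log-normal gene
means (location immaterial — relative shares are renormalized to the library
size; spread 1.2 on the natural-log scale gives a realistic dynamic range),
negative-binomial counts parameterized by mean and dispersion φ
(variance μ + φμ², φ = 0.1 by default, typical bulk overdispersion), a
20-million-read library, 13,440 host plus 300 symbiont genes with the
symbiont share targeted at 0.3% of reads, and an optional planted fraction
of host genes declining geometrically (multipliers 1, δ, δ²). Pooling of
genotypes within a replicate is not modelled explicitly; replicate noise
absorbs it, since the analysis only ever sees pooled replicates. Truth
labels are returned separately and never written into data files.

`simulate_sections` draws per-section hyphal counts (negative binomial,
φ = 0.01 so that generation means estimated from 8–10 genotypes carry a
~2–3 percentage-point sampling error on percent declines), per-hypha
diameters (normal truncated at zero, at most 50 measured per section to
mirror the measured subsample), and binomial vascular counts. Defaults
encode the observed decline pattern: count means 250/180/62.5 (a 75% drop),
diameter means 2.0/1.93/1.74 μm, giving biovolume declines of roughly a
third by G6 and ~80% by G9, and vascular rates rising from 4×10⁻⁴ to
3×10⁻³.

`simulate_maintenance_program` gives every plant a seed-transmission
probability τ, Beta-distributed across founders with mean 0.76 and
concentration 1.0 — a deliberately variable founder pool, the condition
under which selection can move the population mean appreciably per cycle.
Offspring inherit their parent's τ with weight h (default 1) and regress to
a fresh population draw otherwise; each offspring is infected with
probability τ(parent); the next parent pool is the infected offspring,
except in the two generations (3 and 5) bred without selection. Selection on
infection weights parents by τ, so the pool mean ratchets upward whenever
h > 0 and τ varies — from ~76% toward >95% over nine cycles — and stays flat
when h = 0. Real-program mechanics (plot sizes, harvest pooling, pollen
flow) are not modelled; the simulator exposes parameters instead of
asserting historical values.

`simulate_tillering` grows tillers geometrically from 3 initial tillers,
observed every 2 days, with optional multiplicative log-normal noise and
counts constrained non-decreasing within a plant.

What the generators do not emulate: genotype-specific expression (samples
are pools), clonal structure of the symbiont, sequence-level artifacts,
batch effects, or compositional distortion beyond what TMM corrects.
Passing tests therefore demonstrate correctness of the statistics under the
stated sampling models, not robustness to every artifact of real dual
RNA-seq.

## Numerical choices and limitations

- Problem sizes in tests and drivers match the study design (13,440 host
  genes, 3×3 samples, 9/10/8 genotypes, 200 tested plants per generation);
  the permutation oracle uses 10⁵ permutations.
- Seeds: every generator takes an explicit seed; fixing it fixes outputs
  bit-for-bit. Drivers derive stage seeds by small offsets from one base.
- Degenerate inputs: zero library sizes, empty groups, negative counts and
  out-of-range infection counts are hard errors naming the offender;
  zero-hyphae sections, all-tied genes and flat phenotypes are valid data.
- The z-test's normal approximation is comfortable at E ≈ 16; for very small
  expectations an exact Poisson tail would be preferable.
- The monotone criterion is deliberately threshold-free and scale-free; its
  power depends on replicate noise, and with only three replicates per group
  a single outlier replicate defeats an otherwise clear trend.
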