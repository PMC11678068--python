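# Methods

This note documents the models, parameter choices, and numerical
conventions behind each stage of the analysis, the assumptions of the
synthetic-data generator, and the limitations of both.

## Rate estimation (Nei–Gojobori counting)

`kaks_pair` implements classic NG86-style counting with equal pathway
weights:

- **Sites.** Each position of a sense codon contributes
  (# synonymous single-nucleotide mutants at that position)/3 synonymous
  sites; mutants that create a stop codon count as nonsynonymous.  Every
  sense codon therefore contributes s + n = 3 sites, and the 61 sense
  codons of the standard code contribute 183 sites in total.  Per aligned
  pair, S and N are averaged over the two sequences.
- **Differences.** Between two codons differing at d positions, all d!
  orderings of the substitutions are enumerated; each step is classified
  synonymous/nonsynonymous against the standard code.  Pathways passing
  through a stop codon are excluded and the remaining weights
  renormalised; if every pathway passes through a stop (possible for a
  handful of codon pairs), all pathways are kept with equal weight, with
  the step into the stop counted as nonsynonymous.
- **Correction.** pS = Sd/S and pN = Nd/N are corrected for multiple
  hits with the one-parameter formula d = −(3/4)·ln(1 − (4/3)p), which
  is undefined for p ≥ 3/4; the affected rate (and hence ω) is then
  reported as missing rather than clamped.  ω = Ka/Ks is defined only
  when both rates are defined and Ks > 0.
- **Alignment handling.** Codon columns containing a gap or an N in
  either sequence are dropped from both sequences; the reading frame is
  fixed by the alignment (no frame search).  An alignment with zero
  usable codons is an error.

This estimator deliberately omits transition/transversion and
codon-frequency corrections (the YN-class refinements): it is a fully
specified, exhaustively testable method that serves the same role —
per-pair Ka, Ks and ω — and all of its counting behaviour is pinned
against an independent brute-force enumeration oracle in the tests.
Numeric agreement with YN-class estimates on real data is not claimed.

### Ortholog selection and quality control

`select_ortholog_pairs` keeps hits with E-value ≤ 1e−5 and identity
≥ 90% (both bounds inclusive), takes per query the best hit (maximum
bitscore, then minimum E-value, then lexicographically smallest subject
id), and then per subject the best query by the same ordering.  A query
whose best subject is claimed by a stronger query drops out entirely —
its weaker hits are not revisited — so the mapping is strictly
one-to-one.  Filtering happens after pairing.

`apply_qc_filters` removes rows with Ka > 1 or Ks > 5, rows with zero or
missing Ka or Ks, and then trims the Ks distribution symmetrically: rows
strictly below the α/2 or strictly above the 1 − α/2 empirical quantile
(linear-interpolation quantiles) are removed, α = 0.05 by default.  The
trim is an interpretation of a Ks-based α = 0.05 retention step whose
exact definition is not standardised; it is exposed as a configurable
and skippable stage, and the filter log reports per-rule removal counts.

A side effect worth knowing: because Ka = ω·Ks, the Ka ≤ 1 rule couples
ω and Ks in the retained set (it preferentially removes loci where both
are large).  At the interspecies Ks scale used by the generator
(mean ≈ 0.22) the rule essentially never fires and the coupling is
negligible; at much larger Ks scales it induces a visible spurious
positive correlation between expression and Ks downstream.

## Expression metrics

- **Present calls**: EST/cDNA loci are present with at least one
  sequence (abundance ≥ 1); RNA-Seq loci with ≥ 1 RPM (inclusive);
  microarray calls must come from external preprocessing and are left
  missing otherwise, excluding those records from breadth counting.
- **Abundance windows**: loci with zero abundance are excluded (their
  log is undefined); the rest are sorted ascending with ties broken by
  locus id, cut into disjoint windows of exactly 100 loci, and the
  trailing partial window is dropped.  Windows average
  log10(abundance) — the mean of logs, matching per-point averages on a
  log axis — along with Ks, ω and phylostratum.
- **Tertiles** are rank-based equal-size groups (± 1, remainder to the
  lower groups first), with zero-abundance loci in "low".  Fixed
  abundance thresholds would be an alternative reading; rank-based
  groups are scale-free and need no tuning.
- **Breadth** counts present calls over a fixed sample universe
  (11 samples by default, overridable); classes are 0 / 1 / ≥ 2
  (not expressed / specific / broad).

## Distribution-shape test

`norm_approx_test` draws a reference sample of the same length from
Normal(mean(x), sd(x)) with an explicit seed, partitions
[min(ref), max(ref)] into k equal-width bins, widens the outer breaks to
±∞ so every observation of both samples is counted (half-open binning),
and cross-tabulates the k (observed, reference) count pairs by distinct
value into an r×c table tested with Pearson's independence statistic,
df = (r−1)(c−1), no continuity correction.  Equal-probability
(quantile) breaks are available behind a flag; equal width is the
default because it is the executable definition of the procedure.

Two properties deserve emphasis:

- Whenever all reference counts are distinct — overwhelmingly likely for
  continuous data at moderate n — the statistic collapses to the
  structural identity statistic = k(r−1), df = (r−1)(k−1), where r is
  the number of *distinct observed bin counts*.  Two very different
  datasets can therefore print identical results; the tests reproduce
  the canonical k = 30, r = 25 case (statistic 720, df 696, p = 0.2566)
  exactly, and the identity is verified against brute-force table
  computation over small count alphabets.
- The procedure measures association between paired count patterns, not
  goodness of fit in the conventional sense.  `classic_gof_test`
  provides the conventional counterpart (expected counts from the fitted
  normal CDF over the same bins, df = k − 3); on clearly non-normal data
  the two can disagree dramatically, which `analysis/04` demonstrates.

Degenerate tables (a constant count vector) return statistic 0, df 0,
p 1 with a warning rather than erroring.

## Hitchhiking proximity test

Anchors are loci with ω strictly greater than 1.  Every other locus gets
its minimum ordinal distance (in loci) to an anchor on the same
chromosome — distances never cross chromosome boundaries — and is
assigned to the unique band containing that distance (defaults 1–5,
6–10, 11–15; a tighter 1–2/3–4/5–6 set is provided for shallow
comparisons), or to the background otherwise.  Min-distance assignment
counts each locus exactly once even between two nearby anchors.  The
background group is **all** non-anchor loci, banded or not; anchors are
excluded everywhere since their ω > 1 by construction.  Comparisons use
Welch (unequal-variance) two-sample t-tests.

Because each band is a subset of the background, the band-vs-background
test overstates the variance of the mean difference and is conservative
(measured null rejection ≈ 0.015 at nominal 0.05); the adjacent-band
comparisons are disjoint and calibrate at their nominal rate.  The
conservative direction is harmless for the headline claim (elevated ω
near anchors), which is detected at p ≪ 0.01 under the default
generator.

## Correlation smoothing and the permutation test

`rank_nearest_smooth` estimates E(x|z) empirically: for each
observation, the m = 100 observations with the nearest z (self included,
distance ties to the smaller index) are averaged.  A flag smooths
rank-transformed vectors instead; the default smooths raw values, the
more direct reading of "nearest values".  The simulation design point —
x = z + ε, y = z + ε′, ε ~ Normal(0, 3), n = 5000 — has population
marginal cor(x, y) = 1/(1 + 9) = 0.1; smoothing recovers cor ≈ 0.92
because the neighbourhood averages suppress the noise by roughly √m.

`perm_corr_diff_test` tests cor(x, z) − cor(y, z) for paired (x_i, y_i):
under the null each pair may swap its x and y, giving 2^n swap patterns.
The default **aligned** construction mixes elementwise and preserves
pairing with z; the **literal** mode reproduces the concatenation
construction of the original formulation (which misaligns pairs with z
for non-prefix patterns) behind a flag — the two coincide on prefix
patterns and on the observed statistic.  All patterns are enumerated
when 2^n ≤ 100,000, else that many are sampled uniformly with
replacement, seeded.  Complementary patterns negate the statistic, so
the exhaustive aligned distribution is antisymmetric with mean zero and
exhaustive p-values are multiples of 2^−n.

The sign-adaptive one-sided p-value (tail chosen by the sign of the
observed difference) is the minimum of the two one-sided p-values;
rejecting when it is below α has type-I error close to 2α (measured
0.094 at α = 0.05).  An `alternative` parameter fixes the tail a priori
("greater"/"less"), restoring exact calibration (measured 0.051); the
calibration checks in the tests and the acceptance script use the fixed
tail.

## Group summaries

Incidence tables test the G×2 contingency of group × (ω > 1) with
Pearson's chi-square, no continuity correction.  Group profiles report
one-way ANOVA plus pairwise Welch t-tests (two-sided; no multiple-testing
correction by default, Benjamini–Hochberg behind a flag) summarised with
a compact letter display built by insert-and-absorb: start from one
letter covering all groups, split every letter containing a
significantly different pair, absorb letters contained in others.
Groups share a letter iff not significantly different at the chosen α.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
with one seeded `numpy` generator threaded through all sampling so a
fixed seed reproduces every table bit for bit.  Defaults (the study
conditions for all tests):

| parameter | default | meaning |
| --- | --- | --- |
| n_loci / n_chromosomes / n_samples | 20,000 / 5 / 11 | genome and sample universe |
| ks_mean, ks_sd | 0.22, 0.08 | Ks ~ Normal truncated to (0, 5]; the scale of a recent interspecies split |
| omega_logmean, omega_logsd | −1.7, 0.6 | lognormal base ω, median ≈ 0.18, right-skewed |
| ps_probs | decreasing, 0.25 → 0.03 | gene-age classes 1..13; most genes ancient |
| ps_omega_slope | 0.9 | added to log ω, scaled by (ps−1)/12: younger genes evolve faster |
| anchor_rate | 0.0165 | fraction of loci forced ω > 1 (matching a ~1.6% genome-wide incidence) |
| hitch_amplitude, hitch_range | 0.15, 15 | triangular kernel: ω += a·max(0, 1 − d/range) around anchors |
| gea_intercept, gea_omega_slope, gea_ps_slope, gea_noise_sd | 2.5, 2.0, 1.0, 0.8 | log10 GEA = intercept − slope·rank01(ω) − slope·(ps−1)/12 + noise; median expressed locus ≈ 10 RPM |
| breadth_steepness, breadth_pivot | 6.0, 0.35 | per-sample presence is Bernoulli with logistic probability in the abundance rank |

Design notes:

- **Ka = ω·Ks** rather than independently sampled, so emitted tables are
  internally consistent by construction.
- **Ks is independent of expression by construction** — the generator's
  null for the "neutral proxy is uncoupled" claim.  The window-level
  GEA–Ks correlation is then pure sampling noise (sd ≈ 0.07 over ~190
  windows) plus the (negligible at this Ks scale) QC-filter coupling
  described above.
- The **triangular kernel** is linear in distance for analytic
  transparency, with range 15 so all three default bands receive signal.
- The **expression model** is log-linear with additive Gaussian noise —
  the simplest model producing the intended qualitative correlation
  structure (strong negative GEA–ω and GEA–age, near-zero GEA–Ks).
  Total abundance is split across present samples with a uniform
  Dirichlet; EST counts are Poisson in the per-sample abundance;
  microarray signals carry the generative present call, standing in for
  externally preprocessed calls.
- `evolve_codon_pair` mutates a random sense-codon ancestor with exact
  numbers of synonymous and nonsynonymous single-nucleotide events,
  never creating stops, by rejection sampling positions.  Repeated hits
  on one codon can make the NG86 pathway decomposition fractional, so
  "synonymous events only ⇒ Ka = 0" holds when events land on distinct
  codons (overwhelmingly likely at 500 codons and tens of events; the
  test seeds are in that regime).

What the generator does **not** emulate: real codon-usage and mutation
spectra, recombination-rate variation, genuine selective sweeps
(coalescent dynamics), correlated sample structure in expression, gene
length/intron effects on expression, or assay-specific noise models.
Passing tests therefore demonstrate that the pipeline recovers the
couplings it was designed to detect from data with the assumed
structure — not that the biological couplings hold in any real genome.

## Problem sizes and determinism

The default genome (20,000 loci) runs the whole pipeline in seconds;
estimator-vs-oracle checks use 500 random codon pairs; permutation
calibration uses 1000 replicates of n = 12 (exhaustive, 4096 patterns
each); the smoothing demonstration uses n = 5000 with m = 100
neighbours.  Every stochastic stage takes an explicit seed; there is no
global random state anywhere in the package.

## Known limitations

- The NG86-style estimator is biased relative to ML/YN-class estimators
  when transition/transversion rates are strongly asymmetric.
- The paired-count shape test's structural identity makes its p-value
  insensitive to much of the data; treat it as the documented procedure
  it is and consult `classic_gof_test` for conventional inference.
- The literal permutation mode is retained for faithfulness, not
  recommended for inference.
- Microarray present calls are consumed, never computed.
- Phylostrata are taken as an input column; no phylostratigraphic
  mapping is performed.
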