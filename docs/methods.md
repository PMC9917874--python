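# Methods

## Kinetic model and its assumptions

The analysis assumes first-order degradation of the pre-existing light
pool, P_L(t) = P_TOT·e^(−kt), with the heavy pool as its complement
(P_H = P_TOT − P_L), which holds when the experiment is at steady state:
total amount, synthesis rate and k constant over the time course, a single
kinetic compartment, and no recycling of light amino acids into new
protein. Under these assumptions the heavy/light ratio is
r(t) = e^(kt) − 1, and ln(r+1) = kt is linear through the origin. The
model deliberately has **no intercept**: y(0) = 0 is forced by the
chemistry, and a free intercept would absorb label-incorporation lag that
the one-compartment model excludes. There is no cell-division dilution
term because the intended setting is confluent (non-dividing) cultures;
for dividing cells k would be confounded with the growth rate. For
secreted proteins the estimated k conflates degradation and secretion.

## Technical noise model

Replicate peptides of one protein in one sample spread around the protein
ratio with SD(r) = √(α² + β²r²): an additive floor α (ratio units,
default 0.02) from detection noise near r = 0, and a multiplicative
component β (dimensionless, default 0.1, the asymptotic CV) at large r.
Calibration bins protein measurements on r (width 0.05, bins merged
rightward until they hold ≥ 10 measurements; a final under-filled bin is
kept with weight n/10) and least-squares fits (α, β) to the bin-median
SDs in SD space — the quantity the diagnostic plots — with non-negativity
enforced by optimising over α², β². The accompanying trend diagnostic
(one-sided Spearman tests at 0.05 on bin-median SD and CV against the bin
midpoint) rejects the constant-SD and constant-CV alternatives whenever
both components are present. The pipeline default uses the fixed
constants (0.02, 0.1); `noise_source: fit` switches to refitting.

Calibration caveat: the across-peptide sample SD from n peptides is a
noisy, slightly downward-biased estimate of σ (the median of the
chi-distributed SD at n = 5 sits ~8% low), and the 50% measurement-CV
filter further truncates high-SD measurements at small r. Calibration is
therefore best done on data with many replicate peptides per protein; the
validation suite uses 20, while the cohort simulation keeps the realistic
2–15.

## Weighted least-squares fit

With absolute inverse-variance weights w = (1+r)²/SD(r)² (delta method on
y = ln(1+r)), the through-origin WLS estimate has the closed form
k̂ = Σwty/Σwt² and se(k̂) = √(1/Σwt²). The standard error uses the
a-priori weights without residual rescaling: with 2–3 points per fit a
reduced-chi-square estimate of the error scale is far too unstable
(`rescale_se=True` enables it for sensitivity checks). Because the noise
model is evaluated at the protein-level ratio rather than at the
peptide-averaged precision, the stated se is conservative when several
peptides back a measurement; the coverage check in the validation suite
reflects this (observed coverage near 100% at nominal 95%).

Negative or zero k̂ (possible for very slow proteins, where y is within
noise of 0) is marked invalid rather than clipped, and never enters
half-life summaries. CV(k̂) = 100·se/k̂ ≤ 50% defines a reliable fit;
the fraction below 15% is reported as a goodness-of-fit diagnostic.
Precision inherently degrades with half-life: at 24 h a protein with
T½ = 600 h has r ≈ 0.028, barely above the noise floor.

## Filters and their order

1. Across-peptide measurement CV ≤ 50% (strict: exactly 50% is kept).
   Single-peptide measurements carry CV = 0 and are retained but flagged
   `single_peptide` — the filter targets multi-peptide disagreement, and
   excluding singletons would silently bias the set toward abundant
   proteins. Multi-peptide measurements with zero mean have undefined CV
   and are excluded.
2. Time coverage: a (protein, subject) series must include 24 h and at
   least one of 4/7.5 h. The 24 h anchor carries most of the information
   for slow proteins; a series of early points alone cannot constrain k.
3. Estimate CV ≤ 50% after fitting, applied per fit (per subject), before
   any cross-subject averaging.
4. Cross-subject summaries and group tests require ≥ 2 subjects with
   values (per group, for the t-test).

Every filter reports in/kept/excluded counts into the run manifest, and
retained + excluded always equals the input count.

## Relative abundance and the steady-state diagnostic

Per sample (subject × time; runs and gel fractions merged at the peptide
level first), a protein's relative abundance is (Σ peptide intensity /
number of distinct observed peptides) / (total intensity of the merged
sample) — the mean peptide relative intensity, invariant to global
rescaling of a run. Intensities are light + heavy sums, so the measure is
label-independent. Under steady state, per-time values are averaged
arithmetically and log2 is taken of the mean.

The steady-state diagnostic compares, per protein, the median (across
subjects) within-subject variance of abundance over time against the
median (across samples) across-peptide variance of peptide relative
intensities. Both are on the same scale; temporal ≤ technical for most
proteins supports the steady-state premise. Because the technical term is
the spread of individual peptides (not of their mean), the comparison is
deliberately lenient — a temporal trend must exceed peptide-to-peptide
scatter to be flagged — which matches the diagnostic's role as a sanity
check rather than a test.

## Cohort statistics

Group comparison uses the pooled-variance (Student) unpaired two-tailed
t-test (Welch behind a flag); a Shapiro–Wilk flag at 0.05 on pooled
within-group residuals marks, but does not block, non-normal proteins.
Raw p-values are reported alongside Benjamini–Hochberg FDR — chosen as
the field default — because with 5 + 5 subjects and ≈ 1,000 tests,
biological between-subject variability leaves little power after
correction; the validation suite checks exactly this pattern (calibrated
null rate, effect detection by rank concentration rather than per-protein
significance). Abundance fold changes are signed: ratio ≥ 1 kept,
ratio < 1 reported as −1/ratio (negative = lower in the nephropathic
group), so |FC| ≥ 1 always.

Half-life bins use the standard 9 intervals (<20, 20–30, …, 80–90,
≥90 h) and log2-abundance the 8 intervals (<5.0 … ≥9.0), both
left-closed; values exactly at a quadrant threshold classify "high". The
quadrant thresholds are configuration inputs with the cohort medians as
default, since meaningful cut-offs depend on the intensity scale of the
instrument. The complex-coherence analysis draws 10 random same-size
protein sets without replacement (seeded generator) and reports the
fraction with larger SD/IQR than the complex members.

## Synthetic cohort generator

The generator emulates the study design: 2 groups × 5 subjects, times
{4, 7.5, 24} h, ~1,200 proteins per subject with 2–15 peptides, true
half-lives log-uniform over 3–600 h, true abundances log-uniform over 4
orders of magnitude, ratio noise per the SD model (normal, truncated at 0
by resampling), and missing-completely-at-random dropout (default 10% per
protein × time) plus an explicit mechanism forcing a chosen fraction of
series to miss the 24 h point so coverage-filter tests have known
expected counts. Group effects divide k of designated proteins in
nephropathic subjects by a half-life ratio (1.23 in the drivers, matching
the ~20–25% shifts a cohort of this size can plausibly exhibit).

Values the design itself does not pin down were fixed once as realistic
defaults: between-subject biological variability lognormal with 20% CV on
k and 30% on abundance (primary patient-derived cell lines vary
substantially more than technical replicates); peptide ionization factors
lognormal with σ = 1 (intra-protein peptide intensities in MS span well
over an order of magnitude), fixed per peptide across time so that true
abundance is time-stationary; multiplicative intensity measurement noise
lognormal σ = 0.2.

What the generator does **not** emulate: spectral detectability bias
(missingness is independent of abundance), retention-time or charge-state
effects, shared/razor peptides, label-incorporation lag, and
arginine-to-proline conversion. Passing tests therefore validate the
estimator and pipeline logic under the stated generative model, not
robustness to those real-data pathologies.

## Numerical choices and degenerate inputs

- Median of an even peptide count is the midpoint of the central pair;
  sample SD uses the n−1 denominator, SD = 0 for n = 1.
- Noise fit: `scipy.optimize.least_squares` over (α², β²) with bounds at
  0 and tight tolerances; an all-flat SD profile over a wide r range
  triggers a weak-identifiability warning (α absorbs the level).
- WLS: all-zero times or non-finite weights raise; an all-zero ratio
  series yields k = 0, flagged invalid rather than raised, so batch fits
  never abort.
- Zero pooled variance with unequal means maps p to the smallest positive
  float with a flag; identical groups give p = 1.
- t-test requires ≥ 2 subjects per group; smaller groups are recorded as
  skipped with a reason, not dropped silently.
- All randomness flows through `numpy.random.default_rng(seed)`; the same
  seed reproduces byte-identical pipeline outputs.

## Problem sizes used in validation

The test suite and the acceptance script run on simulated cohorts sized
for quick iteration while keeping all design ratios of the study: 500
proteins (single subject) for estimator recovery, 400 proteins × 20
replicate peptides for noise calibration, and 1,000 proteins × 10
subjects for the cohort-level null calibration and effect-detection
checks. These sizes give stable statistics (e.g. binomial error on the
null rate of ±1.5 percentage points) without materially longer runs.

## Known limitations

- se(k̂) ignores the replicate-count advantage of multi-peptide
  measurements (conservative by design; matching the weighting to the
  calibration source).
- The abundance measure is relative within a run; no absolute scaling
  (iBAQ-style) is attempted, so only within-cohort comparisons are
  meaningful.
- The CV-of-estimate reliability gate selects against slow proteins,
  so cohort mean half-lives are conditional on detectability.
- With 5 subjects per group, the t-test on lognormally varying
  half-lives is only approximately calibrated; the validation suite
  checks the null rate empirically.
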