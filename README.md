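# silacturnover

Protein turnover analysis for dynamic-SILAC (pulsed-SILAC) experiments.

In a dynamic-SILAC experiment, cells growing in light medium are switched to
medium containing a heavy isotope-labeled amino acid at t = 0 and sampled
over a time course. The pre-existing (light) pool of each protein decays as
it is degraded, while newly synthesised protein is heavy, so the measured
heavy/light peptide ratio r tracks turnover directly. This package takes
peptide-level quantification tables (one row per peptide observation, with
H/L ratio and peak intensity) and produces per-protein degradation rate
constants, half-lives, relative abundances, and two-group cohort
comparisons — the setting it was built for is a cohort of primary
fibroblast lines from diabetic patients with and without nephropathy,
sampled at 4, 7.5 and 24 h.

## Model

Under steady state (constant total pool P_TOT, constant synthesis, no label
recycling, one compartment), the light pool decays exponentially with rate
constant k and the heavy pool is its complement:

    P_L(t) = P_TOT · e^(−kt),   P_H(t) = P_TOT − P_L(t)

    r(t) = P_H / P_L = (1 − e^(−kt)) / e^(−kt) = e^(kt) − 1
    ln(r + 1) = k·t                 (a line through the origin)
    T½ = ln 2 / k

Peptide-level ratios are aggregated to protein ratios by the median;
replicate peptides of the same protein also calibrate a technical noise
model

    SD(r) = √(α² + β²·r²)          (defaults α = 0.02, β = 0.1)

which is neither constant-SD nor constant-CV: the SD grows with r while the
CV shrinks. k is then estimated per protein per subject by weighted least
squares on y = ln(r+1), with delta-method weights w = (1+r)²/SD(r)², and
se(k̂) = √(1/Σ w t²). The precision metric CV(k̂) = 100·se/k̂ gates
reliability (≤ 50%), after a measurement filter (across-peptide CV ≤ 50%)
and a time-coverage filter (quantified at 24 h plus at least one earlier
time point). Relative abundance is mean peptide intensity over the sample
total, averaged over time points under steady state; groups are compared
per protein with an unpaired two-tailed Student t-test (Shapiro–Wilk
normality flag, Benjamini–Hochberg FDR, signed fold change).

## Worked example

The numbered scripts under `analysis/` run the whole study on a simulated
cohort with known ground truth (2 groups × 5 subjects, 1,200 proteins,
2–15 peptides each, a 23% half-life increase injected into 20 proteins of
the nephropathic group):

```
$ python analysis/01_simulate_cohort.py
cohort: 270438 peptide observations, 1200 proteins x 10 subjects
proteins observed per subject: mean 1198 (range 1194-1200)

$ python analysis/02_calibrate_noise.py
1813 protein measurements in 32 bins
fitted alpha = 0.0188, beta = 0.0995 (generator truth: 0.02, 0.1)
verdict: reject_constant_sd_and_constant_cv

$ python analysis/03_fit_turnover.py
fits: 8236; reliable (estimate CV <= 50%): 8187 (88% of valid fits below 15% CV)
recovery vs truth: median relative bias of k -0.01%, 99.9% of true k within k +/- 2 se

$ python analysis/05_compare_groups.py
half-life: tested 965 proteins, 45 at p <= 0.05, 0 after BH correction
injected x1.23 effect (16 of 20 testable): median p 0.152 vs 0.523 in null
proteins (rank-sum p = 1.27e-04)
```

Reading the output: the noise calibration recovers the generating constants
from binned replicate spread and rejects the flat-SD/flat-CV alternatives;
the weighted fit is essentially unbiased with calibrated error bars; and
with only 5 subjects per group a 23% half-life shift is rarely individually
significant after FDR correction, but the affected proteins concentrate
clearly among the smallest p-values. Scripts 04 and 06 add the steady-state
abundance diagnostic, interval binning, turnover × abundance quadrants, and
the complex-vs-random half-life coherence comparison.

A `silac-turnover` CLI exposes the same stages for external tables
(`simulate`, `fit-noise`, `fit-turnover`, `abundance`, `compare`, `bins`,
`complex`, `run`); see `silac-turnover --help`.

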