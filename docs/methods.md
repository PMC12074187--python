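# Methods

## Overview

`cvrarima` characterizes the autocorrelative structure of cerebral
physiologic signals recorded during neurocritical care (intracranial
pressure, arterial pressure, perfusion pressure, brain oxygenation) and
of the cerebrovascular-reactivity (CVR) indices derived from them. The
pipeline has seven scientific stages: waveform-to-index derivation, a
missing-data rule plus a non-overlapping resolution ladder, ADF/KPSS
stationarity classification, an exhaustive ARIMA (p, d, q) grid search
scored by AIC/BIC/log-likelihood, subgroup comparison of the selected
criteria across clinical covariates, and one-step-ahead forecast
evaluation with Pearson and Bland–Altman agreement. Because real
multi-centre TBI recordings of this kind are not publicly distributable,
the package ships a seeded synthetic cohort generator with known ground
truth, and every stage is validated against that ground truth.

## Synthetic cohort model

A patient's waveforms are a sum-of-sinusoids-plus-noise abstraction, not
a hemodynamic ODE. The downstream object of study is statistical
structure (moving correlations, autocorrelation, stationarity), and that
structure is fully determined by:

- a cardiac sinusoid at `cardiac_freq` (default 1.2 Hz ≈ 72 bpm) with
  amplitudes `cardiac_amp_abp` = 20 mmHg and `cardiac_amp_icp` = 2 mmHg
  (physiologic pulse-pressure scale);
- a band-limited slow-wave process `s(t)` — a random-phase sum of 8
  sinusoids confined to `slow_wave_band` (default 0.005–0.05 Hz, the
  vasogenic-oscillation band), total amplitude `slow_wave_amp` = 5 mmHg;
- an autoregulation coupling gain `g ∈ [−1, 1]` transmitting the
  arterial slow wave into ICP with attenuation κ = 0.5: `g = +1` is
  fully pressure-passive (PRx → +1 downstream), `g = −1` is active
  counter-regulation, `g = 0` decouples the signals. The cardiac
  components of ABP and ICP are independently phased, so the coupling
  acts on the slow-wave band only — which is exactly the band that 10-s
  averaging retains;
- rSO₂ channels following the slow-wave component of CPP with gain
  `rso2_gain·sign(g)`, PbtO₂ as a slow Gaussian drift, and independent
  Gaussian noise per channel (defaults: 1.0 mmHg ABP, 0.5 mmHg ICP,
  0.3 % rSO₂, 0.5 mmHg PbtO₂).

Baselines default to cohort-typical values (MAP 86.9, ICP 11.9 mmHg).
The default sampling rate is 50 Hz — desk-scale, with the cardiac
harmonic far inside Nyquist; configs with `sampling_rate < 4·cardiac_freq`
are rejected. Declared gap runs are written as NaN in every channel.

Covariates (sex, age, hypoxia, hypotension, pupillary response, Marshall
CT class) are drawn from marginal frequencies typical of a large
multi-centre moderate-to-severe TBI cohort (78 % male, median age ≈ 38 y,
~50 % bilateral reactive pupils, ~30 % Marshall ≥ 5). `subgroup_effects`
maps a covariate level to parameter offsets (or a `noise_sd_scale`
multiplier), giving subgroup tests a known ground truth.

Pure ARIMA test series are generated from the stationary/invertible ARMA
recursion (validated via the AR/MA polynomial roots) with a burn-in of
`max(20, 10·(p+q))` samples, then integrated `d` times.

What the generator does **not** emulate: ICP waveform morphology
(P1/P2/P3 peaks), drainage artifacts, non-Gaussian artifact bursts,
heart-rate variability, or nonstationary coupling. Passing tests
therefore demonstrate that the pipeline recovers known statistical
structure, not that it is robust to every artifact of bedside data.

## Index derivation

All waveform channels are reduced by a 10-s non-overlapping mean over
half-open frames `[t, t+10)`; a frame containing any missing sample is
NaN. The ICP pulse amplitude AMP is computed per 10-s frame by discrete
Fourier transform after demeaning: AMP is the sinusoidal amplitude
`2|X_k|/N` of the largest component in a configurable cardiac band
(default 0.66–3 Hz ≈ 40–180 bpm), so a pure tone of amplitude A yields
AMP = A exactly. CPP = MAP − ICP elementwise.

CVR indices are moving Pearson correlations over 30 consecutive 10-s
means updated every minute: PRx (ICP~MAP), PAx (AMP~MAP), RAC (AMP~CPP),
RAP (AMP~ICP), COx (rSO₂~CPP) and COx-a (rSO₂~MAP) per hemisphere —
COx-a reuses the MAP series as the arterial input. Windows are
right-aligned (the value at minute t uses the 300 s ending at t); a
window containing any NaN, or with zero variance in either member,
yields NaN rather than a reduced-n correlation, so the effective window
length never varies silently. Raw signals reach 1-min resolution as the
mean of their six 10-s means. Indices are emitted only when both
channels of the pair exist; partial monitoring leaves NaN columns.

## Resolution ladder and missing data

The ladder is fixed at {1, 5, 10, 30, 60, 120, 180, 240, 300, 360, 720,
1440} minutes. At 1-min resolution, interior missing runs of ≤ 4 points
are linearly interpolated; runs of ≥ 5 points split the series into
separate contiguous segments (a run of exactly 5 is excluded — the
conservative reading of an interpolate-under-five rule), and leading or
trailing runs are trimmed rather than extrapolated. Gap handling happens
once, at 1-min scale, before any reduction. Coarser values are
non-overlapping block means within a segment; a block is emitted only if
at least 50 % of its expected points are present, and the trailing
partial block is dropped. Downstream fits use the longest segment by
default. Sufficiency thresholds: ≥ 30 points for stationarity tests,
≥ 50 for the grid search; insufficient cells are labelled NA.

## Stationarity

ADF (unit-root null) runs with a constant-only regression and AIC lag
selection; KPSS (level-stationarity null) uses the Bartlett-kernel
long-run variance with automatic Newey–West bandwidth. Both use
α = 0.05; KPSS p-values are interpolated from the standard table and
bracketed to [0.01, 0.10], so its rejection flag compares the statistic
to the 5 % critical value directly. Cohort percentage tables are
labelled by the KPSS outcome alone; the two-test agreement flag (ADF
retains AND KPSS rejects) is recorded as the classical differencing
trigger. The pipeline nevertheless applies first-order differencing
universally before the grid search — on these data nearly every signal
at fine resolutions is non-stationary, and a uniform pre-difference
keeps the grid comparable across cells — so the flag is reported, not
acted on per-cell.

## ARIMA grid search

The grid covers p ∈ 1..10, d ∈ {0, 1}, q ∈ 0..10 (220 cells) on the
pre-differenced series, so the reported total integration order is 1 or
2. p deliberately starts at 1, leaving pure-MA models unreachable unless
the caller widens the range. A constant is estimated only for within-fit
d = 0; under differencing a constant would encode a deterministic drift
that is not part of the model class. Fits are exact maximum likelihood
(statsmodels state-space ARIMA). Failed or non-converged cells are kept
with +∞ criteria (−∞ log-likelihood) so grid completeness is auditable,
and they never win selection. Selection minimizes AIC or BIC or
maximizes LL, breaking ties toward smaller p+q, then smaller p.
Population summaries take component-wise medians of the per-patient
optimal orders, flooring half-point medians to the simpler order, next
to the median criterion value. Residual diagnostics report ACF/PACF of
the raw series and of the residuals with a ±1.96/√n band and the
proportion of significant lags before/after modelling; an adequate fit
shows a pronounced reduction. Parallel grid execution (joblib) preserves
the serial record order and yields identical numbers.

## Subgroup comparisons

For each signal × grouping × metric cell: Shapiro–Wilk gates at
α = 0.05 per group (n < 3 counts as non-normal). Two-level groupings use
a pooled-variance two-sample t-test when both groups pass, else a
two-sided Mann–Whitney U — exact when min(n₁, n₂) ≤ 8 and tie-free,
otherwise the tie- and continuity-corrected normal approximation. The
three-level pupil grouping uses one-way ANOVA vs Kruskal–Wallis. Age is
dichotomized at 40 (≥ 40 upper), Marshall at 5 (≥ 5 upper). No
multiple-testing correction is applied by default, matching the raw
0.05-per-cell convention of this literature; a Benjamini–Hochberg column
is available by flag. A Welch t-test variant is likewise available.

## Forecasting

One-step-ahead forecasting fixes the selected (p, d, q); coefficients
are estimated once on the leading half of the series (train fraction
0.5 by default) and then frozen while the Kalman filter advances through
the held-out tail, emitting each prediction before its observation
enters the state. This fixed-coefficient filter-forward scheme is the
default because it is deterministic and fast; per-step re-estimation is
available by flag and agrees closely on smooth series. Agreement is
summarized by Pearson r and Bland–Altman statistics of
`forecast − observed`: mean difference and limits of agreement
mean ± 1.96·SD (sample SD). r and the limits are always computed on the
same paired set.

## Pipeline and reproducibility

`run_pipeline` executes the stages in order, isolating failures per
patient × signal × resolution cell (logged, never fatal). All tables are
CSV: comma-separated, UTF-8, ISO-8601 timestamps, empty cell = missing,
one `#` comment line naming the stage, config hash and seed. The
manifest records the config, its hash (excluding output location and
worker count, which cannot affect any value), the seed, the package
version, and a SHA-256 per output file; a rerun with the same config is
byte-identical. Per-cell fit wall times are inherently non-reproducible
and are therefore written to `*_timings.csv` sidecars excluded from the
manifest's hash set. Waveform CSVs (tens of MB at 50 Hz) are written
only on request; simulate → derive otherwise passes records in memory.

## Validation experiments and problem sizes

The validation suite (`cvrarima.benchmarks`, exercised by the test suite
and `scripts/acceptance.py`) uses desk-scale problem sizes chosen so the
full battery runs on one CPU in minutes: order recovery on ARIMA(2,1,2)
series (φ = (0.5, −0.3), θ = (0.4, 0.2), σ = 1, n = 3000) over a
p ≤ 5, q ≤ 5 grid; stationarity calibration on 100 random walks and 100
iid Gaussian series of n = 1000; subgroup type-I calibration on 200 null
cohorts of 40 patients whose metrics are drawn under a global null (per-
patient metrics come from single cheap fixed-order fits rather than full
220-cell grids, which would be computationally prohibitive at replicate
scale — the test-statistic path itself is exercised in full); power
against a +50 % noise-SD Marshall effect with 20 patients per stratum;
and a 3–5-patient end-to-end determinism run with a reduced grid
(p, q ≤ 3) at resolutions {1, 60, 1440} min, where the coarse rungs
correctly return NA for short recordings.

## Known limitations

- The simulator's linear, stationary coupling cannot probe the
  pipeline's behaviour under regime changes (e.g. decompensation).
- Exhaustive 10×2×11 grids at cohort scale are expensive; the supported
  mode for large runs is a reduced grid plus the ladder's coarser rungs.
- KPSS p-values are interval-censored by the critical-value table;
  inference at α other than the tabulated levels should use the
  statistic and critical values directly.
- The Mann–Whitney exact path requires tie-free data; with ties the
  corrected normal approximation is used even for small samples.
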