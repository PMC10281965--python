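# Methods

## Overview

`pentrace` analyzes single-stroke stylus tracings of three guide shapes
(spiral, square wave, triangular wave) recorded on a consumer tablet at
a nominal 120 frames/s with stylus pressure in device units on
[0, 4.166667]. Per tracing it extracts drawing time (DT), average
pressure (AP) and SPARC pressure smoothness (SP); per cohort it runs
two-group comparisons and seven shape-combination SVM screening models
under leave-one-out cross-validation (LOOCV). Because the clinical
recordings the design is based on are not publicly archived, the
package includes a generator of surrogate cohorts calibrated so that
the *extracted* features reproduce the published per-group, per-shape
medians and IQRs (66 controls, 38 cervical-myelopathy participants).

## Feature extraction

**Resampling.** Pressure is linearly interpolated onto a uniform grid
at the device rate (120 Hz) from the first to the last contact sample;
device-rate data pass through unchanged. DT is taken from the raw
timestamps (`t_last − t_first`); AP is the arithmetic mean on the
uniform grid (= time-weighted mean).

**SPARC.** The spectral arc length of the pressure signal: with
magnitude spectrum `V(f)` on an FFT grid of length
`2^(ceil(log2 n) + pad_level)` and `V̂ = V/V(0)`, the cutoff is
`f_c = min(f_c_max, max{f_k : V̂_k ≥ ε})` and the result is the negative
polyline arc length of `V̂` over the bins up to `f_c`. Defaults:
`pad_level = 0`, `f_c_max = 10 Hz`, `ε = 0.03`, frequency counted in
*bins* (unit step per spectral bin, `freq_scale="bin"`). Two
alternatives are selectable: `"hz"` (frequency in hertz) and
`"normalized"` (the canonical dimensionless metric, frequency scaled by
the cutoff, values typically −1.4 … −6).

The bin-scaled default needs justification, because the canonical
metric is dimensionless. Published pressure-smoothness values for this
task family lie between −34 and −129, with spiral magnitudes about
twice those of the waves and spiral tracings taking about twice as
long. Only an arc length whose frequency extent scales with the number
of spectrum bins — i.e., with recording length at fixed spectral
resolution — reproduces both the magnitude (a 9.5 s tracing has a
2048-point FFT; a cutoff near 6 Hz gives ≈ 6 × 2048/120 ≈ 102 bins)
and that duration scaling; it also explains very wide reported IQRs as
the FFT length doubling at the 8.53 s boundary. The canonical
normalized variant (≈ −1.4 … −6) and a Hz-scaled variant (bounded by
`f_c_max` + total variation ≈ −12) cannot reach that scale for any
physically admissible pressure signal. Pressure mode requires a
nonzero-mean signal (DC normalization); a `pressure_derivative` mode is
provided because "smoothness of the pressure change" is ambiguous
between the signal and its derivative.

The threshold ε = 0.03 (rather than the 0.05 common for velocity
profiles of reaching movements) keeps the tremor amplitude needed to
reach the calibration targets small enough that fewer than 1 % of
simulated pressure samples touch the device limits; the cutoff
parameters of the original analysis are not recoverable from the
published values.

## Synthetic cohorts

Each participant×shape tracing is generated as:

* **trajectory** — constant arc-length speed along the template
  polyline plus low-pass (8 Hz) positional tremor of 1.5 pt RMS. The
  trajectory is deliberately simple: no analysis feature uses it.
* **pressure** — synthesized in the log domain around a personal
  baseline `P₀`: `P(t) = P₀ · g(s(t)) / mean(g(s))`, with
  `g(s) = exp(s)` for `s < 0` and `1 + s` for `s ≥ 0` (floor-safe
  downward, bounded upward, C¹ at 0), where `s(t)` is a slow sinusoidal
  drift (period = stroke duration, relative amplitude 0.12) plus
  "roughness": 12 sinusoids on a log-spaced frequency comb spanning
  2.5–13 Hz with ±8 % log jitter, amplitudes ∝ 1/f, random phases, and
  a participant-specific total relative RMS. Normalizing `g` to unit
  time-mean makes AP equal `P₀` exactly; multiplicative (signal-
  dependent) noise keeps light pressers clear of the device floor.
  Anything escaping [0, 4.166667] is clipped and counted
  (`meta["clipped_samples"]`); calibration rejects parameter sets that
  clip more than 1 % of samples.

**Population model.** Durations, baseline pressures, and relative
roughness are log-normal, parameterized by (median, IQR) — positive
support and right skew consistent with the published asymmetric IQRs.
DT and AP generative medians equal the published feature medians
directly; roughness medians were fitted by `calibrate_generator`
(below). The roughness log-dispersion is 0.20 by default; the latent
pressure and roughness are negatively coupled (r = −0.45):
lighter pressers fluctuate relatively more, the standard
signal-dependent-noise picture with a variability floor.

**Sampling design.** By default the generator draws the three latent
traits by *stratified quantiles on a fixed golden-ratio lattice*: each
trait takes exactly one draw per equal-probability stratum, and the
strata of different traits are aligned by fixed coprime-multiplier
permutations. Marginals are exact in distribution; what the seed
randomizes is the participant-to-stratum assignment, the position
inside each stratum, and all waveform-level noise (phases, comb jitter,
tremor). The point is fidelity at study size: a 38-participant group's
sample median then deviates from its target by ≪ 1 σ of the iid
sampling error (iid draws would make the published-median recovery a
coin flip at the stated tolerances). An `iid` mode retains plain
sampling with a shared per-participant factor producing mild positive
cross-shape correlation (0.4); in stratified mode traits are
independent across shapes. Demographics use exact counts: sex 38 F/66
and 15 F/38, CM severity 9 mild / 18 moderate / 11 severe (JOA scores
uniform within grade), ages normal around the published
medians/IQRs.

**Calibration.** `calibrate_generator` sets DT and AP medians directly
(one-to-one mapping) and fits each roughness median by monotone
bisection in log space against the extracted SP median of a simulated
calibration sample (study-size n, fixed seed, averaged over three
sub-seeds so the target is the *typical* cohort median). The search
brackets geometrically, verifies the decreasing SP–roughness response,
fails loudly on non-monotonicity, non-convergence, or > 1 % clipping,
and exits immediately when the incoming parameters are already within
tolerance (re-calibration is a fixed point). Shipped defaults were
produced by this routine at tolerance 5 %.

## Screening models

`enumerate_models` yields the 7 non-empty shape subsets (singletons,
pairs, full set; lexicographic within size). The feature matrix is one
row per participant, columns shape-major (DT, AP, SP per shape);
participants missing a required shape are dropped with a logged count.

LOOCV: for each held-out participant the remaining rows are
standardized (mean/SD of those rows only — leakage-free; zero-variance
columns get scale 1 with a warning), a soft-margin SVM is fitted
(default RBF kernel, bandwidth by the median-pairwise-distance
heuristic on the standardized training fold; linear selectable), and
the held-out signed decision value is recorded, oriented so larger =
more CM-like. A `global` normalization mode (scale once on the full
matrix) mimics the simpler pipeline many published analyses use without
saying so. Pooled out-of-fold scores give the ROC (thresholds at unique
scores, ties grouped, endpoints (0,0) and (1,1)), trapezoidal AUC
(equal to the tie-corrected rank statistic U/(n₁n₂)), and the operating
point minimizing the distance to (FPR 0, TPR 1), ties broken toward
higher sensitivity then higher specificity.

Hyperparameter tuning searches C ∈ {0.1, 1, 10, 100} in two labeled
modes: `paper_faithful` (default) maximizes sensitivity + specificity
of the full-LOOCV operating point over the grid — the selection
optimism this entails is intrinsic to tuning on the reported
cross-validation; `nested` selects C per outer fold by an inner LOOCV
for an honest estimate. `paper_faithful`'s objective is by construction
at least `nested`'s on the same data.

## Group statistics

Type-7 (linear interpolation) quantiles throughout. Mann-Whitney U is
reported as min(U₁, U₂); p-values are exact by enumeration for
tie-free samples with n₁ + n₂ ≤ 12, else the normal approximation with
tie and continuity corrections (at n = 6+6 the approximation tracks the
exact p within 0.01 for p ≤ 0.2, within 0.016 in the mid-range).
Chi-square defaults to Pearson without continuity correction (Yates by
flag); age uses the pooled-variance two-sample t. P-values are raw —
no multiple-testing correction, as in standard per-row clinical
tables — and flagged at α = 0.05.

## What passing tests do and do not show

The generator reproduces the published *marginal* feature summaries and
the device constants; it does not model practice effects, pen lifts,
tablet quantization, trajectory-error coupling, or the unknown real
correlation structure between features and shapes. Consequently the
screening models' absolute accuracy on synthetic cohorts reflects the
calibrated marginal effect sizes only: single-shape LOOCV AUCs land
near 0.60–0.70 and multi-shape models near 0.72–0.79, and the published
best-model AUC is not a target the synthetic route can or should
reproduce. Recovery tests (medians within 10 % DT/AP and 15 % SP at
study sizes) and the statistical-calibration and oracle tests are the
meaningful guarantees; a directional test additionally checks that the
triangular-wave model separates the groups better than chance —
note that at n = 104 its single-cohort 99 % bootstrap lower bound
sits near, and typically below, 0.5 given these effect sizes.

## Numerical and degenerate-input choices

* Recording round-trip precision: CSV floats at 12 significant digits.
* Gap tolerance for single-stroke validation: 3 nominal sample periods
  (tolerates dropped frames, catches pen lifts); multi-stroke
  recordings are rejected by default, `--keep-longest-stroke` salvages
  the longest contiguous segment with timestamps re-zeroed.
* Resampling grid: `floor(span·rate) + 1` points from `t₀`; the
  endpoint coincides with the last sample whenever the span is an
  integer number of periods (always true for device-rate data).
* SPARC needs ≥ 4 samples and a nonzero DC; an all-zero signal raises.
  Degenerate cutoffs (nothing above threshold beyond DC) return 0.
* Baseline pressure draws are capped at 0.6 × device max so the upward
  modulation cannot saturate the sensor for heavy pressers.
* LOOCV folds with a single class raise; the ROC requires both classes.
* Severity grading is a total partition of JOA 0–17; scores outside
  raise.

## Limitations

* All geometry (template sizes, start conventions) is a documented
  package default; true on-screen dimensions of the study guides are
  unpublished. Features never read the trajectory, so this cannot
  affect results.
* The SPARC parameterization that produced the published magnitudes is
  inferred, not documented; the mode flag and the calibration absorb
  the uncertainty, and the canonical form remains available.
* SP medians at study sizes remain the noisiest recovery target
  (±10–15 % seed-to-seed at n = 38) because the per-subject SP
  distribution is multi-modal (FFT-length tiers × cutoff comb).
* Velocity, tilt, and kinematic accuracy features are out of scope; the
  recordings retain coordinates so they can be added later.
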