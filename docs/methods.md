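# Methods

This note documents the models, numerical choices and known limitations of
`rrestim`, in the spirit of the methods documentation of statsmodels or
msprime: what is computed, under which assumptions, and what the tests do
and do not demonstrate.

## Signal model and simulator

Simulated records replicate a single analytic beat template at a target
heart rate for 210 s at 500 Hz. The ECG template is a sum of localised
Gaussian bumps (P, Q, R, S, T at fixed fractions of the beat, R dominant,
unit peak); the PPG template is a two-bump pulse (systolic peak plus
dicrotic shoulder) baseline-shifted to be non-negative. Beats are rendered
*by phase*: a sample's value is the template evaluated at its fractional
position inside the containing beat interval. Consequences worth knowing:

- FM stretches the entire beat, so beat-interval features (`xb3`), QRS
  duration (`xb7`) and pulse width (`xb10`) all respond to FM, as they
  should; the R wave sits at phase 0.30 of each interval rather than at
  the interval onset.
- AM multiplies the rendered train by `1 + depth·sin(2π·f_resp·t)`; BW
  adds `depth·sin(2π·f_resp·t)`. With `depth = 0` all three modulations
  reduce to the identical unmodulated train.

Parameters: heart rate 30–200 beats/min, RR 4–60 breaths/min, modulation
depth default **0.1** (10 % of beat amplitude for BW/AM, 10 % fractional
interval variation for FM — visible but physiological; no value is
standard, so one was fixed once and exposed as a parameter), modulation
phase 0 for determinism (a seeded random phase is available). The
verification sweep enumerates, per modulation, 35 settings (HR 30:5:200,
RR 18) plus 29 settings (RR 4:2:60, HR 80), rendered for both ECG and PPG:
192 settings, 384 waveforms. The sweep's HR and RR sweeps share the
(HR 80, RR 18) point; counts are kept per sweep.

The simulator emulates *ideal* periodic morphology. It contains no noise,
artifact, ectopy, or beat-to-beat morphology variation, so passing the
verification gate shows that a technique's machinery is implemented
correctly — not that it is robust on clinical data.

## Extraction

All techniques share preprocessing: zero-phase Butterworth high-pass at
4 breaths/min (order 2), low-pass at 100 Hz (ECG) / 35 Hz (PPG) (order 4),
50 Hz notch for ECG (Q = 30). Cutoffs are the design −3 dB points of the
one-pass filter; forward–backward application doubles the attenuation
without moving fiducials.

Respiratory signals are extracted **over the whole record and then
segmented** into adjacent 32 s windows. Filtering each window separately
was tried first and rejected: at 4 breaths/min the filter's settling time
is comparable to the window itself, and edge transients dominated the
spectrum of otherwise clean windows. The centred-correntropy technique is
the exception (below). All respiratory signals are delivered at a common
5 Hz, which makes the estimation stage identical across extraction
families and keeps AR(8) well-conditioned: at 500 Hz the whole 4–60
breaths/min band collapses into a sliver of the unit circle and pole
estimates degenerate.

Filter-based techniques run on a 25 Hz polyphase-decimated copy (cardiac
content extends to 3.7 Hz; decimation cuts the CWT and correntropy cost by
400× with no loss in the bands used):

- `xa1`: band-pass 4–60 breaths/min (final band-pass order 4 — at order 2
  the PPG pulse fundamental at ~1.3 Hz leaked through the 1 Hz edge and
  swamped the baseline wander).
- `xa2`/`xa3`: complex Morlet CWT (`cmor1.5-1.0`), 16 voices/octave over
  30–220 beats/min; per-sample ridge = argmax of |W| over scales; output
  is the ridge amplitude (`xa2`) or ridge frequency (`xa3`).
- `xa4`: centred correntropy `V(l) = mean_n κ(x[n] − x[n−l]) − mean_{i,j}
  κ(x_i − x_j)` with Gaussian kernel. The kernel bandwidth is the
  **standard deviation of the window**: a density-style bandwidth
  (Silverman) collapses to ~1 % of the signal SD on spiky cardiac
  waveforms, making the kernel sensitive only to exact matches of baseline
  samples, and the respiratory component vanishes. Lags span the analysis
  window (so ~9 respiratory cycles at 18 breaths/min are represented) and
  the lag function is linearly detrended before the respiratory band-pass.
  Because `V` is a lag function of the analysed span, `xa4` is recomputed
  per window rather than sliced from a record-level signal. On the
  idealised simulator it recovers RR from baseline wander on ECG; for AM
  and FM the respiratory information lives in the envelope of the
  beat-lag peaks and is weak at baseband — a known limitation here.

Feature-based techniques measure one value per detected beat. Beat
detection: Pan–Tompkins-style chain for ECG (5–15 Hz band-pass,
derivative, squaring, 150 ms integration, adaptive signal/noise
thresholds, R refined as the local waveform maximum); incremental-merge
segmentation for PPG (30 ms line segments merged by slope direction,
up-strokes accepted against an adaptive threshold of 0.5× the mean of the
last three accepted amplitudes, 0.27 s refractory, plus rejection of edge
pulses whose amplitude falls below 0.4× the median pulse amplitude —
truncated first/last pulses otherwise inject large feature outliers).
Trough convention is uniform: `trough[i]` immediately precedes `peak[i]`
(ECG: minimum within 0.10 s before R; PPG: minimum since the previous
peak). "Trough and proceeding peak" pairs (`xb1`, `xb2`) therefore pair
each trough with the peak that follows it.

Ectopic elimination: a beat whose preceding interval deviates more than
30 % from the running median of the ~10 surrounding intervals is
discarded together with the beat opening that interval. This is a
deliberately simple, testable stand-in for published rhythm-outlier
filters; the simulator produces no ectopy, so only the rule itself is
exercised. Surviving features are linearly interpolated onto a 5 Hz grid
spanning [first, last] beat time, high-passed at 4 breaths/min and
band-passed to 4–60 breaths/min (order 4).

`xb9` (kernel PCA) projects beat-centred segments (width = median beat
interval) onto the first principal component of an RBF kernel; the kernel
width is chosen on a 20-point log grid over [0.1, 10]× the median pairwise
segment distance by maximising (first eigenvalue − sum of the rest).
`xb10` (pulse width) measures max-upslope to min-downslope span per pulse;
it is implemented but excluded from the default algorithm set, as is the
lowest-frequency-pole estimator `ef5` (biased low outside ~12–20
breaths/min) — both fail the verification gate by construction of their
known failure modes.

## RR estimation

Spectral techniques report the frequency of maximum power within 4–60
breaths/min (ties break to the lowest frequency): `ef1` zero-padded FFT
(2048 points); `ef2` Burg AR(8) PSD; `ef3` element-wise median of Burg AR
PSDs for orders 2–20 on a common grid; `ef7` Welch with 3 half-overlapping
segments. `ef4`/`ef5` select among upper-half-plane AR(8) poles with
angles inside the band (highest modulus / lowest angle). `ef6` takes the
highest autocorrelation *local* maximum at lags corresponding to 4–60
breaths/min (quantisation at 5 Hz gives ~0.75 bpm granularity at 15
breaths/min). Time-domain techniques (`et1`–`et5`) follow their published
recipes literally; extrema are sign changes of the first difference with
plateaus taking the first sample; `et4`/`et5` detrend by least-squares
line removal and use linear-interpolation percentiles. `et4` averages the
durations of its valid peak-pairs (not the spacing between disjoint
pairs). Estimates outside 4–60 breaths/min, and estimates from constant
or too-short windows, are explicit no-outputs — absence is a value, not
an error.

## Quality gating and the reference

A 32 s window is usable when its rhythm is plausible (mean HR within
30–220 beats/min, no inter-beat gap > 3 s, max/min interval ratio ≤ 2.2)
and the mean Pearson correlation between beat-centred segments and their
average template exceeds 0.66 (ECG) / 0.86 (PPG). The thresholds are
configurable defaults in the spirit of the template-correlation quality
index; they were not re-derived from data here.

Reference RR from oral–nasal pressure: band-pass 4–60 breaths/min,
z-normalise within the window, count positive-gradient crossings of
`k = 0.42`, RR = 60 / mean inter-crossing interval. Windows whose 4–60
breaths/min band power fraction is below 0.25 are excluded as
unscoreable. `threshold_calibration` grid-searches `k ∈ [0.10, 0.90]`
(step 0.01) minimising 2·SD of detector-minus-annotation RR, ties to the
smallest `k`; it recovers the default exactly in a self-consistency test.

## Agreement statistics

The crossed random-effects model (subject intercept ν², shared replicate
effect ω², method×subject interaction τ², method-specific residuals σ²_m)
is fit by REML with the two method means profiled out by GLS. The
restricted likelihood is evaluated per subject-block (blocks sharing a
replicate count share one Cholesky factor), variances are optimised on the
log scale by L-BFGS-B with a Nelder–Mead fallback, started from
closed-form method-of-moments values. The moments estimator — per-cell
variances and cross-method covariances plus a one-way ANOVA on paired
differences — is retained as an independent oracle in the tests, never as
the reporting path. Non-convergence (optimiser failure, non-finite
estimates, degenerate tables: one subject, constant values) is a
reportable state that excludes the combination from ranking. Note that
ν² and ω² cancel in the paired difference, so bias and 2SD are driven by
τ² and the σ²_m alone; `2SD = 2·√(2τ² + σ²_ref + σ²_alg)`.

CP_δ is the empirical CDF of the absolute paired error at δ = 2
breaths/min, in percent. Ranking sorts on (2SD, |bias|) rounded to one
decimal, ties preserving input order. The ECG-vs-PPG comparison uses the
two-sided Wilcoxon signed-rank test, zero differences dropped, exact null
for ≤ 25 pairs and the normal approximation above.

## Problem sizes used by the test suite

- Verification gate: the sweep restricted to RR ∈ [8, 30] breaths/min with
  HR ≥ 2.2×RR (the beat train samples the modulation ≥ 2.2× per breath) —
  270 simulated waveforms, all 314 default algorithms, one 32 s window per
  waveform (t = 64–96 s). One window suffices because the gate consumes
  per-signal absolute errors; the full-record runner in
  `framework.run_algorithm` scores all six windows.
- Agreement recovery: 200 tables at the study's scale (39 subjects × 40
  replicate windows) drawn from the model itself; the suite asserts mean
  bias and mean 2SD within 10 % of the generating values.
- Breath-counting oracles: 1000 random 40 s smoothed-noise windows
  compared element-wise against literal re-implementations of the
  Count-orig/Count-adv pseudocode.

## Limitations

- The simulator's idealised morphology means gate results certify
  implementation correctness, not clinical performance; no claim is made
  about accuracy on real recordings, where artifact, ectopy and
  non-stationarity dominate.
- `xa4` recovers only the baseline-wander route reliably on idealised
  trains (see above); `fm1` (smart fusion) frequently withholds output on
  single-modulation simulated signals because the two unmatched feature
  signals estimate noise — mirroring its coverage/precision trade-off.
- The REML implementation assumes two methods per table (algorithm vs
  reference), which is the only shape the assessment protocol needs.
- I/O is CSV/JSON only; annotation and waveform container formats of
  bedside monitors are out of scope.
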