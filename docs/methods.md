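# Methods

This note documents the models and procedures implemented in `spindlekit`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data generator does and does not
emulate.

## Time and epoch conventions

All times are seconds from recording start.  Intervals are half-open
`[onset, offset)`; 30-s scoring epochs are 0-based, and an event ending
exactly on an epoch boundary belongs to the earlier epoch only.  Hypnograms
use the stage vocabulary {W, N1, N2, N3, R}; a hypnogram shorter than the
recording leaves the trailing samples unscored and excluded.  Recordings
sampled at 100 and 200 Hz are processed at their native rate — every window
and band definition is in seconds/Hz, so no resampling is performed.

## Band limiting

All analysis channels are band-passed to 0.3–30.0 Hz.  The general limit
(`recordings.bandlimit`) is a zero-phase (forward–backward) Butterworth,
order 4 per pass; zero-phase filtering preserves event timing for the
detector.  The σ pipeline applies its specified order-8 Butterworth stage
(`sigma.bandpass`), realized as order 4 per pass so the forward–backward
magnitude response is 8th order; a flag is not provided to run 8 per pass
because the σ band sits far from both edges and the difference is
negligible there.  EDF channels must be in µV or mV (converted); other
physical dimensions are rejected rather than guessed, since all powers are
reported in µV².

## Spindle detection

Sliding-window track (`detect.compute_power_s_track`):

- window length 1.0 s, step 0.2 s — five window starts per second.  Window
  starts lie on the 0.2-s grid within each scored epoch (150 per epoch) and
  a window may extend across the epoch boundary; restricting windows to fit
  inside their epoch would leave a 0.8-s blind gap at every boundary.
- per window, one-sided FFT power is summed over the spindle band
  10.0–16.0 Hz (inclusive edges; 1-Hz native bins at 1 s).  Spectra are
  normalized so a stationary sinusoid of amplitude A sums to A²/2 over its
  band (window-power normalization), making power S a µV² quantity.
- the per-epoch reference is the 30th percentile of power S over the
  windows of the containing 30-s epoch (all windows, not only artifact-free
  ones; configurable).  Epochs with a zero reference (e.g. flat signal)
  have their windows marked invalid and excluded rather than propagating
  NaN.  α and β tracks use the same construction against their own 30th
  percentiles.
- **window taper: rectangular by default.**  No taper is named for the 1-s
  detection FFT in the source description.  A Hann taper here attenuates a
  burst near the window edges, which shortens the supra-threshold run of a
  0.5–0.8 s spindle below the five-consecutive-window rule and costs
  roughly ten sensitivity points on ground-truth simulations; the
  rectangular window keeps a burst's band power high wherever it sits
  inside the window.  `DetectorConfig.window_taper="hann"` restores the
  tapered variant for leakage-sensitive use.

State machine (`detect.detect_candidates`):

- onset: first window of a run of ≥ 5 consecutive valid windows with
  ratio > 3.
- termination: scanning forward, the event ends at the first window whose
  power S falls below max(1.5 × reference, 0.20 × running peak power S) —
  the "whichever is higher" of the two published thresholds.  The binding
  criterion is recorded per event.  The event offset is the end time of the
  terminating window.
- horizon: if no such window ends within 5 s of onset the candidate is
  discarded and scanning resumes.
- merging: a run that resumes at or immediately after the terminating
  window (index gap ≤ 1) continues the same burst and is merged.  Runs
  beginning later are distinct events; merging on event *offsets* (which
  include the 1-s window tail) would fuse a spindle with an adjacent α
  burst a second away and lose both to the α-rejection rule.

Rejection (`detect.reject_candidates`): a candidate is deleted if it
overlaps any arousal interval (any overlap, configurable to full
containment), or if its mean power-S ratio over the event's windows is
below the corresponding mean α or β ratio (mean aggregation; max available
behind a switch), and events whose midpoint lies outside N2 are excluded.
The α and β bands are not defined in the source description; they are set
to [7.5, 10.0) and (16.0, 25.0] Hz — flanking the spindle band without
overlap — and are configurable.

Characterization: peak power S is the maximum window power inside the
event; peak frequency is the maximal spectral bin of the peak window,
zero-padded ×4 (0.25-Hz bins at 1 s) and restricted to 10–16 Hz; fast
spindles have peak frequency ≥ 12.0 Hz (inclusive lower edge).  Metrics:
density = events ÷ N2 minutes exactly; mean frequency/power are means of
event peaks; fast percent = 100 × fast ÷ all; all computed per channel and
averaged over the two central derivations.  Zero N2 minutes raises an
error — an undefined density is flagged, never silently zero.

## σ power

Per 30-s epoch, 22 Hann windows of 2.56 s at a 1.28-s step ("approximately
half" overlap implemented as exactly half) are FFT'd; per-window one-sided
power, window-power normalized, is averaged uniformly into one spectrum
with bin spacing 1/2.56 s = 0.390625 Hz.  The σ band sum includes both
edges: the printed limits 11.33/14.84 Hz are the rounded frequencies of
grid bins 29 and 38 (29 × 0.390625 = 11.328, 38 × 0.390625 = 14.844), so
membership is resolved by nearest-bin index — a strict inclusive-center
test would wrongly drop bin 29.  For a unit-amplitude in-band sinusoid the
spectrum sums to its variance, 0.5 µV² (Parseval with Hann normalization).

Artifact handling is a deliberately simple, configurable stand-in for the
unspecified original procedure: an epoch is rejected when its peak absolute
amplitude exceeds 250 µV or when it intersects an annotated artifact
interval.  An ECG-interference correction hook exists
(`SpectralConfig.ecg_correction`) and defaults to the identity.  "Adjusting
for rejected epochs" is read as averaging σ band power over *accepted*
N2+N3 epochs only (an intensity independent of record length, in µV²), then
averaging C3 and C4.  Zero accepted NREM epochs raises an error.

## Trajectory statistics

- **Degree selection**: the cubic model (with quadratic and linear terms)
  is fitted first; if the cubic term is not significant at α = 0.05 the
  quadratic is refitted, then the linear, which is kept regardless.  Lower
  order terms are always retained.  Covariates: sex, race/ethnicity, BMI,
  AHI, psychiatric/learning-disorder flag and PSG system (nominal).
- **Mean curves** use marginal standardization: each subject's covariate
  row is evaluated at the target age and predictions averaged.  The
  averaged design row is linear in the coefficients, so the pointwise 95 %
  CI is the t-interval with variance x̄ᵀ·Cov(β̂)·x̄.  Extrapolation beyond
  ages [6, 21] is refused.  Extrema of the predicted curve come from the
  real roots of the age-polynomial derivative compared with the endpoints,
  reported to 0.1 year.
- **Piece-wise β_s** divide the outcome by its SD over the full analysis
  sample (once, not per segment, so slopes are comparable across segments)
  and fit covariate-adjusted linear models within the whole-year segments
  6–10, 11–14, 15–17, 18–21 (membership by floor(age)).
- **Group contrasts** (sex; Tanner 1–3 vs 4–5) are ANCOVA within an age
  group; adjusted means by the same marginal standardization, contrast
  p-value from the stratum coefficient (joint Wald test when > 2 strata).
  Longitudinal percent-change models additionally adjust for the baseline
  outcome value and the length of follow-up.  Percent change is
  [(follow-up − baseline)/baseline] × 100; rows with a zero baseline are
  excluded and counted.
- **Lin's ρ_c** uses n−1 variance denominators and the Fisher-z standard
  error of Lin (1989) for the 95 % CI.  ρ_c ≤ |r| always, with equality iff
  means and variances match.
- No multiple-testing correction is applied by default (none is part of
  the modelled procedure).

## Synthetic data

The EEG generator emulates central-derivation staged sleep EEG:

- background: white noise spectrally shaped to PSD ∝ f^(−slope)
  (default slope 1.0), rescaled to a target RMS (default 10 µV) —
  plausible for band-limited pediatric central EEG.
- spindles: sinusoid × raised-cosine (Hann) envelope, centre frequency
  uniform on 11–15 Hz, duration uniform on 0.5–2.0 s, 30 µV peak envelope
  (3× background RMS, a clearly expressed spindle), placed by a
  homogeneous Poisson process at 4/min within N2 epochs with overlap
  rejection.  The clean spindle-only component is returnable, so every
  embedded event is recoverable by direct envelope thresholding — an
  oracle independent of the detector.
- contaminants: 8–9.5 Hz α bursts (0.5/min, any stage), annotation-only
  arousals (4/h) and 500 µV slow movement transients (4/h).
- both channels (C3-M2, C4-M1) share the event sequence over independent
  backgrounds, approximating the bilateral synchrony of central spindles.

Not emulated: K-complexes, REM phasic activity, respiratory/EMG channels,
ECG leakage, within-night stage cycling beyond the configured block
sequence, and physiologically calibrated Tanner timing.  Passing tests on
these simulations therefore demonstrate algorithmic correctness and
parameter recovery under controlled conditions, not clinical-grade
performance on real recordings.

The cohort generator draws ages uniformly (cross-sectional default
n = 572 over 6–21 years; longitudinal default n = 332 pairs, baseline
5–12 years, follow-up interval 6–13 years capped at age 22), sex with 48 %
female, and covariates (BMI percentile, AHI, disorder flag, PSG system)
from simple parametric families.  Tanner stage follows an ordered-logit
ladder in age whose midpoint is 1.5 years earlier in females, the canonical
direction of pubertal timing.  Outcomes are polynomial(age) + optional sex
and covariate effects + Gaussian noise; the default trajectories give
spindle density and σ power inverted-U quadratics peaking at 15.2 and
13.0 years, a linear rise in frequency, a linear decline in power, and a
fast-percent quadratic peaking at 19.3 years, with noise SDs chosen so the
age terms explain roughly 10–30 % of outcome variance — magnitudes typical
of developmental EEG cohorts.  The true generating parameters are returned
alongside every table for recovery tests.

## Problem sizes and numerical choices

Validation suites run at sizes chosen to estimate each quantity stably
while staying desk-scale: detector-oracle agreement on 1 000 random
200-window tracks; detection performance pooled over ten 30-min all-N2
recordings (arousal/artifact rates 0, so that a spindle correctly deleted
for overlapping an arousal is not scored against the detector); parameter
recovery over 100 cohorts of n = 500; null calibration over 500 replicates
of n = 160.  Tolerances in tests reflect estimator noise (e.g. Parseval
within 3 % for a non-bin-centred tone under Hann leakage; filter checks on
the steady-state core away from edge transients).  EDF output quantizes to
16 bits over each channel's observed range; round-trip error is bounded by
one quantization step.  All randomness flows from a single integer seed
through one `numpy` Generator per simulation; identical seed and config
give bit-identical output.

## Known limitations

- The artifact-rejection and ECG-correction procedures of the original
  processing chain are unspecified; the amplitude-threshold criterion and
  no-op hook here are explicit, documented stand-ins.
- Slow/fast spindle-specific density, power and peak frequency are out of
  scope, as is topographic (frontal) analysis and automatic staging.
- Longitudinal modelling is restricted to two-wave percent change; no
  mixed-effects growth curves are fitted.
- The detector's five-window rule implies a minimum detectable burst of
  roughly 0.5 s at high SNR; shorter or low-SNR spindles are missed by
  construction.
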