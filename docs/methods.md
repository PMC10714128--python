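# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of plvloop.  Everything quantitative stated here is
computed by the test suite or the example scripts; nothing is quoted from
external data.

## Scope and design

The package simulates and analyzes a closed-loop EEG–TMS experiment in
which single pulses are triggered on the single-trial phase-locking value
(stPLV) between the C3- and C4-Hjorth signals.  It deliberately excludes
hardware concerns (stimulator control, device firmware, neuronavigation,
audio masking): real-time behavior is represented by its *timing
semantics* (poll cadence, minimum ISI, timeout, post-pulse blanking, and a
configurable trigger latency, default 85 ms, reflecting the 80–90 ms
delivery delay of a PC-in-the-loop setup).  Module boundaries mirror the
processing stages: `synth` (generator), `spatial` (Hjorth montages),
`phase` (edge-of-window estimation), `connectivity` (stPLV family), `loop`
(trigger engine), `emg` (response variable), `analysis` (statistics and
diagnostics), `io`/`edf`/`cli` (formats and plumbing).

## Synthetic data generator

The generator is the package's test surface, so its choices matter:

* **Coupled phase oscillators.** The two μ sources are noisy constant-
  frequency rotators (defaults 10 and 12 Hz); source 2's phase is pulled
  toward `phase1 + coupling_lag` with strength κ (rad/s):
  `dθ₂ = 2πf₂ dt + κ sin(θ₁ + lag − θ₂) dt + σ dW`.  Any generator with
  tunable phase-difference consistency would do; the Kuramoto-style pair is
  the simplest with a planted, monotone κ → stPLV relationship (verified:
  median window stPLV rises monotonically over κ ∈ {0, 0.5, 1, 2, 5}).
  The 2 Hz default detuning makes *uncoupled* 500 ms windows sweep one full
  phase-difference cycle, so their stPLV is properly low; a 1 Hz detuning
  would alias to |sinc(½)| ≈ 0.64 and is worth avoiding in custom configs.
* **Phase noise σ = 0.25 rad/√s.** A deliberately clean oscillator: the
  phase diffuses by only ~4° over the estimator's 0.13 s forecast horizon,
  so phase-estimation accuracy is limited by noise, not by the generator.
  Real μ rhythms have effective linewidths near 1 Hz (σ ≈ 1–2), for which
  edge-of-window estimation is substantially worse; synthetic accuracy
  figures are therefore upper bounds for real data.
* **Arch shape.** Non-sinusoidal μ is modeled as a phase-locked second
  harmonic scaled by `waveform_asymmetry` (power ratio `asymmetry²`,
  verified spectrally).  No quantitative description of μ asymmetry was
  available to calibrate against; the parameter is free.
* **Background noise and SNR.** 1/f^α noise (α = 1, RMS 10 μV per
  electrode) is synthesized by spectral shaping of white noise.  `snr_db`
  is defined exactly as the screening statistic: the Welch periodogram
  peak (2 s Hann segments, 0.5 Hz resolution) over a log-log line fitted
  through 2–45 Hz excluding 7–14 Hz, evaluated in 8–13 Hz.  The source
  amplitude is calibrated against a same-length noise realization so that
  a unit-gain electrode shows the requested peak height (round trip
  verified to ±2 dB).
* **What 5 dB means physically.**  With this definition a 5 dB peak
  carries total μ power ≈ (10^0.5 − 1)·ENBW·P_bg, against in-band (8–15 Hz)
  noise ≈ 7 Hz·P_bg — an in-band SNR of about −6 dB.  Instantaneous-phase
  error at in-band SNR ρ has a floor σ_φ ≈ √(1/2ρ), so ~20° RMS accuracy
  requires roughly a 25 dB peak, and at the 5 dB screening bar the
  estimator's error is necessarily large (measured ≈ 97° RMS).  This is a
  property of the definition, not of the implementation; the corresponding
  accuracy check in the acceptance suite documents the gap rather than
  hiding it.
* **Mixing and volume conduction.** Electrodes are a user-supplied gain
  matrix times the sources plus independent noise and optional 50 Hz line
  noise; there is no head model.  A common source mixed into both montage
  regions with positive gains produces locking angles concentrated at 0 —
  the diagnostic signature the analysis looks for.
* **MEP model.** `log MEP = intercept + b_fc·FC + b_powL·PowL + b_powR·PowR
  + b_isi·ISI + interactions + s·cos(φ + δ) + N(0, σ)`, amplitudes in μV
  (default intercept log 500).  The EMG trial renders the drawn amplitude
  as a damped biphasic wavelet centered 27 ms post-pulse (τ = 3 ms,
  120 Hz); only its peak-to-peak inside the 20–40 ms window is
  contractual.  Baseline EMG noise is 0.5 μV RMS; optional preinnervation
  is a sinusoid added to the pre-pulse segment of both muscles.
* **Trial tables for statistics.** `simulate_trial_table` generates
  response-scale data directly: 15 subjects × 900 trials by default, two
  sessions each, correlated left/right μ-power (r = 0.317), subject random
  intercept SD 0.05 and condition-slope SD 0.1.  Per-session z-scoring of
  real responses leaves almost no between-subject intercept variance,
  hence the small intercept SD; a slope SD comparable to the planted
  effect reproduces the observed minority of subjects with sign-flipped
  condition effects.
* **Reproducibility.** One global seed fans out into named substreams
  (sources, noise, sequence, EMG); full generation is bit-reproducible
  under a fixed seed.

## Real-time phase estimation

Pipeline per window (1 s at the 500 Hz working rate, band 8–15 Hz):
zero-phase FIR bandpass (order 128, forward–backward), trim 64 samples per
side, AR(30) via Yule–Walker (biased/MLE autocovariances — the stable
choice on short windows; the "unbiased" variant produces explosive
forecasts), forecast 128 samples, Hilbert transform, angle at the original
window end.  Phase convention: 0 at the oscillation's positive peak, ±π at
the trough.  Estimates are amplitude-invariant and covariant under time
shifts; constant windows raise an undefined-phase error rather than
returning a silent 0.  Resampling 5 kHz → 500 Hz uses a polyphase
anti-alias decimator.

## Post-hoc re-analysis chain

Pre-pulse windows are shifted 5 ms before the pulse to stay clear of the
stimulus artifact.  μ/α power: [−0.505, −0.005] s, linear detrend, raw
periodogram integrated over 8–13 Hz, log, z-scored within session within
subject.  Post-hoc phase: [−0.605, −0.005] s, detrend → zero-phase FIR
lowpass (order 50, 250 Hz) → decimation to 500 Hz → the phase estimator
with band 8–13.5 Hz and edge trim 48.  We do *not* apply a separate
order-200 band filter to the 300-sample window: a forward–backward FIR of
that order needs more padding than the window holds (MATLAB's filtfilt
rejects the combination outright) and rings across the whole window;
delegating the band filtering to the estimator's order-128 FIR keeps
clean-source errors below ~8°.  Post-hoc stPLV phases come from the
Hilbert transform of the filtered [−0.505, −0.005] s window, with the
filter edges trimmed and bridged by an AR forecast so the last phases are
not Hilbert-edge artifacts (a 0.6 s head of raw data absorbs the leading
transient).

## Trigger engine semantics

Decisions happen on a 100 ms poll grid (optional jitter).  The block start
is treated as a pseudo-pulse so the 8 s timeout clock is defined from the
start; the pseudo-pulse also enforces blanking, so the first poll is at
2 s.  Threshold comparisons are strict (`<` Q1, `>` Q3): ties do not
trigger.  Quartiles use linear interpolation between order statistics.
Every computed stPLV updates the FIFO *after* the comparison that used the
old criteria; no stPLVs are computed during the 2 s post-pulse blanking,
so the buffer can never contain a stimulation artifact.  Timeout pulses
carry no condition, no deciding stPLV and no phase window, and do not
advance the sequence.  An exhausted phase stream yields a flagged partial
result, never silent truncation.  The option
`skip_first_poll_after_pause` (default off) implements the stricter rule
of requiring a non-matching stPLV between pause and trigger, which removes
the short-ISI selection bias inherent in the default waiting scheme.

## Response processing

The moving median truncates its window at session edges (median over the
available part, option `edges="nan"` to drop instead); it runs per
session, matching the per-session z-score.  Preinnervated trials are
removed *before* the median so rejected trials cannot contaminate it.
Degenerate sessions (σ = 0 after de-drifting) get all-zero responses with
a warning.  The MEP window is half-open, (20 ms, 40 ms] — the boundary
choice moves the result by at most one sample.

## Mixed models and tests

Fits use restricted maximum likelihood with a random intercept and a
random slope on the condition-like predictor per subject (the continuous
stPLV/istPLV variants put the slope on that predictor).  AIC and
likelihood-ratio tests use maximum-likelihood refits.  Per-term Wald tests
follow the type-II convention: each term (or cosine/sine pair, tested
jointly with 2 df) is evaluated in the model containing all terms except
its higher-order relatives.  The Wald statistic is referred by default to
an F distribution with denominator degrees of freedom
`n_subjects − rank(subject-level design)`; the plain asymptotic χ²
reference (the convention of several published analyses) is available via
`wald_reference="chi2"` but is anti-conservative at 15 subjects — the
between-within correction keeps the simulated type-I rate at the planted
null within 5% ± 2.5% (500-replicate calibration in the acceptance
suite).  Convergence problems and boundary (singular) fits are recorded
on the result object, never masked.  Per-subject responder tests are
one-sided Wilcoxon rank-sum tests of high > low, reported unadjusted, as
is conventional for descriptive individual-level tables.

Circular predictors always enter and leave models as cosine/sine pairs,
including their interactions; a pair (a, b) is reported as amplitude
s = √(a² + b²) and phase shift δ = atan2(−b, a).  (The equivalent textbook
form `s = a / cos δ` is algebraically identical.)

## Diagnostics

The volume-conduction statistic is `mean cos(2·arg(cstPLV))` over trials:
1 when locking angles concentrate at 0/π, 0 under uniform angles, −1 at
±π/2.  It is a summary of the histogram the analysis also produces; the
2-D (φC3, φC4) histograms default to 12 × 12 bins over [−π, π)².  The
μ-SNR screening statistic is the Welch-periodogram peak height over the
fitted 1/f line described above; 5 dB is the inclusion bar.

## Problem sizes in the test suite

The suites run at the sizes the statistical claims need and no larger:
parameter recovery at 15 subjects × 900 trials × 100 replicates, type-I
calibration at 500 replicates, phase accuracy at 500 trials, loop
contracts over 100 seeded blocks, oracle equivalence over a 50-pulse
simulated session (the equalities checked are exact and size-independent),
and the uniform-disk law at 10⁶ samples.

## Known limitations

* No biophysical head model; mixing is an arbitrary matrix, so spatial
  realism is limited to what the user encodes in it.
* No TMS artifact waveforms in the EEG; post-pulse blanking is the only
  artifact semantics.
* The phase-diffusion oscillator is cleaner than real μ; passing phase
  tests here does not imply the same accuracy on real recordings.
* EDF interchange quantizes to 16 bits (exact for integer μV data; a
  float/JSON fallback is available for lossless storage).
* Streaming phase estimation at one estimate per sample is O(n) estimator
  calls and is meant for example-scale recordings; the loop engine itself
  operates on phase streams and is fast at session scale.
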