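# Methods

## Scope

`bcghr` implements four connected pieces: (i) a seeded generator of synthetic
tri-axial accelerometer traces carrying BCG-like heartbeat pulses with a
prescribed heart-rate profile; (ii) the HR estimation chain (detrend →
standardize → combine → band-pass → envelope → FFT peak search) with sliding
near-real-time windows; (iii) the heart-rate-biofeedback relaxation-session
state machine with its success thresholds and adherence aggregation; and
(iv) the trial's statistical utilities (noncentral-F power machinery and
effect-size conventions). Mixed-model fitting itself is deliberately out of
scope — any statistics ecosystem provides it — as are questionnaire scoring
and UI concerns.

## The synthetic signal model

Each heartbeat at time t_b contributes a causal exponentially damped sinusoid

    p(t) = A · exp(−(t − t_b)/τ) · sin(2π f_c (t − t_b)),   t ≥ t_b

with carrier f_c = 7 Hz, decay τ = 0.15 s and amplitude A = 0.02 m/s², chosen
so per-beat energy sits squarely in the 4–11 Hz isolation band. Beat times
are placed where the running integral of HR(t)/60 crosses successive
integers — this supports arbitrary time-varying rate profiles without
aliasing — and may be perturbed by iid Gaussian jitter (a crude stand-in for
heart-rate variability; 20 ms is the value used throughout the validation
experiments). The pulse train is projected onto a static unit orientation
vector; sinusoidal baseline drift and white noise are added per axis, and
optional Poisson-timed half-sine transients model motion artifacts (default
rate zero).

Noise defaults describe a modern phone resting still on the chest:

| parameter | default | rationale |
|---|---|---|
| drift amplitude | 0.05 m/s² | slow posture sway |
| drift frequency | 0.05 Hz | 20 s period; safely inside the stopband of the 2 s moving-average detrend (<2% residual). A drift frequency in the detrend's transition band (e.g. 0.1 Hz, ~6% residual) intermodulates with the pulse train through the nonlinear RSS and rectification stages and produces ±f_drift spectral sidebands — the generator invariant therefore requires drift below the detrend passband |
| white noise sd | 0.003 m/s² | ≈60 µg/√Hz MEMS noise density over the 25 Hz bandwidth |
| artifact rate | 0 / min | still subject |
| orientation | (0.199, 0.149, 0.966) | mildly tilted z-dominant attitude; see limitations |

Randomness uses one `numpy` Generator per call with a documented draw order
(drift phases, white-noise block, artifact times/axes), so identical
arguments and seed give bit-identical traces across versions.

What the generator does **not** emulate: real BCG waveform morphology (I/J/K
complexes), respiratory modulation of amplitude and rate, motion-artifact
structure beyond isolated bumps, sensor quantization, and timestamp jitter.
Passing the recovery tests therefore shows the chain is correct and robust
under plausible idealized conditions, not that it matches any deployed
product's field accuracy.

## The estimation chain

All filters are applied forward–backward (`scipy.signal.sosfiltfilt`), so no
stage introduces phase delay and event times feed the session engine
undistorted; a deployed app would use causal filters and accept the delay.
Stage parameters (all in `PipelineConfig`):

- moving-average detrend window 2.0 s — passes the cardiac band (>98%
  retained at 7 Hz) while removing sub-0.1 Hz drift;
- BCG isolation band 4–11 Hz, Butterworth order 2;
- envelope low-pass 3.0 Hz, order 2 — above the 2.5 Hz top of the search
  band;
- FFT search band exactly 0.66–2.5 Hz. Note 0.66 Hz is 39.6 bpm, not 45; the
  chain reports the Hz band faithfully and offers `clip_bpm` to restrict
  reported values to 45–150 bpm;
- windows: 20 s single-shot (0.05 Hz native resolution), 10 s streaming
  preset, 1 s hop; zero-padding ×4 plus three-point parabolic interpolation
  gives sub-bpm read-out;
- confidence: peak magnitude ≥ 3× the median in-band magnitude. Ties in the
  peak search resolve to the lowest frequency.

Axis combination is the per-sample root-sum-of-squares of the standardized
axes: deterministic and exactly invariant to axis permutation and sign flips
(the squared axes are summed in sorted order so permutation invariance holds
bit-exactly), unlike a principal-component projection whose sign is
arbitrary. Missing samples (NaN) are linearly interpolated up to 0.2 s;
longer gaps are an input error.

## Measured recovery performance

Constant-rate traces, 60 s at 50 Hz, default noise, tilted orientation,
20 ms beat jitter, 20 seeds per rate; MAE over confidence-flagged estimates:

| true HR (bpm) | 50 | 72 | 90 | 120 | 144 | pooled |
|---|---|---|---|---|---|---|
| MAE (bpm) | ≈2.2 | 0.18 | 0.18 | 0.20 | 0.59 | ≈0.67 |

The 50 bpm column is dominated by octave errors: ~4% of windows lock onto the
second harmonic (100 bpm) of the short-duty-cycle pulse envelope. This is
inherent to plain in-band spectral argmax — harmonic disambiguation is
deliberately not added, both to stay faithful to a single-peak FFT search and
because the peak-bin selection is pinned to the brute-force in-band argmax by
a test oracle.

## Session engine

Phase attribution is conservative: an estimate belongs to a phase only if its
trailing analysis window lies entirely inside that phase, so stress-phase
dips can never trigger relaxation success. With the default 10 s baseline and
10 s streaming window, the baseline maximum rests on a single estimate; if
that estimate is low-confidence the session is reported `invalid` rather than
guessed (a third status beside `completed`/`aborted`). "Maximum value at
baseline" is read literally as the maximum, not the mean, of baseline-phase
estimates; the alternative reading would only matter for baselines longer
than one window. Success comparisons are inclusive (≤), so an HR exactly
10 bpm below the stress maximum or exactly 2 bpm below the baseline maximum
counts. The relaxation phase is bounded by the initial 40 s block plus at
most two 20 s extensions (80 s); a series that ends before the protocol does,
without success, is `aborted` — this truncation semantics is what lets the
adherence aggregator distinguish started from completed exercises. Reported
percentages are rounded half-away-from-zero to two decimals, the convention
that reproduces all published cohort figures.

## Power machinery

The fixed-effects F-test convention: numerator df u = k − 1, denominator
df v = N − k − c, noncentrality λ = f²·N. This matches the G*Power family;
Cohen's-tables and chi-square-limit conventions differ in the third decimal.
Power is the noncentral-F survival function at the central critical value
(`scipy.stats.ncf`); the test suite cross-checks it against an independent
Monte-Carlo oracle (10⁵ noncentral-F draws per grid point, agreement within
0.01). A priori sample size scans N upward for the smallest integer reaching
target power and reports ceil(N/k) per group; sensitivity solves
power(f²) = target by bracketed root-finding to 10⁻⁶ in f².

Effect sizes: d = Δ/s_pooled with the bias-weighted pooled baseline SD;
group SDs may be reconstructed from reported standard errors via
sd = se·√n. The two-group conversion d = 2·√f² is implemented as the
standard convention; note that under it f² = 0.062 corresponds to d ≈ 0.50,
not to ≈0.21 as sometimes quoted alongside such sensitivity analyses — the
package reports the standard conversion.

## Numerical choices and degenerate inputs

- Beat placement integrates the piecewise-linear rate on a 1 ms grid
  (trapezoid; exact for linear segments up to crossing interpolation).
- Standardization maps an axis with sd < 10⁻¹² to all zeros instead of
  dividing by ~0.
- The parabolic peak offset is clamped to ±½ bin; band-edge peaks skip
  interpolation gracefully and bpm is clipped to the band.
- CSV round-trips are lossless: pandas shortest-round-trip float formatting
  on write, `float_precision="round_trip"` on read; a sampling rate within
  10⁻⁶ of an integer is snapped to it to avoid timestamp round-off dust.
- Unknown YAML config keys are rejected (fail fast), not ignored.

## Known limitations

- Exact axis alignment of the device (orientation on a coordinate axis) is a
  degenerate worst case: the two pulse-free axes are standardized up to unit
  variance and contribute pure noise to the RSS combination (measured ~2.6 bpm
  MAE at 72 bpm versus 0.18 bpm for a generic tilt). Real placements are
  never exactly aligned; synthetic experiments should use a generic
  orientation.
- The 10 s streaming window trades accuracy and confidence for latency; at
  default noise a substantial fraction of streaming windows (and hence some
  whole sessions, via the single baseline estimate) are flagged
  low-confidence.
- Low rates near the band floor are exposed to octave errors (above); rates
  below 39.6 bpm or above 150 bpm are outside the search band by design.
- The damped-sinusoid pulse is a stand-in waveform; its parameters are not
  claimed to match any deployed app's detector, and no beat-to-beat (HRV)
  estimation is attempted — spectral windows measure average rate only.
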