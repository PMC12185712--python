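# bcghr

Heart-rate estimation from smartphone ballistocardiography (BCG), the
heart-rate-biofeedback relaxation-session protocol built on top of it, and the
supporting trial statistics (noncentral-F power analysis, effect-size
arithmetic, adherence aggregation).

When a phone rests on the chest, every heartbeat imprints a small oscillatory
wave packet (a few cycles in the 4–11 Hz band, ~0.02 m/s² peak) on the
accelerometer, riding on baseline drift and sensor noise. This package is for
researchers and engineers who want a transparent, testable reference for the
processing chain such mobile-health apps use, plus a seeded synthetic-signal
generator so everything can be validated against known ground truth without
access to device recordings.

## The estimation chain

For a tri-axial record a(t) = (aₓ, a_y, a_z) sampled at f_s (default 50 Hz):

1. **Detrend** — subtract a centered 2 s moving average per axis (removes
   baseline drift below ≈0.2 Hz).
2. **Standardize** — each axis to zero mean, unit variance (orientation and
   gain consistency).
3. **Combine** — per-sample root-sum-of-squares of the standardized axes,
   invariant to axis permutation and sign.
4. **Band-pass** — order-2 Butterworth, 4–11 Hz, applied forward–backward
   (zero phase), isolating the BCG wave packets.
5. **Envelope** — rectify, low-pass (order-2 Butterworth at 3 Hz), remove the
   mean: per-beat packets become a pulse waveform whose fundamental frequency
   is the heart rate.
6. **FFT peak search** — magnitude spectrum of the zero-padded (×4) window;
   the peak in 0.66–2.5 Hz, refined by three-point parabolic interpolation,
   gives HR = 60·f_peak bpm (0.66–2.5 Hz ↔ 39.6–150 bpm; an optional clip
   restricts reports to 45–150 bpm).

Sliding trailing windows (20 s single-shot, 10 s streaming, 1 s hop) give a
near-real-time HR series. A biofeedback session then runs baseline (10 s) →
stress imagination (40 s) → relaxation (40 s, extendable twice by 20 s);
relaxation succeeds when HR ≤ stress-phase max − 10 bpm or ≤ baseline max
− 2 bpm.

The trial utilities compute fixed-effects F-test power from the noncentral-F
distribution with noncentrality λ = f²·N (a priori sample size and post hoc
sensitivity f²), Cohen's d from baseline-pooled SDs, and cohort adherence
percentages.

## Worked example

```sh
$ bcghr simulate --fs 50 --seed 7 --out demo.csv      # 60 s at 70 bpm (default profile)
$ bcghr estimate --in demo.csv --out demo_hr.csv
$ head -3 demo_hr.csv
time_s,bpm,peak_magnitude,confident
20.0,70.67848768094647,30.254087025262397,1
21.0,70.29867411300864,25.01748924827207,1
```

The simulated trace carries a ground-truth heart rate of 70 bpm; across the
41 windows, the 33 confidence-flagged estimates average 70.24 bpm (sd 0.69,
worst deviation 1.9 bpm). The `confident` column marks windows whose spectral
peak stands at least 3× above the median in-band magnitude.

```sh
$ bcghr power sensitivity --u 2 --v 156 --alpha 0.05 --power 0.80
{
 "f2": 0.062,
 "f": 0.249,
 "d_two_group": 0.5,
 "N_total": 159
}
$ bcghr power apriori --f 0.25
{
 "N_total": 158,
 "n_per_group": 53,
 "u": 2,
 "v": 154
}
```

The first call answers "what is the smallest effect an N = 159 trial can
detect at 80% power?" (f² = 0.062); the second, "how many participants per
condition does a three-arm ANCOVA need to detect a medium effect f = 0.25?"
(53 per condition, 158 total).

A full in-memory session:

```python
from bcghr import (SessionProtocol, synth_session_trace, hr_series,
                   run_session, PipelineConfig)

trace, truth = synth_session_trace(SessionProtocol(), 70, 90, 68, seed=2)
series = hr_series(trace, PipelineConfig().streaming())
result = run_session(series)
print(result.status, result.success, result.success_time_s)
# completed True 75.0
```

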