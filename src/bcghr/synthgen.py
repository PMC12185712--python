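"""Seeded generator of synthetic tri-axial accelerometer traces with BCG-like pulses.

A ballistocardiogram recorded by a phone resting on the chest shows, at every
heartbeat, a short oscillatory wave packet (a few cycles around 4–11 Hz) riding
on slow baseline drift and broadband sensor noise, projected onto whatever
orientation the device happens to have.  This module synthesises such traces
from a prescribed heart-rate profile so the estimation pipeline can be tested
against known ground truth.

Pseudo-random stream order inside :func:`synth_trace` is fixed and documented
(drift phases, then white noise, then artifact times/axes) so that traces are
bit-stable across versions for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._errors import ConfigError, DomainError, InputError

__all__ = [
    "DEFAULT_ORIENTATION",
    "HRProfile",
    "PulseTemplate",
    "NoiseSpec",
    "AccelTrace",
    "make_hr_profile",
    "generate_beat_times",
    "synth_trace",
    "synth_session_trace",
]

_BPM_MIN, _BPM_MAX = 30.0, 220.0


@dataclass(frozen=True)
class HRProfile:
    """Piecewise-linear latent heart rate HR(t) in bpm over [0, T].

    ``breakpoints`` is an ordered list of (time_s, bpm) knots; evaluation
    between knots is linear interpolation and is defined exactly on
    [0, duration].
    """

    breakpoints: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.breakpoints) < 1:
            raise DomainError("profile needs at least one breakpoint")
        t = np.array([b[0] for b in self.breakpoints], dtype=float)
        r = np.array([b[1] for b in self.breakpoints], dtype=float)
        if t[0] != 0.0:
            raise DomainError("first breakpoint must be at t = 0")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise DomainError("breakpoint times must be strictly increasing")
        if np.any(r < _BPM_MIN) or np.any(r > _BPM_MAX):
            raise DomainError(
                f"breakpoint rates must lie in [{_BPM_MIN:g}, {_BPM_MAX:g}] bpm"
            )

    @property
    def duration(self) -> float:
        return float(self.breakpoints[-1][0])

    def rate(self, t) -> np.ndarray | float:
        """HR in bpm at time(s) ``t``; raises DomainError outside [0, T]."""
        ta = np.asarray(t, dtype=float)
        if np.any(ta < 0.0) or np.any(ta > self.duration + 1e-12):
            raise DomainError(
                f"profile evaluated outside [0, {self.duration:g}] s"
            )
        knots_t = np.array([b[0] for b in self.breakpoints])
        knots_r = np.array([b[1] for b in self.breakpoints])
        out = np.interp(ta, knots_t, knots_r)
        return float(out) if np.isscalar(t) else out

    __call__ = rate


@dataclass(frozen=True)
class PulseTemplate:
    """Per-beat wave packet: a causal exponentially damped sinusoid.

    amplitude * exp(-(t - t_beat)/decay_tau) * sin(2*pi*carrier_freq*(t - t_beat))
    for t >= t_beat.  The defaults place the packet energy squarely inside the
    4–11 Hz band the estimation pipeline isolates.
    """

    carrier_freq: float = 7.0  # Hz
    decay_tau: float = 0.15  # s
    amplitude: float = 0.02  # m/s^2

    def __post_init__(self) -> None:
        if self.decay_tau <= 0:
            raise ConfigError("decay_tau must be positive")
        if self.amplitude < 0:
            raise ConfigError("amplitude must be nonnegative")
        if self.carrier_freq <= 0:
            raise ConfigError("carrier_freq must be positive")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive disturbances: slow sinusoidal drift, white noise, rare transients.

    Defaults emulate a modern phone resting still on the chest: 0.05 m/s^2
    posture-sway drift at 0.05 Hz (a 20 s period, safely inside the stopband
    of the 2 s moving-average detrend), white sensor noise of 0.003 m/s^2 rms
    (a ~60 ug/sqrt(Hz) MEMS accelerometer integrated over the 25 Hz
    bandwidth), and no motion artifacts.
    """

    drift_amplitude: float = 0.05  # m/s^2
    drift_freq: float = 0.05  # Hz, must stay below the pipeline's detrend passband
    white_sd: float = 0.003  # m/s^2
    artifact_rate: float = 0.0  # events per minute
    artifact_amplitude: float = 0.0  # m/s^2

    def __post_init__(self) -> None:
        for name in ("drift_amplitude", "drift_freq", "white_sd",
                     "artifact_rate", "artifact_amplitude"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        if self.drift_freq >= 0.3:
            raise ConfigError("drift_freq must be below 0.3 Hz")


ZERO_NOISE = NoiseSpec(0.0, 0.0, 0.0, 0.0, 0.0)

# a phone resting on the chest is never perfectly axis-aligned; the default
# device attitude is a mild tilt of the z-dominant orientation.  (Exact
# alignment with one sensor axis is a degenerate case: the two pulse-free
# axes then contribute pure noise after standardization.)
_v = np.array([0.2, 0.15, 0.97])
DEFAULT_ORIENTATION: tuple[float, float, float] = tuple(_v / np.linalg.norm(_v))
del _v


@dataclass(frozen=True)
class AccelTrace:
    """Uniformly sampled tri-axial acceleration record.

    ``samples`` is an (n, 3) float array in m/s^2; implied timestamps are
    t0 + k/fs.  NaN marks a missing sample (short runs are interpolated at
    pipeline entry); infinities are rejected outright.
    """

    fs: float
    t0: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ConfigError("fs must be positive")
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] < 1:
            raise InputError("samples must be an (n, 3) array with n >= 1")
        if np.any(np.isinf(arr)):
            raise InputError("samples must not contain infinities")
        object.__setattr__(self, "samples", arr)

    @property
    def n(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.n / self.fs

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs


def make_hr_profile(
    segments: Sequence[tuple[float, float, float]],
) -> HRProfile:
    """Build a continuous piecewise-linear HR profile from phase segments.

    Each segment is ``(duration_s, target_bpm, transition_s)``: the rate ramps
    linearly from the previous level to ``target_bpm`` over ``transition_s``
    seconds, then holds.  The first segment starts at its own target (no ramp
    from nowhere).  Total duration is the sum of segment durations.
    """
    if not segments:
        raise DomainError("segment list must be non-empty")
    points: list[tuple[float, float]] = []
    t = 0.0
    level = float(segments[0][1])
    for duration, target, transition in segments:
        duration, target, transition = float(duration), float(target), float(transition)
        if duration <= 0:
            raise DomainError("segment duration must be positive")
        if not (_BPM_MIN <= target <= _BPM_MAX):
            raise DomainError(f"target bpm {target:g} outside [{_BPM_MIN:g}, {_BPM_MAX:g}]")
        if transition < 0 or transition > duration:
            raise DomainError("transition must satisfy 0 <= transition <= duration")
        points.append((t, level))
        if transition > 0 and target != level:
            points.append((t + transition, target))
        points.append((t + duration, target))
        level = target
        t += duration
    # deduplicate consecutive knots with identical times (keep the later value)
    dedup: list[tuple[float, float]] = []
    for pt in points:
        if dedup and abs(pt[0] - dedup[-1][0]) < 1e-12:
            dedup[-1] = pt
        else:
            dedup.append(pt)
    return HRProfile(tuple(dedup))


def generate_beat_times(
    profile: HRProfile, jitter_sd: float = 0.0, seed: int = 0
) -> np.ndarray:
    """Realise the latent rate as heartbeat times over [0, profile.duration].

    Beats are placed where the cumulative integral of rate(t)/60 crosses
    successive integers, then perturbed by iid zero-mean Gaussian jitter of
    standard deviation ``jitter_sd`` seconds (a crude HRV stand-in).  With
    jitter 0 the beat count over [0, T] is within one of the integral of the
    rate.
    """
    if jitter_sd < 0:
        raise DomainError("jitter_sd must be nonnegative")
    T = profile.duration
    # fine grid: piecewise-linear rate, trapezoid integration is exact up to
    # grid resolution of the crossing locations
    dt = 1e-3
    tg = np.arange(0.0, T + dt / 2, dt)
    tg[-1] = min(tg[-1], T)
    rate = profile.rate(tg) / 60.0
    cum = np.concatenate([[0.0], np.cumsum((rate[1:] + rate[:-1]) / 2 * np.diff(tg))])
    n_beats = int(np.floor(cum[-1]))
    targets = np.arange(1, n_beats + 1, dtype=float)
    beats = np.interp(targets, cum, tg)
    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        beats = beats + rng.normal(0.0, jitter_sd, size=beats.shape)
        beats = np.sort(np.clip(beats, 0.0, T))
    return beats


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.shape != (3,) or abs(np.linalg.norm(v) - 1.0) > 1e-6:
        raise ConfigError("orientation must be a unit 3-vector")
    return v


def synth_trace(
    beat_times: Sequence[float] | np.ndarray,
    template: PulseTemplate = PulseTemplate(),
    noise: NoiseSpec = NoiseSpec(),
    orientation=DEFAULT_ORIENTATION,
    fs: float = 50.0,
    duration_s: float | None = None,
    seed: int = 0,
) -> AccelTrace:
    """Render beats into a tri-axial trace with drift, noise and artifacts.

    Each beat contributes the template's damped sinusoid, projected onto the
    (static) device ``orientation``; drift and white noise are then added per
    axis.  Same seed and arguments give bit-identical output.
    """
    orientation = _unit(orientation)
    beats = np.sort(np.asarray(beat_times, dtype=float))
    if duration_s is None:
        duration_s = float(beats[-1]) + 5 * template.decay_tau if beats.size else 1.0
    if beats.size and beats[-1] > duration_s:
        raise ConfigError("duration_s must cover all beat times")
    if fs < 4 * template.carrier_freq:
        raise ConfigError(
            f"fs = {fs:g} Hz too low for carrier {template.carrier_freq:g} Hz "
            "(need fs >= 4 x carrier)"
        )
    n = int(round(fs * duration_s))
    t = np.arange(n) / fs

    pulse = np.zeros(n)
    if template.amplitude > 0:
        # each packet is negligible beyond ~8 tau; render only that support
        span = int(np.ceil(8 * template.decay_tau * fs))
        for tb in beats:
            i0 = int(np.ceil(tb * fs))
            i1 = min(n, i0 + span)
            if i0 >= n:
                continue
            dt_loc = t[i0:i1] - tb
            pulse[i0:i1] += (
                template.amplitude
                * np.exp(-dt_loc / template.decay_tau)
                * np.sin(2 * np.pi * template.carrier_freq * dt_loc)
            )

    xyz = np.outer(pulse, orientation)

    rng = np.random.default_rng(seed)
    # stream order: (1) three drift phases, (2) white noise block, (3) artifacts
    phases = rng.uniform(0, 2 * np.pi, size=3)
    if noise.drift_amplitude > 0 and noise.drift_freq > 0:
        for ax in range(3):
            xyz[:, ax] += noise.drift_amplitude * np.sin(
                2 * np.pi * noise.drift_freq * t + phases[ax]
            )
    if noise.white_sd > 0:
        xyz += rng.normal(0.0, noise.white_sd, size=(n, 3))
    if noise.artifact_rate > 0 and noise.artifact_amplitude > 0:
        n_events = rng.poisson(noise.artifact_rate * duration_s / 60.0)
        for _ in range(n_events):
            te = rng.uniform(0.0, duration_s)
            ax = rng.integers(0, 3)
            width = 0.2  # s half-sine bump
            i0 = int(te * fs)
            i1 = min(n, i0 + int(width * fs))
            if i0 >= n:
                continue
            local = t[i0:i1] - te
            xyz[i0:i1, ax] += noise.artifact_amplitude * np.sin(
                np.pi * np.clip(local, 0, width) / width
            )
    return AccelTrace(fs=fs, t0=0.0, samples=xyz)


def synth_session_trace(
    protocol,
    baseline_bpm: float,
    stress_peak_bpm: float,
    relax_end_bpm: float,
    template: PulseTemplate = PulseTemplate(),
    noise: NoiseSpec = NoiseSpec(),
    fs: float = 50.0,
    seed: int = 0,
    jitter_sd: float = 0.02,
    orientation=DEFAULT_ORIENTATION,
) -> tuple[AccelTrace, HRProfile]:
    """Trace + ground-truth profile following the biofeedback session phases.

    The latent HR holds ``baseline_bpm`` during the baseline phase, ramps to
    ``stress_peak_bpm`` across the stress phase, and decays linearly toward
    ``relax_end_bpm`` over the maximum relaxation length the protocol allows.
    Under the default protocol the trace lasts 10 + 40 + 80 = 130 s.
    """
    for name, bpm in (("baseline_bpm", baseline_bpm),
                      ("stress_peak_bpm", stress_peak_bpm),
                      ("relax_end_bpm", relax_end_bpm)):
        if not (45.0 <= bpm <= 150.0):
            raise ConfigError(f"{name} = {bpm:g} outside the measurable 45–150 bpm band")
    relax_total = protocol.relax_initial_s + protocol.max_extensions * protocol.relax_extension_s
    profile = make_hr_profile([
        (protocol.baseline_s, baseline_bpm, 0.0),
        (protocol.stress_s, stress_peak_bpm, protocol.stress_s),
        (relax_total, relax_end_bpm, relax_total),
    ])
    ss = np.random.SeedSequence(seed)
    beat_seed, trace_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    beats = generate_beat_times(profile, jitter_sd=jitter_sd, seed=beat_seed)
    trace = synth_trace(
        beats, template, noise, orientation, fs,
        duration_s=profile.duration, seed=trace_seed,
    )
    return trace, profile
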