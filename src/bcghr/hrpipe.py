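"""Heart-rate estimation from tri-axial ballistocardiographic accelerometry.

The chain mirrors how smartphone BCG heart-rate extraction is usually built:

1. moving-average detrend per axis (removes baseline drift),
2. per-axis standardization (orientation/amplitude consistency),
3. root-sum-of-squares axis combination,
4. Butterworth band-pass isolating the 4–11 Hz BCG wave-packet band,
5. envelope refinement (rectify + low-pass) turning per-beat packets into a
   pulse waveform whose fundamental is the heart rate,
6. FFT magnitude peak search in 0.66–2.5 Hz with parabolic interpolation.

Sliding trailing windows give a near-real-time HR series.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import numpy as np
from scipy import signal as sps

from ._errors import ConfigError, InputError
from .synthgen import AccelTrace

__all__ = [
    "MonoSignal",
    "PipelineConfig",
    "HREstimate",
    "HRSeries",
    "detrend_ma",
    "standardize_axes",
    "combine_axes",
    "bandpass_bcg",
    "envelope_refine",
    "estimate_hr_fft",
    "process_window",
    "hr_series",
    "fill_gaps",
]


@dataclass(frozen=True)
class MonoSignal:
    """A uniformly sampled scalar signal."""

    fs: float
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ConfigError("fs must be positive")
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise InputError("signal values must be finite")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def duration(self) -> float:
        return self.n / self.fs


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable parameters of the estimation chain.

    The search band default (0.66, 2.5) Hz is the published peak-search
    interval; note 0.66 Hz is 39.6 bpm, so the optional ``clip_bpm`` flag
    additionally clips reported rates to the stated 45–150 bpm range.
    """

    ma_window_s: float = 2.0
    bcg_band_hz: tuple[float, float] = (4.0, 11.0)
    bp_order: int = 2
    envelope_cutoff_hz: float = 3.0
    search_band_hz: tuple[float, float] = (0.66, 2.5)
    window_s: float = 20.0
    hop_s: float = 1.0
    zero_pad_factor: int = 4
    min_snr: float = 3.0
    clip_bpm: bool = False

    def __post_init__(self) -> None:
        for lo, hi in (self.bcg_band_hz, self.search_band_hz):
            if not (0 < lo < hi):
                raise ConfigError(f"band ({lo:g}, {hi:g}) must satisfy 0 < low < high")
        if self.ma_window_s <= 0 or self.window_s <= 0 or self.hop_s <= 0:
            raise ConfigError("window and hop durations must be positive")
        if self.zero_pad_factor < 1:
            raise ConfigError("zero_pad_factor must be >= 1")

    def streaming(self) -> "PipelineConfig":
        """The near-real-time preset: shorter 10 s trailing windows."""
        return replace(self, window_s=10.0)


@dataclass(frozen=True)
class HREstimate:
    """One windowed HR estimate; ``time`` is the right edge of the window."""

    time: float
    bpm: float
    peak_magnitude: float
    confident: bool


@dataclass(frozen=True)
class HRSeries:
    """Time-ordered HR estimates at uniform hop spacing.

    ``window_s`` records the trailing-window length used, which downstream
    phase attribution (the session engine) needs.
    """

    estimates: tuple[HREstimate, ...]
    window_s: float = 10.0

    def __post_init__(self) -> None:
        times = [e.time for e in self.estimates]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise InputError("estimate times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([e.time for e in self.estimates])

    @property
    def bpm(self) -> np.ndarray:
        return np.array([e.bpm for e in self.estimates])


def detrend_ma(sig: MonoSignal, window_s: float = 2.0) -> MonoSignal:
    """Subtract a centered moving average (baseline-drift removal).

    At the boundaries the averaging window shrinks symmetrically so the
    output has the same length as the input.
    """
    w = int(round(window_s * sig.fs))
    if w < 3:
        raise ConfigError("moving-average window must span at least 3 samples")
    if w > sig.n:
        raise ConfigError("moving-average window longer than the signal")
    if w % 2 == 0:
        w += 1
    half = w // 2
    v = sig.values
    c = np.concatenate([[0.0], np.cumsum(v)])
    idx = np.arange(sig.n)
    h = np.minimum(half, np.minimum(idx, sig.n - 1 - idx))
    lo, hi = idx - h, idx + h
    ma = (c[hi + 1] - c[lo]) / (hi - lo + 1)
    return MonoSignal(sig.fs, v - ma)


def standardize_axes(trace: AccelTrace) -> AccelTrace:
    """Scale each axis to zero mean, unit sd; degenerate axes become zeros."""
    if trace.n < 2:
        raise InputError("need at least 2 samples to standardize")
    out = np.empty_like(trace.samples)
    for ax in range(3):
        v = trace.samples[:, ax]
        sd = v.std()
        out[:, ax] = 0.0 if sd < 1e-12 else (v - v.mean()) / sd
    return AccelTrace(trace.fs, trace.t0, out)


def combine_axes(trace: AccelTrace) -> MonoSignal:
    """Per-sample root-sum-of-squares of the three (standardized) axes.

    Invariant to axis permutation and sign flips, hence to device orientation
    after standardization.  The squared axes are summed in sorted order so the
    result is bit-identical under axis permutation.
    """
    sq = np.sort(trace.samples**2, axis=1)
    return MonoSignal(trace.fs, np.sqrt(sq[:, 0] + sq[:, 1] + sq[:, 2]))


def _butter_sos(order: int, band, fs: float, btype: str):
    nyq = fs / 2
    edges = np.atleast_1d(band) / nyq
    if np.any(edges <= 0) or np.any(edges >= 1):
        raise ConfigError(
            f"filter band {band} invalid against Nyquist {nyq:g} Hz"
        )
    wn = float(edges[0]) if edges.size == 1 else edges
    return sps.butter(order, wn, btype=btype, output="sos")


def bandpass_bcg(
    sig: MonoSignal, band_hz: tuple[float, float] = (4.0, 11.0), order: int = 2
) -> MonoSignal:
    """Zero-phase Butterworth band-pass isolating the BCG wave packets."""
    lo, hi = band_hz
    if not (0 < lo < hi):
        raise ConfigError(f"band ({lo:g}, {hi:g}) must satisfy 0 < low < high")
    sos = _butter_sos(order, (lo, hi), sig.fs, "bandpass")
    return MonoSignal(sig.fs, sps.sosfiltfilt(sos, sig.values))


def envelope_refine(sig: MonoSignal, cutoff_hz: float = 3.0) -> MonoSignal:
    """Rectify, low-pass, mean-remove: per-beat packets -> pulse waveform."""
    if not (0 < cutoff_hz < sig.fs / 2):
        raise ConfigError(
            f"envelope cutoff {cutoff_hz:g} Hz must lie in (0, fs/2)"
        )
    sos = _butter_sos(2, cutoff_hz, sig.fs, "lowpass")
    env = sps.sosfiltfilt(sos, np.abs(sig.values))
    return MonoSignal(sig.fs, env - env.mean())


def _inband_bins(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    return np.nonzero((freqs >= band[0]) & (freqs <= band[1]))[0]


def estimate_hr_fft(
    sig: MonoSignal,
    search_band_hz: tuple[float, float] = (0.66, 2.5),
    zero_pad_factor: int = 4,
    min_snr: float = 3.0,
    clip_bpm: bool = False,
    time: float | None = None,
) -> HREstimate:
    """Locate the heart-rate peak in the magnitude spectrum.

    The mean-removed signal is zero-padded, the magnitude spectrum restricted
    to the search band (inclusive), and the maximum bin refined by three-point
    parabolic interpolation.  Ties go to the lowest frequency (argmax returns
    the first maximum).  ``confident`` flags a peak at least ``min_snr`` times
    the median in-band magnitude.
    """
    if sig.duration < 4.0:
        raise InputError("signal must be at least 4 s long for HR estimation")
    v = sig.values - sig.values.mean()
    nfft = int(zero_pad_factor * len(v))
    mag = np.abs(np.fft.rfft(v, n=nfft))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / sig.fs)
    band = _inband_bins(freqs, search_band_hz)
    if band.size == 0:
        raise ConfigError("search band contains no FFT bins")
    k_rel = int(np.argmax(mag[band]))
    k = int(band[k_rel])
    # parabolic refinement on the log-free magnitude, guarded at spectrum edges
    if 0 < k < len(mag) - 1:
        a, b, c = mag[k - 1], mag[k], mag[k + 1]
        denom = a - 2 * b + c
        delta = 0.0 if denom == 0 else 0.5 * (a - c) / denom
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    f_peak = freqs[k] + delta * (freqs[1] - freqs[0])
    bpm = float(np.clip(60.0 * f_peak, 60.0 * search_band_hz[0], 60.0 * search_band_hz[1]))
    if clip_bpm:
        bpm = float(np.clip(bpm, 45.0, 150.0))
    med = float(np.median(mag[band]))
    peak = float(mag[k])
    confident = med > 0 and peak / med >= min_snr
    return HREstimate(
        time=float(time) if time is not None else sig.duration,
        bpm=bpm,
        peak_magnitude=peak,
        confident=confident,
    )


def fill_gaps(trace: AccelTrace, max_gap_s: float = 0.2) -> AccelTrace:
    """Linearly interpolate NaN runs up to ``max_gap_s``; longer gaps error."""
    samples = np.asarray(trace.samples, dtype=float)
    if np.all(np.isfinite(samples)):
        return trace
    out = samples.copy()
    max_run = int(np.floor(max_gap_s * trace.fs))
    for ax in range(3):
        col = out[:, ax]
        bad = ~np.isfinite(col)
        if not bad.any():
            continue
        # find runs of consecutive NaNs
        edges = np.diff(np.concatenate([[0], bad.astype(int), [0]]))
        starts, ends = np.nonzero(edges == 1)[0], np.nonzero(edges == -1)[0]
        for s, e in zip(starts, ends):
            if e - s > max_run or s == 0 or e == len(col):
                raise InputError(
                    f"gap of {(e - s) / trace.fs:.2f} s at sample {s} exceeds "
                    f"the {max_gap_s:g} s interpolation limit"
                )
        good = np.nonzero(~bad)[0]
        col[bad] = np.interp(np.nonzero(bad)[0], good, col[good])
    return AccelTrace(trace.fs, trace.t0, out)


def process_window(trace: AccelTrace, config: PipelineConfig,
                   time: float | None = None) -> HREstimate:
    """Run the full chain on one analysis window of a trace."""
    std = standardize_axes(_detrend_trace(trace, config.ma_window_s))
    mono = combine_axes(std)
    bp = bandpass_bcg(mono, config.bcg_band_hz, config.bp_order)
    env = envelope_refine(bp, config.envelope_cutoff_hz)
    return estimate_hr_fft(
        env,
        config.search_band_hz,
        config.zero_pad_factor,
        config.min_snr,
        config.clip_bpm,
        time=time,
    )


def _detrend_trace(trace: AccelTrace, window_s: float) -> AccelTrace:
    cols = [
        detrend_ma(MonoSignal(trace.fs, trace.samples[:, ax]), window_s).values
        for ax in range(3)
    ]
    return AccelTrace(trace.fs, trace.t0, np.column_stack(cols))


def hr_series(trace: AccelTrace, config: PipelineConfig | None = None) -> HRSeries:
    """Near-real-time HR: the chain applied to trailing windows at hop spacing.

    The first estimate sits at t = window_s (trace-relative); subsequent
    estimates follow every hop_s.
    """
    config = config or PipelineConfig()
    trace = fill_gaps(trace)
    win_n = int(round(config.window_s * trace.fs))
    hop_n = int(round(config.hop_s * trace.fs))
    if trace.n < win_n:
        raise InputError(
            f"trace of {trace.duration:g} s shorter than the {config.window_s:g} s window"
        )
    estimates = []
    for end in range(win_n, trace.n + 1, hop_n):
        seg = AccelTrace(trace.fs, trace.t0, trace.samples[end - win_n:end])
        est = process_window(seg, config, time=end / trace.fs)
        estimates.append(est)
    return HRSeries(tuple(estimates), window_s=config.window_s)
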