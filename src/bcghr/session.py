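"""HR-biofeedback relaxation-session engine and adherence aggregation.

A session walks through three phases: a short rest for baseline HR, a
stress-imagination phase, and a guided relaxation phase.  Relaxation succeeds
as soon as the estimated HR drops at least ``delta_stress_bpm`` below the
stress-phase maximum or at least ``delta_baseline_bpm`` below the baseline
maximum; otherwise the relaxation block is repeated up to ``max_extensions``
times before the session ends unsuccessfully.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from enum import Enum
from typing import Optional, Sequence

from ._errors import ConfigError, InputError
from .hrpipe import HREstimate, HRSeries

__all__ = [
    "SessionProtocol",
    "SessionResult",
    "UsageStats",
    "FeedbackCategory",
    "SUCCESS_FEEDBACK_TEXT",
    "classify_relaxation",
    "run_session",
    "feedback_category",
    "aggregate_usage",
    "round_half_up",
    "percentage",
]

SUCCESS_FEEDBACK_TEXT = "Very good!"


class FeedbackCategory(str, Enum):
    ACHIEVED_INITIAL = "ACHIEVED_INITIAL"
    ACHIEVED_EXTENDED = "ACHIEVED_EXTENDED"
    NOT_ACHIEVED = "NOT_ACHIEVED"


@dataclass(frozen=True)
class SessionProtocol:
    """Phase durations (s) and success thresholds (bpm) of one session."""

    baseline_s: float = 10.0
    stress_s: float = 40.0
    relax_initial_s: float = 40.0
    relax_extension_s: float = 20.0
    max_extensions: int = 2
    delta_stress_bpm: float = 10.0
    delta_baseline_bpm: float = 2.0

    def __post_init__(self) -> None:
        for name in ("baseline_s", "stress_s", "relax_initial_s", "relax_extension_s"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.max_extensions < 0:
            raise ConfigError("max_extensions must be nonnegative")
        if self.delta_stress_bpm <= 0 or self.delta_baseline_bpm <= 0:
            raise ConfigError("success deltas must be positive")

    @property
    def relax_max_s(self) -> float:
        return self.relax_initial_s + self.max_extensions * self.relax_extension_s

    @property
    def total_s(self) -> float:
        return self.baseline_s + self.stress_s + self.relax_max_s


@dataclass(frozen=True)
class SessionResult:
    """Outcome record of one biofeedback session."""

    baseline_max_bpm: Optional[float]
    stress_max_bpm: Optional[float]
    success: bool
    success_time_s: Optional[float]
    extensions_used: int
    relax_duration_s: float
    status: str  # completed | aborted | invalid
    feedback_category: FeedbackCategory
    hr_trajectory: Optional[HRSeries] = None
    invalid_reason: Optional[str] = None


@dataclass(frozen=True)
class UsageStats:
    """Cohort-level adherence numbers (percentages at 2 dp)."""

    n_users: int
    n_started: int
    n_completed: int
    pct_completed: Optional[float]
    n_achieved: int
    pct_achieved: Optional[float]
    mean_starts_per_user: Optional[float]
    pct_of_total: Optional[float] = None


def classify_relaxation(
    baseline_max_bpm: float,
    stress_max_bpm: float,
    hr_bpm: float,
    protocol: SessionProtocol = SessionProtocol(),
) -> bool:
    """True iff HR meets either relaxation-success criterion (inclusive).

    Primary: HR at least ``delta_stress_bpm`` below the stress-phase maximum.
    Secondary: HR at least ``delta_baseline_bpm`` below the baseline maximum.
    """
    for name, v in (("baseline_max_bpm", baseline_max_bpm),
                    ("stress_max_bpm", stress_max_bpm), ("hr_bpm", hr_bpm)):
        if not (math.isfinite(v) and v > 0):
            raise InputError(f"{name} must be finite and positive")
    return (hr_bpm <= stress_max_bpm - protocol.delta_stress_bpm
            or hr_bpm <= baseline_max_bpm - protocol.delta_baseline_bpm)


def _phase_estimates(hr: HRSeries, start: float, end: float) -> list[HREstimate]:
    """Estimates whose trailing window lies fully inside [start, end]."""
    w = hr.window_s
    eps = 1e-9
    return [e for e in hr.estimates
            if e.time - w >= start - eps and e.time <= end + eps]


def run_session(hr: HRSeries, protocol: SessionProtocol = SessionProtocol()) -> SessionResult:
    """Drive the session state machine over an estimated HR series.

    An estimate belongs to a phase iff its trailing analysis window lies fully
    inside that phase; low-confidence estimates are ignored throughout.  The
    relaxation phase is scanned in time order; the first estimate meeting a
    success criterion ends the session successfully.  When the initial block
    (and then each extension) elapses without success, an extension is granted
    until ``max_extensions`` is exhausted.  A series that stops before the
    protocol does, without success, counts as aborted.
    """
    t_base_end = protocol.baseline_s
    t_stress_end = t_base_end + protocol.stress_s

    base = [e for e in _phase_estimates(hr, 0.0, t_base_end) if e.confident]
    if not base:
        return SessionResult(
            baseline_max_bpm=None, stress_max_bpm=None, success=False,
            success_time_s=None, extensions_used=0, relax_duration_s=0.0,
            status="invalid", feedback_category=FeedbackCategory.NOT_ACHIEVED,
            hr_trajectory=hr, invalid_reason="no confident baseline estimate",
        )
    baseline_max = max(e.bpm for e in base)

    stress = [e for e in _phase_estimates(hr, t_base_end, t_stress_end) if e.confident]
    stress_max = max((e.bpm for e in stress), default=baseline_max)

    relax = [e for e in hr.estimates
             if e.confident and e.time - hr.window_s >= t_stress_end - 1e-9]
    relax.sort(key=lambda e: e.time)

    eps = 1e-9
    extensions = 0
    allowed_end = t_stress_end + protocol.relax_initial_s
    success = False
    success_time: Optional[float] = None
    last_seen = t_stress_end
    for e in relax:
        # grant extensions as the stream crosses each block boundary
        while e.time > allowed_end + eps and extensions < protocol.max_extensions:
            extensions += 1
            allowed_end += protocol.relax_extension_s
        if e.time > allowed_end + eps:
            last_seen = allowed_end
            break
        last_seen = e.time
        if classify_relaxation(baseline_max, stress_max, e.bpm, protocol):
            success = True
            success_time = e.time
            break

    if success:
        relax_duration = success_time - t_stress_end
        rel = relax_duration
        if rel <= protocol.relax_initial_s + eps:
            category = FeedbackCategory.ACHIEVED_INITIAL
        else:
            category = FeedbackCategory.ACHIEVED_EXTENDED
        status = "completed"
    else:
        # did the stream cover the full protocol?
        stream_end = hr.estimates[-1].time if hr.estimates else 0.0
        full_end = t_stress_end + protocol.relax_max_s
        if stream_end + eps >= full_end:
            status = "completed"
            extensions = protocol.max_extensions
            relax_duration = protocol.relax_max_s
        else:
            status = "aborted"
            relax_duration = max(0.0, min(stream_end, allowed_end) - t_stress_end)
        category = FeedbackCategory.NOT_ACHIEVED

    return SessionResult(
        baseline_max_bpm=baseline_max,
        stress_max_bpm=stress_max,
        success=success,
        success_time_s=success_time,
        extensions_used=extensions,
        relax_duration_s=relax_duration,
        status=status,
        feedback_category=category,
        hr_trajectory=hr,
    )


def feedback_category(result: SessionResult,
                      protocol: SessionProtocol = SessionProtocol()) -> FeedbackCategory:
    """Three-way feedback mapping from a finished session."""
    if not result.success:
        return FeedbackCategory.NOT_ACHIEVED
    rel = result.success_time_s - (protocol.baseline_s + protocol.stress_s)
    if rel <= protocol.relax_initial_s + 1e-9:
        return FeedbackCategory.ACHIEVED_INITIAL
    return FeedbackCategory.ACHIEVED_EXTENDED


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals (reporting rule)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percentage(numerator: float, denominator: float, ndigits: int = 2) -> float:
    """100 * ratio, rounded half away from zero to ``ndigits`` decimals."""
    if denominator == 0:
        raise InputError("percentage denominator must be nonzero")
    return round_half_up(100.0 * numerator / denominator, ndigits)


def aggregate_usage(
    results: Sequence[SessionResult],
    n_users: int,
    cohort_n: Optional[int] = None,
) -> UsageStats:
    """Aggregate per-session outcomes into cohort adherence statistics.

    Started = all sessions; completed = sessions that ran the protocol to its
    end (successfully or not); achieved = completed sessions that met a
    relaxation criterion.  Percentages are rounded half away from zero to two
    decimals; with ``cohort_n`` given, ``pct_of_total`` reports users as a
    share of the cohort.
    """
    results = list(results)
    if results and n_users <= 0:
        raise InputError("n_users must be positive when results are present")
    n_started = len(results)
    n_completed = sum(1 for r in results if r.status == "completed")
    n_achieved = sum(1 for r in results if r.status == "completed" and r.success)
    return UsageStats(
        n_users=n_users,
        n_started=n_started,
        n_completed=n_completed,
        pct_completed=percentage(n_completed, n_started) if n_started else None,
        n_achieved=n_achieved,
        pct_achieved=percentage(n_achieved, n_completed) if n_completed else None,
        mean_starts_per_user=round_half_up(n_started / n_users) if n_users else None,
        pct_of_total=percentage(n_users, cohort_n) if cohort_n else None,
    )
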