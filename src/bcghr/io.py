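"""File formats: accelerometer CSV, HR-series CSV, session/usage JSON, YAML config.

CSV dialect is pinned (comma separator, ``.`` decimal, UTF-8, Unix newlines)
so fixtures stay portable; all round-trips are lossless at double precision.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from ._errors import ConfigError, ParseError
from .hrpipe import HREstimate, HRSeries, PipelineConfig
from .session import FeedbackCategory, SessionProtocol, SessionResult, UsageStats
from .synthgen import DEFAULT_ORIENTATION, AccelTrace, NoiseSpec, PulseTemplate

__all__ = [
    "SCHEMA_VERSION",
    "read_trace_csv",
    "write_trace_csv",
    "read_hr_csv",
    "write_hr_csv",
    "write_session_json",
    "read_session_json",
    "write_usage_json",
    "load_run_config",
]

SCHEMA_VERSION = 1

_TRACE_HEADER = ["t", "x", "y", "z"]


def write_trace_csv(trace: AccelTrace, path) -> None:
    """Write a trace as ``t,x,y,z`` rows (seconds, m/s²), full precision."""
    df = pd.DataFrame(
        {
            "t": trace.t,
            "x": trace.samples[:, 0],
            "y": trace.samples[:, 1],
            "z": trace.samples[:, 2],
        }
    )
    df.to_csv(path, index=False, lineterminator="\n")


def read_trace_csv(path) -> AccelTrace:
    """Parse a ``t,x,y,z`` CSV; fs inferred from the median timestamp step.

    Timestamps must be strictly increasing and uniform to within 1% relative
    jitter; the first offending row is named in the error.
    """
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # malformed CSV
        raise ParseError(f"{path}: cannot parse CSV ({exc})") from exc
    if list(df.columns) != _TRACE_HEADER:
        raise ParseError(
            f"{path}: header must be exactly 't,x,y,z', got {','.join(map(str, df.columns))}"
        )
    if len(df) < 2:
        raise ParseError(f"{path}: need at least 2 samples")
    arr = df.to_numpy(dtype=float)
    bad = np.nonzero(~np.isfinite(arr).all(axis=1))[0]
    if bad.size:
        raise ParseError(f"{path}: non-finite value at data row {bad[0] + 1}")
    t = arr[:, 0]
    dt = np.diff(t)
    nonpos = np.nonzero(dt <= 0)[0]
    if nonpos.size:
        raise ParseError(
            f"{path}: timestamps not strictly increasing at data row {nonpos[0] + 2}"
        )
    med = float(np.median(dt))
    irregular = np.nonzero(np.abs(dt - med) > 0.01 * med)[0]
    if irregular.size:
        raise ParseError(
            f"{path}: irregular sampling at data row {irregular[0] + 2} "
            f"(step {dt[irregular[0]]:g} s vs median {med:g} s)"
        )
    fs = 1.0 / med
    if abs(fs - round(fs)) < 1e-6 * fs:  # snap away timestamp round-off
        fs = float(round(fs))
    return AccelTrace(fs=fs, t0=float(t[0]), samples=arr[:, 1:4])


def write_hr_csv(series: HRSeries, path) -> None:
    """Write an HR series as ``time_s,bpm,peak_magnitude,confident``."""
    df = pd.DataFrame(
        {
            "time_s": [e.time for e in series.estimates],
            "bpm": [e.bpm for e in series.estimates],
            "peak_magnitude": [e.peak_magnitude for e in series.estimates],
            "confident": [int(e.confident) for e in series.estimates],
        }
    )
    df.to_csv(path, index=False, lineterminator="\n")


def read_hr_csv(path, window_s: float = 10.0) -> HRSeries:
    """Read an HR series CSV; ``window_s`` re-attaches the analysis window."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse CSV ({exc})") from exc
    want = ["time_s", "bpm", "peak_magnitude", "confident"]
    if list(df.columns) != want:
        raise ParseError(f"{path}: header must be exactly {','.join(want)}")
    ests = tuple(
        HREstimate(
            time=float(r.time_s),
            bpm=float(r.bpm),
            peak_magnitude=float(r.peak_magnitude),
            confident=bool(int(r.confident)),
        )
        for r in df.itertuples()
    )
    return HRSeries(ests, window_s=window_s)


def _session_dict(result: SessionResult) -> dict[str, Any]:
    traj = None
    if result.hr_trajectory is not None:
        traj = {
            "window_s": result.hr_trajectory.window_s,
            "estimates": [
                [e.time, e.bpm, e.peak_magnitude, bool(e.confident)]
                for e in result.hr_trajectory.estimates
            ],
        }
    return {
        "schema_version": SCHEMA_VERSION,
        "baseline_max_bpm": result.baseline_max_bpm,
        "stress_max_bpm": result.stress_max_bpm,
        "success": result.success,
        "success_time_s": result.success_time_s,
        "extensions_used": result.extensions_used,
        "relax_duration_s": result.relax_duration_s,
        "status": result.status,
        "feedback_category": result.feedback_category.value,
        "invalid_reason": result.invalid_reason,
        "hr_trajectory": traj,
    }


def write_session_json(result: SessionResult, path) -> None:
    """Serialize a session result with a stable key order and schema tag."""
    Path(path).write_text(
        json.dumps(_session_dict(result), indent=1) + "\n", encoding="utf-8"
    )


def read_session_json(path) -> SessionResult:
    d = json.loads(Path(path).read_text(encoding="utf-8"))
    if d.get("schema_version") != SCHEMA_VERSION:
        raise ParseError(f"{path}: unsupported schema version {d.get('schema_version')}")
    traj = None
    if d.get("hr_trajectory") is not None:
        traj = HRSeries(
            tuple(
                HREstimate(time=e[0], bpm=e[1], peak_magnitude=e[2], confident=e[3])
                for e in d["hr_trajectory"]["estimates"]
            ),
            window_s=d["hr_trajectory"]["window_s"],
        )
    return SessionResult(
        baseline_max_bpm=d["baseline_max_bpm"],
        stress_max_bpm=d["stress_max_bpm"],
        success=d["success"],
        success_time_s=d["success_time_s"],
        extensions_used=d["extensions_used"],
        relax_duration_s=d["relax_duration_s"],
        status=d["status"],
        feedback_category=FeedbackCategory(d["feedback_category"]),
        hr_trajectory=traj,
        invalid_reason=d.get("invalid_reason"),
    )


def write_usage_json(stats: UsageStats, path) -> None:
    d = {"schema_version": SCHEMA_VERSION, **asdict(stats)}
    Path(path).write_text(json.dumps(d, indent=1) + "\n", encoding="utf-8")


def _build(cls, data: dict, what: str):
    known = set(cls.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown {what} key(s): {', '.join(sorted(unknown))}")
    try:
        return cls(**data)
    except TypeError as exc:
        raise ConfigError(f"invalid {what} config: {exc}") from exc


def load_run_config(path) -> dict[str, Any]:
    """Load a YAML (or JSON) run configuration; unknown keys are rejected.

    Top-level sections: ``pipeline``, ``protocol``, ``simulation`` (with
    ``template`` and ``noise`` subsections plus ``profile`` segments), ``seed``,
    ``log_level``.  Missing sections fall back to package defaults.
    """
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    allowed = {"pipeline", "protocol", "simulation", "seed", "log_level"}
    unknown = set(raw) - allowed
    if unknown:
        raise ConfigError(f"{path}: unknown top-level key(s): {', '.join(sorted(unknown))}")
    pipe_raw = dict(raw.get("pipeline") or {})
    for band_key in ("bcg_band_hz", "search_band_hz"):
        if band_key in pipe_raw and isinstance(pipe_raw[band_key], (list, tuple)):
            pipe_raw[band_key] = tuple(pipe_raw[band_key])
    out: dict[str, Any] = {
        "pipeline": _build(PipelineConfig, pipe_raw, "pipeline"),
        "protocol": _build(SessionProtocol, dict(raw.get("protocol") or {}), "protocol"),
        "seed": int(raw.get("seed", 0)),
        "log_level": str(raw.get("log_level", "INFO")),
    }
    sim = dict(raw.get("simulation") or {})
    sim_allowed = {"template", "noise", "profile", "fs", "jitter_sd", "orientation"}
    unknown = set(sim) - sim_allowed
    if unknown:
        raise ConfigError(f"{path}: unknown simulation key(s): {', '.join(sorted(unknown))}")
    out["template"] = _build(PulseTemplate, dict(sim.get("template") or {}), "template")
    out["noise"] = _build(NoiseSpec, dict(sim.get("noise") or {}), "noise")
    out["profile_segments"] = [tuple(seg) for seg in (sim.get("profile") or [])]
    out["fs"] = float(sim.get("fs", 50.0))
    out["jitter_sd"] = float(sim.get("jitter_sd", 0.02))
    out["orientation"] = tuple(sim.get("orientation", DEFAULT_ORIENTATION))
    return out
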