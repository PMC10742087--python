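"""The 7-day cued-entrainment session protocol.

A session opens with a 10-second baseline period during which the dominant
tremor frequency f0 is measured from the accelerometer.  The remaining
treatment time is split into two equal halves: auditory cues tick at
2/3·f0 for the first half and 1/3·f0 for the second, each clamped to a
configurable [f_min, f_max] band so that sessions remain tolerable and can
start even when no tremor is detectable (the baseline then falls back to
``f_default`` and is flagged).  Day 1 is a 60-minute supervised session;
days 2–7 are 30-minute at-home sessions.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import datetime, timezone

import numpy as np
from scipy import fft as sp_fft
from scipy import signal as sp_signal

from ._kv import coerce_fields, parse_kv_file
from .errors import AnalysisError, ConfigError
from .recording import AccelerometerRecording
from .session_log import SessionLogEntry
from .signal_analysis import (
    DEFAULT_HOP,
    DEFAULT_MIN_RESOLUTION,
    DEFAULT_WINDOW,
    FrequencyTrace,
    combine_axes,
    track_frequency,
)


class SessionPhase(str, enum.Enum):
    BASELINE = "baseline"
    PHASE1 = "phase1"
    PHASE2 = "phase2"
    COMPLETE = "complete"


@dataclass(frozen=True)
class ProtocolConfig:
    """All protocol constants.

    Defaults encode the published protocol: 10-s baseline, cue ratios 2/3
    and 1/3, 60-minute day-1 and 30-minute daily sessions over 7 days.
    Clamps, fallback frequency, search band, gauge tolerance and the peak
    prominence criterion are implementation parameters (see docs).
    """

    baseline_duration: float = 10.0  # s
    ratio_phase1: float = 2.0 / 3.0
    ratio_phase2: float = 1.0 / 3.0
    f_min: float = 1.0  # Hz, treatment clamp floor
    f_max: float = 5.0  # Hz, treatment clamp ceiling
    f_default: float = 4.5  # Hz, baseline fallback when tremor undetectable
    day1_duration: float = 3600.0  # s
    daily_duration: float = 1800.0  # s, days 2..n_days
    n_days: int = 7
    band_low: float = 1.0  # Hz, tremor search band
    band_high: float = 12.0
    goal_tolerance: float = 0.10  # fraction of goal frequency
    prominence_factor: float = 5.0

    def __post_init__(self) -> None:
        if not 0 < self.ratio_phase2 < self.ratio_phase1 < 1:
            raise ConfigError(
                f"need 0 < ratio_phase2 < ratio_phase1 < 1, got "
                f"{self.ratio_phase2}, {self.ratio_phase1}"
            )
        if not 0 < self.f_min < self.f_max:
            raise ConfigError(f"need 0 < f_min < f_max, got {self.f_min}, {self.f_max}")
        if not self.baseline_duration > 0:
            raise ConfigError("baseline_duration must be positive")
        if self.baseline_duration >= min(self.day1_duration, self.daily_duration):
            raise ConfigError("baseline_duration must be shorter than every session")
        if not 0 < self.goal_tolerance < 1:
            raise ConfigError(f"goal_tolerance must be in (0, 1), got {self.goal_tolerance}")
        if self.n_days < 1:
            raise ConfigError("n_days must be at least 1")
        if not 0 < self.band_low < self.band_high:
            raise ConfigError(f"invalid band [{self.band_low}, {self.band_high}]")
        if self.prominence_factor <= 0:
            raise ConfigError("prominence_factor must be positive")


def load_config(path) -> ProtocolConfig:
    """Read a flat ``key = value`` protocol file; unknown keys rejected."""
    return ProtocolConfig(**coerce_fields(ProtocolConfig, parse_kv_file(path), path))


@dataclass(frozen=True)
class PhasePlan:
    """Resolved timing and cue frequencies for one session."""

    day: int
    scheduled_duration: float
    baseline_end: float
    phase1_end: float
    phase1_frequency: float
    phase2_frequency: float
    baseline_frequency: float
    baseline_significant: bool

    def __post_init__(self) -> None:
        if not 0 < self.baseline_end < self.phase1_end < self.scheduled_duration:
            raise ConfigError("phase boundaries out of order")


@dataclass(frozen=True)
class CueSchedule:
    """Tick times in seconds from session start, strictly increasing."""

    tick_times: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.tick_times, dtype=float)
        object.__setattr__(self, "tick_times", t)
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ConfigError("tick times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.tick_times.size)


def scheduled_duration(day: int, cfg: ProtocolConfig) -> float:
    """Session length in seconds for a protocol day (day 1 is the long one)."""
    if not 1 <= day <= cfg.n_days:
        raise ConfigError(f"day must be in 1..{cfg.n_days}, got {day}")
    return cfg.day1_duration if day == 1 else cfg.daily_duration


def compute_baseline(
    rec: AccelerometerRecording,
    cfg: ProtocolConfig,
    method: str = "magnitude",
) -> tuple[float, bool]:
    """Average baseline tremor frequency over the opening period.

    A Welch-style averaged periodogram (Hann-tapered overlapping
    sub-windows, zero-padded to the analysis resolution) is computed over
    the first ``cfg.baseline_duration`` seconds; its in-band peak is the
    baseline frequency.  If the peak fails the prominence criterion the
    configured fallback ``cfg.f_default`` is returned with flag False.
    """
    if rec.duration + 1e-9 < cfg.baseline_duration:
        raise AnalysisError(
            f"recording of {rec.duration:.2f} s shorter than baseline period "
            f"{cfg.baseline_duration} s"
        )
    prefix = rec.truncated(cfg.baseline_duration)
    series = combine_axes(prefix, method=method)
    fs = rec.sample_rate
    # sub-windows of ~40% of the baseline period, 50% overlap -> 4 averages
    nperseg = min(series.size, int(round(0.4 * cfg.baseline_duration * fs)))
    nfft = sp_fft.next_fast_len(max(nperseg, int(np.ceil(fs / DEFAULT_MIN_RESOLUTION))))
    freqs, power = sp_signal.welch(
        series, fs=fs, window="hann", nperseg=nperseg, nfft=nfft, detrend="constant"
    )
    in_band = (freqs >= cfg.band_low) & (freqs <= cfg.band_high)
    band_power = power[in_band]
    peak_idx = int(np.argmax(band_power))
    significant = bool(
        band_power[peak_idx] >= cfg.prominence_factor * np.median(band_power)
    )
    if not significant:
        return cfg.f_default, False
    return float(freqs[in_band][peak_idx]), True


def treatment_frequency(f0: float, phase, cfg: ProtocolConfig) -> float:
    """Cue frequency for a phase: the phase ratio times f0, clamped to
    [f_min, f_max]."""
    if not f0 > 0:
        raise ConfigError(f"baseline frequency must be positive, got {f0}")
    phase = SessionPhase(phase)
    if phase is SessionPhase.PHASE1:
        ratio = cfg.ratio_phase1
    elif phase is SessionPhase.PHASE2:
        ratio = cfg.ratio_phase2
    else:
        raise ConfigError(f"no treatment frequency for phase {phase.value!r}")
    return float(np.clip(ratio * f0, cfg.f_min, cfg.f_max))


def build_phase_plan(
    day: int, f0: float, significant: bool, cfg: ProtocolConfig
) -> PhasePlan:
    """Split the post-baseline treatment time into two equal halves and
    attach the clamped cue frequency of each."""
    total = scheduled_duration(day, cfg)
    treatment = total - cfg.baseline_duration
    return PhasePlan(
        day=day,
        scheduled_duration=total,
        baseline_end=cfg.baseline_duration,
        phase1_end=cfg.baseline_duration + treatment / 2.0,
        phase1_frequency=treatment_frequency(f0, SessionPhase.PHASE1, cfg),
        phase2_frequency=treatment_frequency(f0, SessionPhase.PHASE2, cfg),
        baseline_frequency=f0,
        baseline_significant=significant,
    )


def generate_cue_times(plan: PhasePlan) -> CueSchedule:
    """Tick timestamps: each phase starts with a tick at its start and
    continues at 1/phase_frequency spacing up to (excluding) the phase end."""
    ticks = []
    for start, end, freq in (
        (plan.baseline_end, plan.phase1_end, plan.phase1_frequency),
        (plan.phase1_end, plan.scheduled_duration, plan.phase2_frequency),
    ):
        dur = end - start
        if dur <= 0:
            continue
        n = int(np.ceil(dur * freq - 1e-9))
        ticks.append(start + np.arange(n) / freq)
    times = np.concatenate(ticks) if ticks else np.empty(0)
    return CueSchedule(tick_times=times)


def phase_at(elapsed: float, plan: PhasePlan) -> tuple[SessionPhase, float]:
    """Session phase at an elapsed time and the remaining seconds.

    Boundaries are half-open [start, end); at or past the scheduled end the
    session is complete with zero remaining.
    """
    if elapsed < 0:
        raise ConfigError(f"elapsed time must be non-negative, got {elapsed}")
    remaining = max(0.0, plan.scheduled_duration - elapsed)
    if elapsed < plan.baseline_end:
        return SessionPhase.BASELINE, remaining
    if elapsed < plan.phase1_end:
        return SessionPhase.PHASE1, remaining
    if elapsed < plan.scheduled_duration:
        return SessionPhase.PHASE2, remaining
    return SessionPhase.COMPLETE, 0.0


@dataclass(frozen=True)
class SessionResult:
    """Everything one offline session replay produces."""

    plan: PhasePlan
    cues: CueSchedule
    trace: FrequencyTrace
    gauge: list
    log_entry: SessionLogEntry


def run_session(
    rec: AccelerometerRecording,
    day: int,
    cfg: ProtocolConfig | None = None,
    method: str = "magnitude",
    started_at: datetime | None = None,
) -> SessionResult:
    """Replay a full session offline from a recording.

    Computes the baseline, builds the phase plan and cue schedule, tracks
    the voluntary movement frequency over the treatment portion in sliding
    windows, scores each window on the biofeedback gauge, and produces the
    time-stamped log entry.  A recording shorter than the scheduled
    duration is truncated, never extrapolated, and flagged ``ended_early``.
    """
    from .biofeedback import gauge_trace  # deferred: biofeedback uses PhasePlan

    cfg = cfg if cfg is not None else ProtocolConfig()
    total = scheduled_duration(day, cfg)
    f0, significant = compute_baseline(rec, cfg, method=method)
    plan = build_phase_plan(day, f0, significant, cfg)
    cues = generate_cue_times(plan)

    clipped = rec.truncated(total) if rec.duration > total else rec
    series = combine_axes(clipped, method=method)
    start_idx = int(round(plan.baseline_end * rec.sample_rate))
    treatment_series = series[start_idx:]
    if treatment_series.size >= int(round(DEFAULT_WINDOW * rec.sample_rate)):
        trace = track_frequency(
            treatment_series,
            rec.sample_rate,
            window_length=DEFAULT_WINDOW,
            hop=DEFAULT_HOP,
            band_low=cfg.band_low,
            band_high=cfg.band_high,
            prominence_factor=cfg.prominence_factor,
        ).shifted(plan.baseline_end)
    else:
        trace = FrequencyTrace(
            np.empty(0), np.empty(0), DEFAULT_WINDOW, DEFAULT_HOP
        )
    gauge = gauge_trace(trace, plan, cfg)

    completed = min(rec.duration, total)
    if total - completed < 1.0 / rec.sample_rate:  # duration quantized to samples
        completed = total
    if started_at is None:
        started_at = datetime.now(timezone.utc).astimezone()
    entry = SessionLogEntry(
        day=day,
        started_at=started_at.isoformat(),
        completed_duration=completed,
        scheduled_duration=total,
        baseline_frequency=f0,
        baseline_significant=significant,
        ended_early=completed < total,
    )
    return SessionResult(plan=plan, cues=cues, trace=trace, gauge=gauge, log_entry=entry)
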