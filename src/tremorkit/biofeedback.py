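"""Biofeedback gauge: measured movement frequency → bounded needle position.

The needle is linear in the relative frequency error, zero exactly at the
goal (the goal range sits in the middle of the dial), and clips at ±1 when
the error exceeds ``half_scale`` of the goal.  A window with no significant
movement pegs the needle low so absence of movement stays visible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ConfigError
from .protocol import PhasePlan, ProtocolConfig, SessionPhase, phase_at
from .signal_analysis import FrequencyTrace

DEFAULT_HALF_SCALE = 0.5  # full deflection at ±50% relative frequency error


@dataclass(frozen=True)
class GaugeReading:
    """One gauge sample: needle in [−1, +1], zero at the goal frequency."""

    needle: float
    in_goal: bool
    measured: float | None  # Hz; None when no significant movement detected
    goal: float  # Hz


def gauge_position(
    measured: float | None,
    goal: float,
    goal_tolerance: float = 0.10,
    half_scale: float = DEFAULT_HALF_SCALE,
) -> GaugeReading:
    """Score one measured frequency against the goal cue frequency.

    needle = clip((measured − goal) / (half_scale · goal), −1, +1);
    in_goal ⇔ |measured − goal| ≤ goal_tolerance · goal.
    """
    if not goal > 0:
        raise ConfigError(f"goal frequency must be positive, got {goal}")
    if not 0 < goal_tolerance < half_scale:
        raise ConfigError(
            f"need 0 < goal_tolerance < half_scale, got {goal_tolerance}, {half_scale}"
        )
    if measured is None or (isinstance(measured, float) and math.isnan(measured)):
        return GaugeReading(needle=-1.0, in_goal=False, measured=None, goal=goal)
    needle = (measured - goal) / (half_scale * goal)
    needle = max(-1.0, min(1.0, needle))
    in_goal = abs(measured - goal) <= goal_tolerance * goal
    return GaugeReading(needle=needle, in_goal=in_goal, measured=float(measured), goal=goal)


def gauge_trace(
    trace: FrequencyTrace, plan: PhasePlan, cfg: ProtocolConfig
) -> list[GaugeReading]:
    """Score every tracker window against the cue frequency of its phase.

    The phase of each window is decided by its center time; windows must lie
    within the treatment portion of the plan.
    """
    readings: list[GaugeReading] = []
    for center, freq in zip(trace.window_centers, trace.frequencies):
        phase, _ = phase_at(float(center), plan)
        if phase is SessionPhase.PHASE1:
            goal = plan.phase1_frequency
        elif phase is SessionPhase.PHASE2:
            goal = plan.phase2_frequency
        else:
            raise ConfigError(
                f"window at {center:.2f} s lies outside the treatment portion"
            )
        measured = None if math.isnan(freq) else float(freq)
        readings.append(
            gauge_position(measured, goal, cfg.goal_tolerance, DEFAULT_HALF_SCALE)
        )
    return readings


def write_gauge_trace(trace: FrequencyTrace, readings: list[GaugeReading], path) -> None:
    """Export a gauge trace as tab-delimited text
    (t, measured, goal, needle, in_goal)."""
    if len(trace) != len(readings):
        raise ConfigError("trace and readings lengths differ")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("t\tmeasured\tgoal\tneedle\tin_goal\n")
        for center, r in zip(trace.window_centers, readings):
            measured = "nan" if r.measured is None else f"{r.measured:.6f}"
            fh.write(
                f"{center:.6f}\t{measured}\t{r.goal:.6f}\t{r.needle:.6f}\t"
                f"{int(r.in_goal)}\n"
            )
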