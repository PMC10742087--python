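"""Synthetic tremor and entrained-subject accelerometer recordings.

Every generator is fully reproducible from the scenario seed and exposes
its ground truth, so each pipeline stage can be tested against known
parameters without hardware.  Three regimes are covered:

* free-running tremor — a noisy oscillation at ``f_tremor`` with an
  optional second harmonic and a slow linear frequency drift;
* a cue-following subject — the instantaneous movement frequency relaxes
  first-order (time constant ``tracking_lag``) toward a convex combination
  of the phase cue frequency and the native tremor frequency, the weight
  being ``responsiveness`` (1 = entrains fully, 0 = ignores the cue), with
  optional low-pass-filtered frequency jitter;
* noise only (``amplitude = 0``) — the no-detectable-tremor startup case.

Gravity (9.81 m/s²) rides on one axis and the oscillation is distributed
across axes by a unit weight vector, so magnitude-based axis combination is
genuinely exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sp_signal

from ._kv import coerce_fields, parse_kv_file
from .errors import ConfigError
from .protocol import PhasePlan
from .recording import AccelerometerRecording

GRAVITY = 9.81  # m/s²
JITTER_CUTOFF = 0.5  # Hz low-pass on frequency jitter: windows stay quasi-stationary


@dataclass(frozen=True)
class SimulationScenario:
    """Ground-truth parameters for one synthetic recording."""

    f_tremor: float = 6.0  # Hz, native tremor frequency
    amplitude: float = 1.0  # m/s², oscillation amplitude (0 = no tremor)
    harmonic_ratio: float = 0.0  # fraction of amplitude at 2×f_tremor
    drift_rate: float = 0.0  # Hz per minute, slow linear frequency drift
    noise_sd: float = 0.1  # m/s², i.i.d. Gaussian noise per axis
    axis_weights: tuple = (0.577350269189626, 0.577350269189626, 0.577350269189626)
    gravity_axis: str = "z"
    responsiveness: float = 1.0  # 0..1, cue-following weight
    tracking_lag: float = 1.0  # s, first-order time constant of entrainment
    jitter_sd: float = 0.0  # Hz, sd of low-passed frequency jitter
    sample_rate: float = 50.0  # Hz
    duration: float = 60.0  # s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.noise_sd < 0 or self.jitter_sd < 0:
            raise ConfigError("amplitude, noise_sd and jitter_sd must be >= 0")
        if not 0 <= self.responsiveness <= 1:
            raise ConfigError(f"responsiveness must be in [0, 1], got {self.responsiveness}")
        if not self.duration > 0:
            raise ConfigError("duration must be positive")
        if not self.sample_rate > 0:
            raise ConfigError("sample_rate must be positive")
        if self.f_tremor <= 0:
            raise ConfigError("f_tremor must be positive")
        if self.tracking_lag < 0:
            raise ConfigError("tracking_lag must be >= 0")
        w = np.asarray(self.axis_weights, dtype=float)
        if w.shape != (3,) or abs(np.linalg.norm(w) - 1.0) > 1e-6:
            raise ConfigError("axis_weights must be a unit 3-vector")
        if self.gravity_axis not in ("x", "y", "z"):
            raise ConfigError(f"gravity_axis must be x, y or z, got {self.gravity_axis!r}")


def load_scenario(path) -> SimulationScenario:
    """Read a flat ``key = value`` scenario file; unknown keys rejected."""
    return SimulationScenario(
        **coerce_fields(SimulationScenario, parse_kv_file(path), path)
    )


def _synthesize(
    sc: SimulationScenario, inst_freq: np.ndarray, rng: np.random.Generator
) -> AccelerometerRecording:
    """Waveform from an instantaneous-frequency series: phase is the
    cumulative integral of frequency; noise and gravity added per axis."""
    n = inst_freq.size
    dt = 1.0 / sc.sample_rate
    t = np.arange(n) * dt
    phase0 = rng.uniform(0, 2 * np.pi)
    phase = 2 * np.pi * np.cumsum(inst_freq) * dt + phase0
    s = sc.amplitude * (
        np.sin(phase) + sc.harmonic_ratio * np.sin(2 * phase)
    )
    weights = np.asarray(sc.axis_weights, dtype=float)
    axes = {}
    for i, name in enumerate("xyz"):
        axes[name] = weights[i] * s + rng.normal(0.0, sc.noise_sd, n)
        if name == sc.gravity_axis:
            axes[name] = axes[name] + GRAVITY
    return AccelerometerRecording(
        sample_rate=sc.sample_rate, time=t, ax=axes["x"], ay=axes["y"], az=axes["z"]
    )


def simulate_tremor(sc: SimulationScenario) -> AccelerometerRecording:
    """Free-running tremor: frequency f_tremor + drift_rate·t/60."""
    n = int(round(sc.duration * sc.sample_rate))
    t = np.arange(n) / sc.sample_rate
    inst_freq = sc.f_tremor + sc.drift_rate * t / 60.0
    return _synthesize(sc, inst_freq, np.random.default_rng(sc.seed))


def _filtered_jitter(
    sc: SimulationScenario, n: int, rng: np.random.Generator
) -> np.ndarray:
    if sc.jitter_sd == 0 or n < 30:
        return np.zeros(n)
    white = rng.normal(0.0, 1.0, n)
    sos = sp_signal.butter(2, JITTER_CUTOFF, fs=sc.sample_rate, output="sos")
    low = sp_signal.sosfilt(sos, white)
    sd = low.std()
    return low * (sc.jitter_sd / sd) if sd > 0 else np.zeros(n)


def simulate_entrained_subject(
    sc: SimulationScenario, plan: PhasePlan
) -> AccelerometerRecording:
    """Cue-following subject for a given phase plan.

    The movement-frequency target is f_tremor during baseline and
    ``responsiveness·f_cue + (1 − responsiveness)·f_tremor`` once each
    phase's cues begin; the realised frequency approaches the target
    first-order with time constant ``tracking_lag``, plus filtered jitter.
    """
    if sc.duration + 1e-9 < plan.scheduled_duration:
        raise ConfigError(
            f"scenario duration {sc.duration} s shorter than the "
            f"{plan.scheduled_duration} s session"
        )
    rng = np.random.default_rng(sc.seed)
    n = int(round(sc.duration * sc.sample_rate))
    dt = 1.0 / sc.sample_rate
    t = np.arange(n) * dt

    target = np.full(n, sc.f_tremor)
    r = sc.responsiveness
    in1 = (t >= plan.baseline_end) & (t < plan.phase1_end)
    in2 = t >= plan.phase1_end
    target[in1] = r * plan.phase1_frequency + (1 - r) * sc.f_tremor
    target[in2] = r * plan.phase2_frequency + (1 - r) * sc.f_tremor

    if sc.tracking_lag <= dt:
        inst_freq = target.copy()
    else:
        # first-order relaxation as an IIR filter on the deviation from f_tremor
        a = 1.0 - np.exp(-dt / sc.tracking_lag)
        inst_freq = sc.f_tremor + sp_signal.lfilter(
            [a], [1.0, -(1.0 - a)], target - sc.f_tremor
        )
    inst_freq = inst_freq + _filtered_jitter(sc, n, rng)
    return _synthesize(sc, inst_freq, rng)
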