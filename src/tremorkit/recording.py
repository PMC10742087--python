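"""3-axis accelerometer recordings: container, reader, writer.

The on-disk format is delimited text with a header line ``t,x,y,z`` (comma
or tab, auto-detected): ``t`` in seconds on a uniform grid, ``x``/``y``/``z``
acceleration in m/s².  Irregularly sampled streams are rejected rather than
resampled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import RecordingError

#: Allowed deviation of each time step from 1/sample_rate, in seconds.
UNIFORMITY_TOL = 1e-6

_COLUMNS = ("t", "x", "y", "z")


@dataclass(frozen=True)
class AccelerometerRecording:
    """Uniformly sampled 3-axis acceleration time series.

    Parameters
    ----------
    sample_rate : float
        Sampling frequency in Hz.
    time : ndarray
        Seconds from recording start, strictly increasing, uniform grid.
    ax, ay, az : ndarray
        Acceleration in m/s² along the device x/y/z axes.
    """

    sample_rate: float
    time: np.ndarray = field(repr=False)
    ax: np.ndarray = field(repr=False)
    ay: np.ndarray = field(repr=False)
    az: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        for name in ("time", "ax", "ay", "az"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.ndim != 1:
                raise RecordingError(f"{name} must be one-dimensional")
        n = self.time.size
        if n < 1:
            raise RecordingError("recording is empty")
        if any(getattr(self, a).size != n for a in ("ax", "ay", "az")):
            raise RecordingError("time and axis series lengths differ")
        if not self.sample_rate > 0:
            raise RecordingError(f"sample_rate must be positive, got {self.sample_rate}")
        if n > 1:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                raise RecordingError("non-monotonic time")
            if np.any(np.abs(dt - 1.0 / self.sample_rate) > UNIFORMITY_TOL):
                raise RecordingError(
                    "non-uniform sampling: time spacing deviates from "
                    f"1/{self.sample_rate} Hz by more than {UNIFORMITY_TOL} s"
                )

    @property
    def n_samples(self) -> int:
        return int(self.time.size)

    @property
    def duration(self) -> float:
        """Recording length in seconds (n_samples / sample_rate)."""
        return self.n_samples / self.sample_rate

    def truncated(self, duration: float) -> "AccelerometerRecording":
        """Return the prefix covering at most `duration` seconds."""
        n = min(self.n_samples, int(round(duration * self.sample_rate)))
        if n < 1:
            raise RecordingError("truncation would leave an empty recording")
        return AccelerometerRecording(
            sample_rate=self.sample_rate,
            time=self.time[:n],
            ax=self.ax[:n],
            ay=self.ay[:n],
            az=self.az[:n],
        )


def _detect_delimiter(header: str) -> str:
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    raise RecordingError("could not detect delimiter (expected comma or tab)")


def load_recording(path, expected_rate: float | None = None) -> AccelerometerRecording:
    """Read a ``t,x,y,z`` delimited-text file into a validated recording.

    When `expected_rate` is omitted the sample rate is inferred from the
    median time spacing; either way the time grid must be uniform within
    :data:`UNIFORMITY_TOL`.
    """
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().strip()
        if not header:
            raise RecordingError(f"{path}: empty file")
        delim = _detect_delimiter(header)
        names = tuple(c.strip().lower() for c in header.split(delim))
        if names != _COLUMNS:
            raise RecordingError(
                f"{path}: expected header {','.join(_COLUMNS)!r}, got {header!r}"
            )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)  # empty-input warning
                data = np.loadtxt(fh, delimiter=delim, ndmin=2)
        except ValueError as exc:
            raise RecordingError(f"{path}: malformed data line ({exc})") from exc
    if data.size == 0:
        raise RecordingError(f"{path}: no data rows")
    if data.shape[1] != 4:
        raise RecordingError(f"{path}: expected 4 columns, got {data.shape[1]}")
    t = data[:, 0]
    if t.size > 1:
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise RecordingError(f"{path}: non-monotonic time")
        # span-based estimate averages out per-line rounding of t values
        rate = (
            expected_rate
            if expected_rate is not None
            else (t.size - 1) / float(t[-1] - t[0])
        )
    else:
        if expected_rate is None:
            raise RecordingError(f"{path}: cannot infer sample rate from one sample")
        rate = expected_rate
    return AccelerometerRecording(
        sample_rate=rate, time=t, ax=data[:, 1], ay=data[:, 2], az=data[:, 3]
    )


def write_recording(rec: AccelerometerRecording, path) -> None:
    """Write a recording in the ``t,x,y,z`` comma format read by
    :func:`load_recording`; values round-trip within 1e-9."""
    data = np.column_stack([rec.time, rec.ax, rec.ay, rec.az])
    try:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(",".join(_COLUMNS) + "\n")
            np.savetxt(fh, data, fmt="%.9f", delimiter=",")
    except FileNotFoundError as exc:
        raise RecordingError(f"cannot write {path}: {exc}") from exc
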