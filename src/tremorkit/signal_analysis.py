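"""Dominant-frequency estimation from accelerometer oscillation signals.

Three axes are reduced to one zero-mean scalar series (Euclidean magnitude
by default, orientation-independent), a Hann-tapered, zero-padded FFT power
spectrum is evaluated on a grid at least as fine as ``min_resolution``, and
the dominant frequency is the in-band grid point of maximal power.  A peak
counts as *significant* when its power exceeds ``prominence_factor`` times
the median in-band power — a simple scale-free criterion that rejects the
flat spectrum of noise-only input.  Sliding-window application of the same
estimator yields a frequency trace for continuous movement tracking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sp_fft

from .errors import AnalysisError
from .recording import AccelerometerRecording

DEFAULT_BAND = (1.0, 12.0)  # physiological tremor search band, Hz
DEFAULT_MIN_RESOLUTION = 0.1  # Hz
DEFAULT_PROMINENCE = 5.0
DEFAULT_WINDOW = 3.0  # s, >= 3 cycles at the 1 Hz band floor
DEFAULT_HOP = 0.5  # s


@dataclass(frozen=True)
class SpectralEstimate:
    """Dominant frequency from one analysis window.

    `significant` is False when no in-band peak passed the prominence
    criterion; `dominant_frequency` is still reported but should not be
    trusted in that case.
    """

    dominant_frequency: float
    peak_power: float
    band_low: float
    band_high: float
    resolution: float
    significant: bool


@dataclass(frozen=True)
class FrequencyTrace:
    """Per-window dominant frequencies; NaN marks non-significant windows."""

    window_centers: np.ndarray = field(repr=False)
    frequencies: np.ndarray = field(repr=False)
    window_length: float
    hop: float

    def __post_init__(self) -> None:
        wc = np.asarray(self.window_centers, dtype=float)
        fr = np.asarray(self.frequencies, dtype=float)
        object.__setattr__(self, "window_centers", wc)
        object.__setattr__(self, "frequencies", fr)
        if wc.size != fr.size:
            raise AnalysisError("window_centers and frequencies lengths differ")
        if wc.size > 1 and np.any(np.diff(wc) <= 0):
            raise AnalysisError("window_centers must be strictly increasing")

    def __len__(self) -> int:
        return int(self.window_centers.size)

    def defined(self) -> np.ndarray:
        """Boolean mask of windows with a significant frequency estimate."""
        return ~np.isnan(self.frequencies)

    def shifted(self, offset: float) -> "FrequencyTrace":
        """Trace with all window centers displaced by `offset` seconds."""
        return FrequencyTrace(
            self.window_centers + offset, self.frequencies, self.window_length, self.hop
        )


def combine_axes(rec: AccelerometerRecording, method: str = "magnitude") -> np.ndarray:
    """Reduce a 3-axis recording to one zero-mean scalar series (m/s²).

    ``magnitude``: per-sample Euclidean norm of (ax, ay, az), mean-subtracted
    — orientation-independent and insensitive to the gravity offset.
    ``dominant_axis``: the single mean-subtracted axis of greatest variance.
    """
    if method == "magnitude":
        mag = np.sqrt(rec.ax**2 + rec.ay**2 + rec.az**2)
        return mag - mag.mean()
    if method == "dominant_axis":
        axes = np.stack([rec.ax, rec.ay, rec.az])
        best = axes[int(np.argmax(np.var(axes, axis=1)))]
        return best - best.mean()
    raise AnalysisError(f"unknown axis-combination method {method!r}")


def _spectrum(
    series: np.ndarray, sample_rate: float, min_resolution: float
) -> tuple[np.ndarray, np.ndarray, float]:
    """Hann-tapered, zero-padded one-sided power spectrum.

    Returns (frequencies, power, resolution) with resolution <= min_resolution.
    """
    x = np.asarray(series, dtype=float)
    x = x - x.mean()
    n = x.size
    nfft = max(n, int(np.ceil(sample_rate / min_resolution)))
    nfft = sp_fft.next_fast_len(nfft)
    coeffs = sp_fft.rfft(x * np.hanning(n), n=nfft)
    power = np.abs(coeffs) ** 2
    freqs = sp_fft.rfftfreq(nfft, d=1.0 / sample_rate)
    return freqs, power, sample_rate / nfft


def estimate_dominant_frequency(
    series: np.ndarray,
    sample_rate: float,
    band_low: float = DEFAULT_BAND[0],
    band_high: float = DEFAULT_BAND[1],
    min_resolution: float = DEFAULT_MIN_RESOLUTION,
    prominence_factor: float = DEFAULT_PROMINENCE,
) -> SpectralEstimate:
    """Estimate the dominant in-band frequency of a zero-mean series.

    The series must span at least two cycles of `band_low`.  Ties in the
    power argmax resolve to the lowest frequency.
    """
    series = np.asarray(series, dtype=float)
    if not 0 < band_low < band_high:
        raise AnalysisError(f"invalid band [{band_low}, {band_high}] Hz")
    if band_high >= sample_rate / 2:
        raise AnalysisError(
            f"band_high {band_high} Hz is not below the Nyquist frequency "
            f"{sample_rate / 2} Hz"
        )
    min_len = 2 * sample_rate / band_low
    if series.size < min_len:
        raise AnalysisError(
            f"series too short: {series.size} samples < {min_len:.0f} needed "
            f"for two cycles at {band_low} Hz"
        )
    freqs, power, resolution = _spectrum(series, sample_rate, min_resolution)
    in_band = (freqs >= band_low) & (freqs <= band_high)
    band_power = power[in_band]
    peak_idx = int(np.argmax(band_power))  # first occurrence: lowest f wins ties
    peak_power = float(band_power[peak_idx])
    dominant = float(freqs[in_band][peak_idx])
    median_power = float(np.median(band_power))
    significant = bool(peak_power >= prominence_factor * median_power)
    return SpectralEstimate(
        dominant_frequency=dominant,
        peak_power=peak_power,
        band_low=band_low,
        band_high=band_high,
        resolution=resolution,
        significant=significant,
    )


def track_frequency(
    series: np.ndarray,
    sample_rate: float,
    window_length: float = DEFAULT_WINDOW,
    hop: float = DEFAULT_HOP,
    band_low: float = DEFAULT_BAND[0],
    band_high: float = DEFAULT_BAND[1],
    prominence_factor: float = DEFAULT_PROMINENCE,
    min_resolution: float = DEFAULT_MIN_RESOLUTION,
) -> FrequencyTrace:
    """Dominant frequency in sliding windows of `window_length` seconds
    advanced by `hop` seconds; non-significant windows are NaN."""
    series = np.asarray(series, dtype=float)
    if window_length <= 0 or hop <= 0:
        raise AnalysisError("window_length and hop must be positive")
    win = int(round(window_length * sample_rate))
    if series.size < win:
        raise AnalysisError(
            f"series of {series.size / sample_rate:.1f} s shorter than "
            f"window_length {window_length} s"
        )
    step = int(round(hop * sample_rate))
    starts = np.arange(0, series.size - win + 1, step)
    centers = (starts + win / 2) / sample_rate
    freqs = np.empty(starts.size)
    for i, s in enumerate(starts):
        est = estimate_dominant_frequency(
            series[s : s + win],
            sample_rate,
            band_low=band_low,
            band_high=band_high,
            min_resolution=min_resolution,
            prominence_factor=prominence_factor,
        )
        freqs[i] = est.dominant_frequency if est.significant else np.nan
    return FrequencyTrace(centers, freqs, window_length, hop)
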