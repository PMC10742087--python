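"""Shared fixtures and the independent brute-force spectral oracle."""

from __future__ import annotations

import numpy as np
import pytest

from tremorkit import ProtocolConfig


@pytest.fixture
def cfg() -> ProtocolConfig:
    return ProtocolConfig()


@pytest.fixture
def wide_cfg() -> ProtocolConfig:
    """Config whose clamps never bind for baseline frequencies up to 12 Hz."""
    return ProtocolConfig(f_min=0.1, f_max=12.0, band_high=12.0)


def sine_series(freq: float, duration: float, rate: float, amplitude: float = 1.0,
                phase: float = 0.0) -> np.ndarray:
    t = np.arange(int(round(duration * rate))) / rate
    return amplitude * np.sin(2 * np.pi * freq * t + phase)


def dense_dft_peak(series: np.ndarray, sample_rate: float, resolution: float,
                   band_low: float, band_high: float) -> float:
    """Independent O(n²) oracle: Hann-tapered power evaluated term by term
    on the uniform frequency grid of the given resolution; returns the
    in-band frequency of maximal power (lowest frequency on ties)."""
    x = np.asarray(series, dtype=float)
    x = (x - x.mean()) * np.hanning(x.size)
    j = np.arange(x.size)
    freqs = np.arange(0.0, sample_rate / 2 + resolution / 2, resolution)
    in_band = freqs[(freqs >= band_low) & (freqs <= band_high)]
    best_f, best_p = in_band[0], -1.0
    for f in in_band:
        c = np.sum(x * np.cos(2 * np.pi * f * j / sample_rate))
        s = np.sum(x * np.sin(2 * np.pi * f * j / sample_rate))
        p = c * c + s * s
        if p > best_p:  # strict: first (lowest) frequency wins ties
            best_f, best_p = f, p
    return float(best_f)
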