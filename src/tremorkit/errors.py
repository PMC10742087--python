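"""Exception hierarchy.

All validation failures raise subclasses of :class:`TremorKitError` so the
CLI can map them onto distinct exit codes.
"""


class TremorKitError(Exception):
    """Base class for all tremorkit errors."""


class RecordingError(TremorKitError, ValueError):
    """Invalid accelerometer recording (file format, time axis, sampling)."""


class ConfigError(TremorKitError, ValueError):
    """Invalid protocol configuration or scenario file."""


class AnalysisError(TremorKitError, ValueError):
    """Invalid spectral-analysis request (band, window, series length)."""


class SessionLogError(TremorKitError, ValueError):
    """Malformed session log or inconsistent log entries."""
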