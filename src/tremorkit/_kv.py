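"""Flat key-value config parsing shared by protocol and scenario files.

Format: one ``key = value`` per line; blank lines and ``#`` comments
ignored; keys must exactly match the target dataclass field names.
"""

from __future__ import annotations

import dataclasses
import typing

from .errors import ConfigError


def parse_kv_file(path) -> dict[str, str]:
    pairs: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            if key in pairs:
                raise ConfigError(f"{path}:{lineno}: duplicate key {key!r}")
            pairs[key] = value
    return pairs


def coerce_fields(cls, pairs: dict[str, str], path="<config>") -> dict[str, object]:
    """Convert string values to the field types of dataclass `cls`.

    Unknown keys are rejected.  Handles int, float, bool, str and
    tuple-of-float fields (comma-separated).
    """
    hints = typing.get_type_hints(cls)
    fields = {f.name: hints[f.name] for f in dataclasses.fields(cls)}
    out: dict[str, object] = {}
    for key, value in pairs.items():
        if key not in fields:
            raise ConfigError(f"{path}: unknown key {key!r}")
        ftype = fields[key]
        try:
            if ftype is bool:
                if value.lower() in ("true", "1", "yes"):
                    out[key] = True
                elif value.lower() in ("false", "0", "no"):
                    out[key] = False
                else:
                    raise ValueError(f"not a boolean: {value!r}")
            elif ftype is int:
                out[key] = int(value)
            elif ftype is float:
                out[key] = float(value)
            elif ftype is str:
                out[key] = value
            else:  # tuple of floats, e.g. axis weights
                out[key] = tuple(float(v) for v in value.split(","))
        except ValueError as exc:
            raise ConfigError(f"{path}: bad value for {key!r}: {exc}") from exc
    return out
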