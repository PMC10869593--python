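"""Plain-text (YAML) configuration for trials and scans.

The YAML mirrors the dataclass tree: top-level TrialConfig fields, with
nested ``ensemble``, ``pulse`` and ``tuner`` sections.  Unknown keys
are rejected so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import asdict, fields
from pathlib import Path

import yaml

from .ensemble import EnsembleParams
from .experiment import TrialConfig
from .pulses import PulseShape
from .tuner import TunerParams

__all__ = ["load_config", "save_config"]

_SECTIONS = {"ensemble": EnsembleParams, "pulse": PulseShape,
             "tuner": TunerParams}


def _build(cls, data: dict):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


def load_config(path) -> TrialConfig:
    """Read a TrialConfig from a YAML file (missing keys -> defaults)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in raw:
            kwargs[name] = _build(cls, raw.pop(name) or {})
    allowed = {f.name for f in fields(TrialConfig)}
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs.update(raw)
    return _build(TrialConfig, kwargs)


def save_config(config: TrialConfig, path) -> None:
    """Write the full parameter set (a reproducibility snapshot)."""
    Path(path).write_text(
        yaml.safe_dump(asdict(config), sort_keys=False))
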