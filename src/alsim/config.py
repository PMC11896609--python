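"""Shared YAML/JSON configuration.

One config file can carry the circuit exclusion list, sensitivity
multipliers, drive parameters, and stimulus protocol::

    excluded_glomeruli: [VP1d, VP1l, VP1m, VP2, VP3, VP4, VP5]
    sensitivities: {a_orn: 0.1, a_eln: 0.04, a_iln: 0.02, a_pn: 0.4}
    drive: {fr_max: 400, f_a: 0.75, t_a: 110, spontaneous_rate: 10}
    protocol: {odors: [OCT, MCH], on_duration: 400, gap_duration: 300, lead_in: 300}

Unspecified sections fall back to package defaults.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .circuit_model import DEFAULT_EXCLUDED_GLOMERULI, SensitivityConfig
from .odor_drive import DriveParams, StimulusProtocol

__all__ = [
    "load_config",
    "sensitivities_from_config",
    "drive_from_config",
    "protocol_from_config",
    "excluded_glomeruli_from_config",
]


def load_config(path) -> dict:
    """Read a YAML or JSON config file into a dict."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text) or {}


def sensitivities_from_config(cfg: dict) -> SensitivityConfig:
    return SensitivityConfig(**cfg.get("sensitivities", {}))


def drive_from_config(cfg: dict) -> DriveParams:
    return DriveParams(**cfg.get("drive", {}))


def protocol_from_config(cfg: dict) -> StimulusProtocol:
    section = dict(cfg.get("protocol", {}))
    if "odors" not in section:
        raise KeyError("protocol config requires an 'odors' list")
    section["odors"] = tuple(section["odors"])
    return StimulusProtocol(**section)


def excluded_glomeruli_from_config(cfg: dict) -> tuple[str, ...]:
    return tuple(cfg.get("excluded_glomeruli", DEFAULT_EXCLUDED_GLOMERULI))
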