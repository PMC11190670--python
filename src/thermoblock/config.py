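"""Run configuration, validation, results ledger and outcome serialization.

Configs are flat YAML/JSON mappings validated before any simulation starts;
outcomes are JSON documents carrying a full config echo so every artifact is
reproducible from its own metadata. Units follow the package conventions:
mV, ms, nA, degC, mm (geometry), um (diameter).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .membrane import MembraneParams, MODIFIED, ORIGINAL

__all__ = ["RunConfig", "ConfigError", "load_config", "write_outcome",
           "settings_hash", "results_ledger_append", "write_trace_csv"]

PROTOCOLS = ("simulate", "block-length", "block-temp", "threshold-current",
             "scaling", "snapshot", "repetitive", "calibrate", "synth")


class ConfigError(ValueError):
    """Raised when a run configuration fails validation."""


_SCHEMA = {
    # field: (type(s), required, validator or None)
    "protocol": (str, True, lambda v: v in PROTOCOLS),
    "variant": (str, False, lambda v: v in (MODIFIED, ORIGINAL)),
    "diameter_um": ((int, float), False, lambda v: 0.1 <= v <= 1000),
    "length_mm": ((int, float), False, lambda v: v > 0),
    "dt_ms": ((int, float), False, lambda v: v > 0),
    "temperature_c": ((int, float), False, None),
    "flank_temp_c": ((int, float), False, None),
    "central_temp_c": ((int, float), False, None),
    "central_length_mm": ((int, float), False, lambda v: v > 0),
    "placement": (str, False, lambda v: v in ("centered", "midpoint", "initial")),
    "stimulus_na": ((int, float), False, None),
    "stimulus_width_ms": ((int, float), False, lambda v: v > 0),
    "pulse_width_ms": ((int, float), False, lambda v: v > 0),
    "diameters_um": (list, False, None),
    "kind": (str, False, None),
    "drive": (str, False, lambda v: v in ("steady", "pulse-train")),
    "t_end_ms": ((int, float), False, lambda v: v > 0),
    "probes_mm": (list, False, None),
    "seed": (int, False, None),
    "noise_sd": ((int, float), False, lambda v: v >= 0),
    "temperatures_c": (list, False, None),
    "reference_csv": (str, False, None),
    "output": (str, False, None),
    "trace_csv": (str, False, None),
    "block": (bool, False, None),
}


@dataclass
class RunConfig:
    """Validated flat configuration for one protocol run."""

    data: dict = field(default_factory=dict)

    def __post_init__(self):
        if "protocol" not in self.data:
            raise ConfigError("missing required field 'protocol'")
        for key, value in self.data.items():
            if key not in _SCHEMA:
                raise ConfigError(f"unknown field '{key}'")
            types, _req, check = _SCHEMA[key]
            if not isinstance(value, types) or isinstance(value, bool) != (
                    types is bool or (isinstance(types, tuple) and bool in types)):
                if not isinstance(value, types):
                    raise ConfigError(
                        f"field '{key}' has invalid type {type(value).__name__}")
            if check is not None and not check(value):
                raise ConfigError(f"field '{key}' has invalid value {value!r}")

    def get(self, key, default=None):
        return self.data.get(key, default)

    def __getitem__(self, key):
        return self.data[key]

    @property
    def protocol(self) -> str:
        return self.data["protocol"]

    def membrane_params(self) -> MembraneParams:
        return MembraneParams(model_variant=self.get("variant", MODIFIED))


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    return RunConfig(raw)


def settings_hash(settings: dict) -> str:
    """Stable hash of a settings mapping (order-independent)."""
    canon = json.dumps(settings, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_outcome(path, name: str, value, units: str, config: dict,
                  extra: dict | None = None) -> dict:
    """Write a JSON outcome with a full config echo; returns the document."""
    doc = {
        "name": name,
        "value": value,
        "units": units,
        "config": dict(config),
        "settings_hash": settings_hash(config),
        "software_version": __version__,
    }
    if extra:
        doc.update(extra)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, default=str)
    return doc


LEDGER_COLUMNS = ["name", "value", "units", "settings_hash", "settings_json"]


def results_ledger_append(outcome, path) -> pd.DataFrame:
    """Append one ProtocolOutcome row to an append-only CSV ledger."""
    row = {
        "name": outcome.name,
        "value": outcome.value,
        "units": outcome.units,
        "settings_hash": settings_hash(outcome.settings),
        "settings_json": json.dumps(outcome.settings, sort_keys=True, default=str),
    }
    path = Path(path)
    if path.exists():
        ledger = pd.read_csv(path)
        if list(ledger.columns) != LEDGER_COLUMNS:
            raise ValueError(f"ledger at {path} has clashing schema")
        ledger = pd.concat([ledger, pd.DataFrame([row])], ignore_index=True)
    else:
        ledger = pd.DataFrame([row], columns=LEDGER_COLUMNS)
    ledger.to_csv(path, index=False)
    return ledger


def write_trace_csv(path, result) -> None:
    """Long-format (t, x, V) CSV of a result's probe traces."""
    frames = []
    for x, v in sorted(result.probe_v.items()):
        frames.append(pd.DataFrame({"t_ms": result.t, "x_mm": x, "v_mv": v}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
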