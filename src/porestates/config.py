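"""Run configuration: schemas, config-file loading, flag precedence.

Every CLI run is described by a :class:`RunConfig` that round-trips
losslessly through a plain dict, so an output's sidecar metadata is enough
to reproduce it.  Config files may be TOML or YAML; CLI flags always take
precedence over file values; unknown keys are rejected with a spelling
suggestion.
"""

from __future__ import annotations

import difflib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["RunConfig", "ConfigError", "load_config_file", "merge_config", "SCHEMAS"]


class ConfigError(ValueError):
    """A config file or flag set is invalid (unknown key, wrong type)."""


# allowed keys and their types, per subcommand
_KINETIC_KEYS: dict[str, type] = {
    "i": int,
    "k_coll": float,
    "k_hop": float,
    "k_exit": float,
    "k_enter": float,
    "a_l": float,
    "a_r": float,
    "tracer_fraction_l": float,
    "t_max": float,
    "burn_in": float,
    "n_batches": int,
    "seed": int,
}

SCHEMAS: dict[str, dict[str, type]] = {
    "census": {"i": int, "max_i": int, "out": str, "format": str},
    "ratio-table": {"i_list": str, "out": str, "format": str},
    "simulate": {**_KINETIC_KEYS, "oracle": bool, "out": str, "format": str, "trace": str},
    "ratio-scan": {
        **{k: v for k, v in _KINETIC_KEYS.items() if k != "i"},
        "i_list": str,
        "reps": int,
        "gradient_a_l": float,
        "out": str,
        "format": str,
    },
}


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved description of one CLI run."""

    subcommand: str
    parameters: dict[str, Any]
    seed: int | None = None
    output_path: str | None = None
    output_format: str = "csv"

    def to_dict(self) -> dict[str, Any]:
        return {
            "subcommand": self.subcommand,
            "parameters": dict(self.parameters),
            "seed": self.seed,
            "output_path": self.output_path,
            "output_format": self.output_format,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        return cls(
            subcommand=d["subcommand"],
            parameters=dict(d["parameters"]),
            seed=d.get("seed"),
            output_path=d.get("output_path"),
            output_format=d.get("output_format", "csv"),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


def load_config_file(path: str | Path) -> dict[str, Any]:
    """Parse a TOML (``.toml``) or YAML (``.yaml``/``.yml``) config file."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".toml":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    elif suffix in (".yaml", ".yml"):
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    else:
        raise ConfigError(f"unsupported config format {suffix!r} (use .toml or .yaml)")
    if not isinstance(data, dict):
        raise ConfigError("config file must define a mapping of keys to values")
    return data


def validate_keys(data: Mapping[str, Any], subcommand: str) -> dict[str, Any]:
    """Check keys and coerce values against the subcommand schema."""
    schema = SCHEMAS[subcommand]
    out: dict[str, Any] = {}
    for key, value in data.items():
        norm = key.replace("-", "_").lower()
        if norm not in schema:
            hint = difflib.get_close_matches(norm, schema, n=1)
            suggestion = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ConfigError(f"unknown config key {key!r} for {subcommand}{suggestion}")
        expected = schema[norm]
        if expected is float and isinstance(value, int) and not isinstance(value, bool):
            value = float(value)
        if not isinstance(value, expected) or (expected in (int, float) and isinstance(value, bool)):
            raise ConfigError(
                f"config key {key!r} expects {expected.__name__}, got {type(value).__name__}"
            )
        out[norm] = value
    return out


def merge_config(
    file_values: Mapping[str, Any],
    flag_values: Mapping[str, Any],
    flag_is_default: Mapping[str, bool],
) -> dict[str, Any]:
    """Resolve parameters: explicit flags beat file values beat defaults."""
    merged = dict(flag_values)
    for key, value in file_values.items():
        if flag_is_default.get(key, True):
            merged[key] = value
    return merged
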