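"""Run configuration: flat key-value files and strict parameter merging."""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Optional

import yaml

from .exceptions import ConfigError
from .kinetics import ModelParams

__all__ = ["load_config", "build_params"]

_PARAM_FIELDS = {f.name for f in dataclasses.fields(ModelParams)}


def load_config(path: str | Path) -> dict:
    """Read a flat key-value (YAML mapping) config file.

    Only :class:`~zigzag.kinetics.ModelParams` field names are accepted;
    unknown keys are rejected outright rather than silently ignored.
    """
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, Mapping):
        raise ConfigError(f"config {path} must be a flat key-value mapping")
    unknown = set(data) - _PARAM_FIELDS
    if unknown:
        raise ConfigError(
            f"unknown config key(s) in {path}: {', '.join(sorted(unknown))}"
        )
    return dict(data)


def build_params(
    config: Optional[Mapping] = None, overrides: Optional[Mapping] = None
) -> ModelParams:
    """Defaults < config file < explicit flags, validated at the end."""
    merged: dict = {}
    for source in (config, overrides):
        if source:
            merged.update({k: v for k, v in source.items() if v is not None})
    unknown = set(merged) - _PARAM_FIELDS
    if unknown:
        raise ConfigError(f"unknown parameter(s): {', '.join(sorted(unknown))}")
    try:
        return ModelParams(**merged)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
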