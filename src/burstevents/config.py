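"""Structured-text run configuration (JSON or YAML mapping)."""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .core import BurstParams, EventDurationModel, InvalidParameterError

__all__ = ["load_config", "params_from_config", "ConfigError"]

_PARAM_KEYS = {
    "tau_P", "tau_S1", "tau_S2", "tau_S3", "tau_S", "p1", "p2", "tau_m",
    "duration_models",
}


class ConfigError(ValueError):
    pass


def load_config(path) -> dict:
    """Load a JSON (or YAML) mapping from disk."""
    text = Path(path).read_text()
    try:
        obj = json.loads(text)
    except json.JSONDecodeError:
        obj = yaml.safe_load(text)
    if not isinstance(obj, dict):
        raise ConfigError("config must be a mapping")
    return obj


def params_from_config(cfg: dict) -> BurstParams:
    """Build :class:`BurstParams` from a config mapping.

    Either the component form (``tau_S1``, ``tau_S2``, ``tau_S3``, ``p2``) or
    the direct form (``tau_S``) may be used; unknown keys are rejected.
    """
    unknown = set(cfg) - _PARAM_KEYS
    if unknown:
        raise ConfigError(f"unknown parameter keys: {sorted(unknown)}")
    cfg = dict(cfg)
    models = None
    if "duration_models" in cfg:
        models = {
            kind: EventDurationModel(**spec)
            for kind, spec in cfg.pop("duration_models").items()
        }
    if "tau_S" in cfg:
        if {"tau_S1", "tau_S2", "tau_S3"} & set(cfg):
            raise ConfigError("give either tau_S or its components, not both")
        tau_S = cfg.pop("tau_S")
        cfg["tau_S1"] = tau_S
        cfg.setdefault("p2", 0.0)
    try:
        return BurstParams(duration_models=models, **cfg)
    except (TypeError, InvalidParameterError) as exc:
        raise ConfigError(str(exc)) from exc
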