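"""YAML configuration loading for the command-line interface.

A config file holds per-method sections whose keys mirror the config
dataclasses, e.g.::

    mcuve:
      n_runs: 500
      noise_amplitude: 0.001
    vcpa:
      edf_runs: 50
      omega: 14

Flat dotted keys (``mcuve.n_runs: 500``) are accepted as well.
"""

from __future__ import annotations

from dataclasses import fields
from typing import Any, TypeVar

import yaml

T = TypeVar("T")


def load_config(path) -> dict[str, Any]:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must hold a mapping")
    nested: dict[str, Any] = {}
    for key, value in raw.items():
        if "." in str(key):
            section, name = str(key).split(".", 1)
            nested.setdefault(section, {})[name] = value
        elif isinstance(value, dict):
            nested.setdefault(str(key), {}).update(value)
        else:
            nested[str(key)] = value
    return nested


def build_method_config(cfg: dict[str, Any], section: str, cls: type[T], **overrides) -> T:
    """Instantiate a method config dataclass from a config mapping."""
    params = dict(cfg.get(section, {}) or {})
    params.update({k: v for k, v in overrides.items() if v is not None})
    valid = {f.name for f in fields(cls)}
    unknown = set(params) - valid
    if unknown:
        raise ValueError(f"unknown {section} config keys: {sorted(unknown)}")
    return cls(**params)
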