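"""Declarative run configuration (YAML or JSON; JSON is a YAML subset)."""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .models import params_from_dict, params_to_dict

__all__ = ["load_config", "save_config", "params_from_config"]


def load_config(path) -> dict:
    """Load a flat key/value config; YAML and JSON dialects both accepted."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping of keys to values")
    return data


def save_config(data: dict, path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))


def params_from_config(data: dict):
    """Extract model parameters from a config mapping (ignores run keys)."""
    model = data.get("model")
    keys = {"gv": ("b", "d", "alpha", "beta", "omega"),
            "minimal": ("r", "alpha", "beta", "omega"),
            "threepool": ("tau", "gamma", "mu", "omega")}.get(model)
    if keys is None:
        raise ValueError("config must set model to one of gv | minimal | threepool")
    return params_from_dict({"model": model, **{k: data[k] for k in keys if k in data}})
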