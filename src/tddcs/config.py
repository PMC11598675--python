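"""YAML configuration: probe geometry, optics, correlator, fit and protocol
defaults in one file.

`load_config` merges a user file over the packaged defaults; `config_hash`
gives a stable digest recorded in run logs.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import yaml

__all__ = ["default_config", "load_config", "config_hash"]


def default_config() -> dict:
    with resources.files("tddcs.data").joinpath("default_config.yaml").open() as fh:
        return yaml.safe_load(fh)


def _merge(base: dict, over: dict) -> dict:
    out = dict(base)
    for k, v in over.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None) -> dict:
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            cfg = _merge(cfg, yaml.safe_load(fh) or {})
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(yaml.safe_dump(cfg, sort_keys=True).encode()).hexdigest()[:16]
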