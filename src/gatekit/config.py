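"""Configuration loading: packaged defaults deep-merged with user YAML."""

from __future__ import annotations

from importlib import resources

import yaml

from .structio import SelectionSpec

__all__ = ["load_config", "selection_from_config", "ConfigError"]


class ConfigError(ValueError):
    pass


def _deep_merge(base: dict, override: dict, path: str = "") -> dict:
    out = dict(base)
    for key, val in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise ConfigError(f"unknown config key: {here!r}")
        if isinstance(base[key], dict) and isinstance(val, dict):
            out[key] = _deep_merge(base[key], val, here)
        else:
            out[key] = val
    return out


def default_config() -> dict:
    text = (
        resources.files("gatekit.data") / "default_config.yaml"
    ).read_text()
    return yaml.safe_load(text)


def load_config(path=None) -> dict:
    """Load the packaged defaults, optionally merged with a user YAML.

    Unknown keys raise :class:`ConfigError` naming the offending key.
    """
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError(f"config root must be a mapping: {path}")
        cfg = _deep_merge(cfg, user)
    return cfg


def selection_from_config(cfg: dict, chains=None) -> SelectionSpec:
    sel = cfg["selection"]
    return SelectionSpec(
        segment_ranges={
            name: (int(lo), int(hi)) for name, (lo, hi) in sel["segments"].items()
        },
        backbone_atom_names=frozenset(sel["backbone_atoms"]),
        include_loops=bool(sel["include_loops"]),
        chains=tuple(chains) if chains is not None else None,
    )
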