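"""Study configuration: YAML-backed, with versioned defaults shipped in-package.

All analysis windows and electrode sets default to the study's registered
values; a user config YAML overrides keys by deep merge.  Every source of
randomness in a run derives from the single top-level ``seed``.
"""

from __future__ import annotations

import importlib.resources
from copy import deepcopy
from typing import Any

import yaml


class ConfigError(ValueError):
    pass


def _deep_merge(base: dict, override: dict) -> dict:
    out = deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = deepcopy(v)
    return out


def default_config() -> dict:
    text = importlib.resources.files("rewardsdt").joinpath("defaults.yaml").read_text()
    return yaml.safe_load(text)


def load_config(path: str | None = None, overrides: dict | None = None) -> dict:
    """Defaults, optionally merged with a user YAML and explicit overrides."""
    cfg = default_config()
    if path is not None:
        with open(path) as f:
            user = yaml.safe_load(f) or {}
        if not isinstance(user, dict):
            raise ConfigError("config file must contain a mapping")
        cfg = _deep_merge(cfg, user)
    if overrides:
        cfg = _deep_merge(cfg, overrides)
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    """Schema and range checks; raises ConfigError naming the offending key."""
    def need(path: str, typ, pred=None) -> Any:
        node = cfg
        for part in path.split("."):
            if not isinstance(node, dict) or part not in node:
                raise ConfigError(f"missing config key: {path}")
            node = node[part]
        if typ is float and isinstance(node, int):
            node = float(node)
        if not isinstance(node, typ):
            raise ConfigError(f"config key {path} must be {typ}")
        if pred is not None and not pred(node):
            raise ConfigError(f"config key {path} out of range: {node!r}")
        return node

    need("seed", int)
    need("n_participants", int, lambda n: n >= 1)
    sessions = need("sessions", list, lambda s: len(s) >= 1)
    for s in sessions:
        if s not in ("space_specific", "choice_specific"):
            raise ConfigError(f"unknown session type {s!r}")
    need("schedule.n_blocks", int, lambda n: n >= 1)
    need("schedule.trials_per_block", int, lambda n: n >= 10)
    need("observer.lapse_rate", float, lambda x: 0 <= x <= 0.1)
    need("eeg.iaf_hz", float, lambda x: 7.5 <= x <= 13)
    band = need("eeg.band_hz", list, lambda b: len(b) == 2 and 0 < b[0] < b[1])
    fs = need("eeg.fs_hz", int, lambda x: x > 0)
    if band[1] >= fs / 2:
        raise ConfigError("eeg.band_hz upper edge must be below Nyquist")
    need("gaze.fs_hz", int, lambda x: x > 0)
    need("dynamics.width", int, lambda x: x >= 1)
    need("dynamics.shift", int, lambda x: x >= 1)
    need("stats.alpha_cluster", float, lambda x: 0 < x < 1)
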