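"""Flat key-value run configuration, validated against a schema at load."""

from __future__ import annotations

import yaml

__all__ = ["DEFAULTS", "load_config"]

# key -> (type, validator). The config is deliberately flat.
_SCHEMA = {
    "radii": (list, lambda v: all(isinstance(x, (int, float)) and x >= 0 for x in v)),
    "primary_radius": ((int, float), lambda v: v >= 0),
    "cell_size": ((int, float), lambda v: v > 0),
    "gini_t_low": ((int, float), lambda v: 0 <= v <= 1),
    "gini_t_high": ((int, float), lambda v: 0 <= v <= 1),
    "connectivity": (int, lambda v: v in (4, 8)),
    "binarize_threshold": ((int, float), lambda v: 0 <= v <= 1),
    "screen_p": ((int, float), lambda v: 0 < v < 1),
    "screen_r": ((int, float), lambda v: 0 <= v < 1),
    "screen_partial": ((int, float), lambda v: 0 <= v < 1),
    "adjusted_r2": (bool, lambda v: True),
}

DEFAULTS = {
    "radii": [500.0, 1000.0, 1500.0],
    "primary_radius": 500.0,
    "cell_size": 100.0,
    "gini_t_low": 0.3,
    "gini_t_high": 0.5,
    "connectivity": 8,
    "binarize_threshold": 0.5,
    "screen_p": 0.001,
    "screen_r": 0.1,
    "screen_partial": 0.1,
    "adjusted_r2": True,
}


def load_config(path=None) -> dict:
    """Load a YAML config, overlaying DEFAULTS; unknown keys are errors."""
    cfg = dict(DEFAULTS)
    if path is None:
        return cfg
    with open(path, encoding="utf-8") as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ValueError("config must be a flat key-value mapping")
    for key, value in user.items():
        if key not in _SCHEMA:
            raise ValueError(f"unknown config key {key!r}")
        typ, check = _SCHEMA[key]
        if not isinstance(value, typ) or isinstance(value, bool) and typ is not bool:
            raise ValueError(f"config key {key!r}: wrong type {type(value).__name__}")
        if not check(value):
            raise ValueError(f"config key {key!r}: invalid value {value!r}")
        cfg[key] = value
    if not cfg["gini_t_low"] < cfg["gini_t_high"]:
        raise ValueError("gini_t_low must be < gini_t_high")
    return cfg
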