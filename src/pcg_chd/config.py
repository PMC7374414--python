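"""Nested pipeline configuration with YAML overrides.

Defaults are versioned here; a YAML file may override any subset but
unknown keys are rejected so typos fail loudly instead of silently
running with defaults.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

DEFAULTS: dict = {
    "seed": 0,
    "verbosity": 1,
    "emd": {
        "sd_threshold": 0.2,
        "max_imfs": 12,
        "max_sift_iters": 100,
        "on_shallow": "error",  # or "passthrough"
    },
    "ltp": {
        "half_width": 4,
        "phi": 0.1,
        "phi_mode": "relative",
        "n_bins": 10,
        "weight_convention": "standard",
    },
    "mfcc": {
        "win_ms": 30.0,
        "hop_ms": 10.0,
        "preemphasis": 0.97,
        "n_filters": 26,
        "n_coeffs": 13,
        "fft_size": None,
        "fmin": 0.0,
        "fmax": None,
        "include_c0": True,
    },
    "svm": {
        "kernel": "cubic",
        "kernel_scale": "automatic",
        "box_constraint": 1.0,
        "standardize": True,
    },
    "eval": {
        "folds": 10,
        "repeats": 100,
        "task": "multiclass",  # or "binary"
    },
}


def _merge(base: dict, override: dict, trail: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        here = f"{trail}{key}"
        if key not in base:
            raise KeyError(f"unknown config key: {here}")
        if isinstance(base[key], dict):
            if not isinstance(val, dict):
                raise TypeError(f"config key {here} must be a mapping")
            out[key] = _merge(base[key], val, trail=f"{here}.")
        else:
            out[key] = val
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Resolve the full configuration: defaults <- YAML file <- in-code overrides."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise TypeError(f"config file {path} must contain a mapping")
        cfg = _merge(cfg, loaded)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg
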