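"""Run configuration: defaults, YAML loading, strict key validation."""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

from .genome import ParameterError

__all__ = ["DEFAULT_CONFIG", "load_config", "ConfigError", "dump_default"]


class ConfigError(ParameterError):
    """Invalid or unknown configuration keys."""


# Fully-written default configuration; CLI flags override file values,
# file values override these built-ins.  Depth, bin size and sort purity
# of the emulated sort-seq experiment are free choices of the generator.
DEFAULT_CONFIG: dict = {
    "genome": {
        "n_chrom": 4,
        "chrom_length": 400000,
        "origin_spacing": 40000,
        "peri_offsets": [17500],
        "t_sigma": 4.0,
        "competence": 1.0,
        "t_jitter_sd": 1.0,
    },
    "kinetics": {
        "v": 1.5,  # fork velocity, kb/min
        "S_dur": 40.0,  # S-phase duration, min
        "mode": "deterministic",
        "n_cells": 500,
    },
    "mutant": {
        "cutoff_kb": 17.5,  # hidden-truth delayed-origin cutoff
        "delay_min": 10.0,
    },
    "sortseq": {
        "depth": 300,  # mean reads per bin
        "bin_width": 1000,
        "min_count": 10,
        "normalization": "quantile",
        "smooth_window_kb": 15.0,
    },
    "chip": {
        "depth": 300,
        "amplitude": 5.0,
        "rho": 0.3,
        "lambda_kb": 20.0,
        "peak_spacing": 10000,  # synthetic cohesin peak spacing, bp
        "min_input": 10,
        "min_separation_kb": 2.0,
        "threshold": None,
    },
    "fit": {
        "D_grid_kb": [0.0, 2.5, 5.0, 7.5, 10.0, 12.5, 15.0, 17.5, 20.0, 22.5,
                      25.0, 27.5, 30.0, 32.5, 35.0, 37.5, 40.0, 42.5, 45.0, 47.5, 50.0],
        "delta_grid_min": [0.0, 2.5, 5.0, 7.5, 10.0, 12.5, 15.0, 17.5, 20.0,
                           22.5, 25.0, 27.5, 30.0],
        "scoring_window_kb": 100.0,
    },
    "seed": 7,
}


def _check_keys(user: dict, defaults: dict, path: str = "") -> list[str]:
    bad = []
    for key, value in user.items():
        here = f"{path}.{key}" if path else str(key)
        if key not in defaults:
            bad.append(here)
        elif isinstance(defaults[key], dict) and isinstance(value, dict):
            bad.extend(_check_keys(value, defaults[key], here))
    return bad


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Merge built-in defaults, an optional YAML file, and overrides.

    Unknown keys anywhere in the hierarchy raise :class:`ConfigError`
    listing every offending key.
    """
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    for source in (path and yaml.safe_load(Path(path).read_text()), overrides):
        if not source:
            continue
        bad = _check_keys(source, DEFAULT_CONFIG)
        if bad:
            raise ConfigError(f"unknown configuration keys: {', '.join(sorted(bad))}")
        for section, value in source.items():
            if isinstance(value, dict):
                cfg[section].update(value)
            else:
                cfg[section] = value
    if not cfg["fit"]["D_grid_kb"] or not cfg["fit"]["delta_grid_min"]:
        raise ConfigError("fit.D_grid_kb and fit.delta_grid_min must be non-empty")
    return cfg


def dump_default(path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(DEFAULT_CONFIG, sort_keys=False))
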