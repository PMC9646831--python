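"""Study configuration: YAML file -> validated nested dict with explicit
defaults.

Every default is materialized into the resolved configuration so run
reports contain the complete parameter set (no silent defaults).
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

DEFAULT_CONFIG: dict = {
    "geometry": {
        "parent_width": 4.0e-3,
        "parent_length": 40.0e-3,
        "curvature": 50.0,  # 1/m -> 20 mm centerline radius
        "sac_shape": "circular_segment",
        "sac_neck_width": 4.0e-3,
        "sac_dome_radius": 3.0e-3,
        "sac_depth": None,  # derived from dome radius when None
        "sac_center_arc": None,  # mid-wall when None
        "coil_fill_fraction": 1.0,
    },
    "mesh": {
        "resolution": 5.0e-4,
        "kind": "auto",
    },
    "rheology": {
        "model": "casson",
        "density": 1060.0,
        "plasma_viscosity": 1.45e-3,
        "yield_coefficient": 0.185,
        "critical_hct": 0.1,
        "viscosity_exponent": -2.5,
        "gamma_min": 1.0e-3,
        "mu_inf_override": None,
        "tau_y_override": None,
    },
    "waveform": {
        "period": 0.8,
        "mean_velocity": 0.3,
        "harmonics": [
            [0.135, -1.9],
            [0.066, -2.8],
            [0.03, -3.7],
        ],
    },
    "coil": {
        "porosities": [0.79, 0.89],
        "wire_diameter": 2.5e-4,
        "permeability_override": None,
        "inertial_override": None,
    },
    "hct": [0.35, 0.45],
    "solver": {
        "dt": 1.6e-3,  # period/500
        "cycles_to_run": 3,
        "cycles_to_discard": 2,
        "pressure_velocity_scheme": "projection",
        "divergence_tolerance": 0.1,
        "nonlinear_tolerance": 1.0e-3,
        "max_inner_iterations": 1,
        "seed": None,
    },
    "postprocess": {
        "osi_threshold": 0.2,
        "osi_window_fraction": 0.25,
        "osi_noise_floor": 0.01,
        "iso_velocity_levels": [0.3, 0.4],
        "neck_samples": 65,
    },
    "study": {
        "include_uncoiled_baseline": False,
        "reference_condition": None,  # [eps, hct]; default: highest eps, hct
    },
    "grid_study": {
        "resolutions": [8.0e-4, 6.0e-4, 4.5e-4],
        "cycles_to_run": 2,
        "cycles_to_discard": 1,
        "target_change_percent": 1.0,
        "porosity": None,  # None -> uncoiled sac for the ladder
    },
    "output": {
        "directory": "sacflow_out",
    },
}


class ConfigError(ValueError):
    pass


def _deep_merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise ConfigError(f"unknown configuration key: {here}")
        if isinstance(base[key], dict) and isinstance(val, dict):
            out[key] = _deep_merge(base[key], val, here)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Resolved configuration: defaults <- YAML file <- overrides."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as f:
            user = yaml.safe_load(f) or {}
        if not isinstance(user, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        cfg = _deep_merge(cfg, user)
    if overrides:
        cfg = _deep_merge(cfg, overrides)
    _validate(cfg)
    return cfg


def _validate(cfg: dict) -> None:
    if not cfg["coil"]["porosities"]:
        raise ConfigError("coil.porosities must be a non-empty list")
    if not cfg["hct"]:
        raise ConfigError("hct must be a non-empty list")
    for eps in cfg["coil"]["porosities"]:
        if not 0.0 < eps < 1.0:
            raise ConfigError(f"porosity {eps} outside (0, 1)")
    for h in cfg["hct"]:
        if not 0.0 < h < 1.0:
            raise ConfigError(f"hct {h} outside (0, 1)")
    res = cfg["grid_study"]["resolutions"]
    if sorted(res, reverse=True) != list(res):
        raise ConfigError("grid_study.resolutions must be strictly decreasing (coarse to fine)")


def dump_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(cfg, f, sort_keys=True)
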