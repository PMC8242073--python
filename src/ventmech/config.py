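"""Run configuration: defaults, YAML round-trip, and config hashing."""

from __future__ import annotations

import hashlib
import json

import yaml

__all__ = ["default_config", "load_config", "save_config", "config_hash",
           "merge_config"]


def default_config():
    """Complete default configuration of the synthetic LV pipeline."""
    return {
        "geometry": {
            "base_radius_endo_mm": 20.0,
            "wall_thickness_mm": 11.0,
            "long_axis_mm": 48.0,
            "truncation_fraction": 0.5,
            "target_edge_len_mm": 6.0,
            "coarse_edge_len_mm": 10.0,
            "helix_endo_deg": 60.0,
            "helix_epi_deg": -60.0,
        },
        "material": {
            "c": 1.522,
            "alpha": 1.0,
            "A1": 12.0,
            "A2": 8.0,
            "A3": 26.0,
            "K_inc_factor": 3.0e3,   # K_inc = factor * c (incompressible)
            "K_inc_factor_compressible": 600.0,  # softer passive penalty in
            # the contraction-modulated law; keeps its calibration
            # well-conditioned while staying >> c (diastolic |J-1| ~ 2e-3)
            "K_floor_factor": 1.0e-2,
            "beta": 1.45,
            "gamma": 0.0,
            "mode": "incompressible",
        },
        "synth": {
            "EDV_mL": 60.0,
            "EF": 0.30,
            "P_ed_mmHg": 15.0,
            "P_peak_mmHg": 95.0,
            "HR_bpm": 90.0,
            "n_pv_samples": 120,
            "n_map_sites": 71,
            "apex_base_delay": 0.06,
            "map_jitter": 0.003,
            "infarct_fraction": 0.20,
            "seed": 1,
        },
        "activation": {
            "kind": "sync",          # sync | async
            "shape_a": 3.0,
            "width_scale": 1.2,
        },
        "calibration": {
            "n_cycle_steps": 24,
            "tol_V_active_mL": 0.1,
            "tol_V_passive_mL": 0.53,
            "J_target_mean": 0.90,
            "tol_J": 0.005,
            "T_max_kPa": 500.0,
            "klotz_An": 27.78,
            "klotz_Bn": 2.76,
        },
    }


def merge_config(base, override):
    """Overlay override onto base, rejecting unknown sections/keys."""
    out = {k: dict(v) for k, v in base.items()}
    defaults = default_config()
    for sec, vals in (override or {}).items():
        if sec not in defaults:
            raise KeyError(f"unknown config section {sec!r}")
        if not isinstance(vals, dict):
            raise KeyError(f"config section {sec!r} must be a mapping")
        for key in vals:
            if key not in defaults[sec]:
                raise KeyError(f"unknown config key {sec}.{key}")
        out.setdefault(sec, {}).update(vals)
    return out


def load_config(path=None, overrides=None):
    cfg = default_config()
    if path:
        with open(path) as fh:
            cfg = merge_config(cfg, yaml.safe_load(fh) or {})
    return merge_config(cfg, overrides)


def save_config(path, cfg):
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def config_hash(cfg):
    """Short deterministic hash recorded in every output."""
    blob = json.dumps(cfg, sort_keys=True, default=float).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
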