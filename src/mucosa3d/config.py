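"""Run configuration: one file drives the whole pipeline.

Every stage parameter lives in a single nested mapping that is validated —
with the offending key named — before any stage runs.  All randomness flows
from the single ``rng_seed``.
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any, Mapping

import yaml

from .phantom import PhantomSpec

__all__ = ["DEFAULT_CONFIG", "load_config", "validate_config", "make_phantom_spec"]

DEFAULT_CONFIG: dict[str, Any] = {
    "rng_seed": 0,
    "output_dir": "runs/default",
    "phantom": {
        "volume_extent": [600, 100, 168],
        "voxel_size": [2.0, 3.0, 2.0],
        "tissue_class": "normal",
        "n_slices": 100,
        "slice_thickness": 3.0,
        "epithelium_stain_period": 3,
        "period_offset": 0,
        "crypt_pitch": 100.0,
        "crypt_radius": 25.0,
        "crypt_distortion": 0.0,
        "vessel_radius_mean": 5.0,
        "vessel_radius_sd": 1.0,
        "vessel_wall_thickness": 3.0,
        "vessel_depth_range": [15.0, 250.0],
        "broken_wall_fraction": 0.1,
        "jitter_max_translation": 3.0,
        "jitter_max_rotation": 0.0,
        "noise_sd": 0.02,
        "sectioning_axis": "vertical_section",
        "vessel_layout": "straight",
        "n_vessels": 40,
        "include_crypts": True,
        "n_extravasation": 0,
    },
    "segmentation": {
        "method": "fixed",
        "threshold": 0.5,
        "closing_radius": 2,
        "min_object_area": 4,
    },
    "registration": {
        "max_rotation": 0.0,
        "rotation_step": 0.5,
        "max_shift": 15,
        "anchor": "middle",
    },
    "reconstruction": {
        "smoothing_window": 15,
        "depth_mode": "axis",
        "windows": [50.0, 100.0, 150.0],
    },
    "analysis": {
        "n_areas": 50,
        "max_depth": 400.0,
        "roi": None,  # None: line along x over the central fifth of y
        "visibility_source": "virtual_bli",
        "labels_csv": None,
        "contrast_threshold": 0.01,
        "visibility_scale": 40.0,
        "hard_cutoff": 80.0,
        "reconcile": False,
        "lateral_tolerance": 10.0,
    },
}


def _merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, Mapping) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def _check_unknown(cfg: Mapping, schema: Mapping, prefix: str = "") -> None:
    for key, value in cfg.items():
        if key not in schema:
            raise ValueError(f"unknown configuration key: {prefix}{key}")
        if isinstance(value, Mapping) and isinstance(schema[key], Mapping):
            _check_unknown(value, schema[key], prefix=f"{prefix}{key}.")


def validate_config(cfg: Mapping) -> None:
    """Validate stage parameters against their preconditions, naming the
    offending key in the error message."""
    _check_unknown(cfg, DEFAULT_CONFIG)

    def _require(cond: bool, key: str, msg: str) -> None:
        if not cond:
            raise ValueError(f"invalid value for {key}: {msg}")

    seg = cfg["segmentation"]
    _require(seg["closing_radius"] >= 0, "segmentation.closing_radius", "must be >= 0")
    _require(seg["min_object_area"] >= 0, "segmentation.min_object_area", "must be >= 0")
    _require(seg["method"] in ("fixed", "automatic"), "segmentation.method",
             "must be 'fixed' or 'automatic'")
    if seg["method"] == "fixed":
        _require(seg["threshold"] is not None, "segmentation.threshold",
                 "required for the fixed method")
    reg = cfg["registration"]
    _require(reg["max_rotation"] >= 0, "registration.max_rotation", "must be >= 0")
    _require(reg["rotation_step"] > 0, "registration.rotation_step", "must be > 0")
    _require(reg["max_shift"] >= 1, "registration.max_shift", "must be >= 1")
    rec = cfg["reconstruction"]
    _require(rec["smoothing_window"] >= 0, "reconstruction.smoothing_window", "must be >= 0")
    _require(rec["depth_mode"] in ("axis", "euclidean"), "reconstruction.depth_mode",
             "must be 'axis' or 'euclidean'")
    _require(all(w > 0 for w in rec["windows"]), "reconstruction.windows",
             "windows must be positive")
    ana = cfg["analysis"]
    _require(ana["n_areas"] >= 2, "analysis.n_areas", "must be >= 2")
    _require(ana["max_depth"] > 0, "analysis.max_depth", "must be > 0")
    _require(ana["visibility_scale"] > 0, "analysis.visibility_scale", "must be > 0")
    _require(ana["hard_cutoff"] > 0, "analysis.hard_cutoff", "must be > 0")
    _require(ana["lateral_tolerance"] >= 0, "analysis.lateral_tolerance", "must be >= 0")
    _require(ana["visibility_source"] in ("virtual_bli", "manual_label"),
             "analysis.visibility_source", "must be 'virtual_bli' or 'manual_label'")
    # phantom parameters are validated by PhantomSpec itself
    make_phantom_spec(cfg).validate()


def load_config(path=None, overrides: Mapping | None = None) -> dict:
    """Defaults, overlaid with a YAML file and then explicit overrides;
    validated before returning."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        cfg = _merge(cfg, loaded)
    if overrides:
        cfg = _merge(cfg, overrides)
    validate_config(cfg)
    return cfg


def make_phantom_spec(cfg: Mapping) -> PhantomSpec:
    p = cfg["phantom"]
    return PhantomSpec(
        volume_extent=tuple(p["volume_extent"]),
        voxel_size=tuple(p["voxel_size"]),
        tissue_class=p["tissue_class"],
        n_slices=p["n_slices"],
        slice_thickness=p["slice_thickness"],
        epithelium_stain_period=p["epithelium_stain_period"],
        period_offset=p["period_offset"],
        crypt_pitch=p["crypt_pitch"],
        crypt_radius=p["crypt_radius"],
        crypt_distortion=p["crypt_distortion"],
        vessel_radius_mean=p["vessel_radius_mean"],
        vessel_radius_sd=p["vessel_radius_sd"],
        vessel_wall_thickness=p["vessel_wall_thickness"],
        vessel_depth_range=tuple(p["vessel_depth_range"]),
        broken_wall_fraction=p["broken_wall_fraction"],
        jitter_max_translation=p["jitter_max_translation"],
        jitter_max_rotation=p["jitter_max_rotation"],
        noise_sd=p["noise_sd"],
        rng_seed=int(cfg["rng_seed"]),
        sectioning_axis=p["sectioning_axis"],
        vessel_layout=p["vessel_layout"],
        n_vessels=p["n_vessels"],
        include_crypts=p["include_crypts"],
        n_extravasation=p["n_extravasation"],
    )
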