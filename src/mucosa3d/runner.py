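"""Pipeline orchestration: simulate → segment → register → reconstruct →
project → analyze, with a run manifest for reproducibility.

Each stage reads its inputs from and writes its outputs to the run
directory, so stages can be re-run individually from the command line; the
manifest records the configuration, the seed, the software version and a
SHA-256 hash of every output file, and is written atomically at run end.
Deterministic stages reproduce identical hashes for the same configuration
and seed.
"""

from __future__ import annotations

import json
import logging
import os
import time
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from . import __version__
from .config import make_phantom_spec
from .io import (
    read_section_series,
    read_transforms,
    save_projection,
    save_volume,
    load_volume,
    sha256_file,
    write_ground_truth,
    write_section_series,
    write_transforms,
)
from .phantom import build_phantom, render_virtual_bli, section_volume
from .reconstruction import (
    LabeledVolume,
    compute_depth_field,
    depth_window_projection,
    extract_surface,
    stack,
)
from .registration import register_series
from .segmentation import component_report, fill_vessel_lumens, segment_epithelium, segment_positive
from .visibility import (
    divide_roi,
    label_visibility,
    mann_whitney_u,
    measure_area_depths,
    plot_area_depths,
    reconcile_gaps,
    records_to_frame,
    summarize,
)

log = logging.getLogger("mucosa3d")

__all__ = ["run_stage", "run_pipeline", "STAGES"]

STAGES = ("simulate", "segment", "register", "reconstruct", "project", "analyze")


class _Manifest:
    def __init__(self, cfg: Mapping, outdir: Path):
        self.data: dict[str, Any] = {
            "software": {"name": "mucosa3d", "version": __version__},
            "seed": cfg["rng_seed"],
            "config": json.loads(json.dumps(cfg)),
            "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "stages": {},
        }
        self.outdir = outdir

    def record(self, stage: str, outputs: list[Path], seconds: float) -> None:
        self.data["stages"][stage] = {
            "seconds": round(seconds, 3),
            "outputs": {str(p.relative_to(self.outdir)): sha256_file(p) for p in outputs},
        }

    def write(self) -> Path:
        self.data["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        path = self.outdir / "manifest.json"
        tmp = path.with_suffix(".json.tmp")
        tmp.write_text(json.dumps(self.data, indent=1))
        os.replace(tmp, path)
        return path


def _masks_path(outdir: Path) -> Path:
    return outdir / "masks.npz"


def _stage_simulate(cfg: Mapping, outdir: Path) -> list[Path]:
    spec = make_phantom_spec(cfg)
    volume, truth = build_phantom(spec)
    series = section_volume(volume, spec)
    write_section_series(series, outdir / "series.tif")
    write_ground_truth(truth, outdir / "ground_truth.csv", outdir / "true_surface.tif")
    ana = cfg["analysis"]
    bli = render_virtual_bli(volume, truth,
                             visibility_scale=ana["visibility_scale"],
                             hard_cutoff=ana["hard_cutoff"])
    np.save(outdir / "virtual_bli.npy", bli)
    return [outdir / "series.tif", outdir / "series.json", outdir / "ground_truth.csv",
            outdir / "true_surface.tif", outdir / "virtual_bli.npy"]


def _stage_segment(cfg: Mapping, outdir: Path) -> list[Path]:
    series = read_section_series(outdir / "series.tif")
    seg = cfg["segmentation"]
    vessel_masks: dict[str, np.ndarray] = {}
    epith_masks: dict[str, np.ndarray] = {}
    report = []
    for s in series.slices:
        if s.stain == "vessel_stain":
            m = segment_positive(s.image, method=seg["method"], threshold=seg["threshold"],
                                 pixel_size=s.pixel_size, stain=s.stain, slice_index=s.index)
            m = fill_vessel_lumens(m, closing_radius=seg["closing_radius"])
            vessel_masks[str(s.index)] = m.pixels
        else:
            m = segment_epithelium(s.image, min_object_area=seg["min_object_area"],
                                   method=seg["method"], threshold=seg["threshold"],
                                   pixel_size=s.pixel_size, slice_index=s.index)
            epith_masks[str(s.index)] = m.pixels
        report.append(m)
    np.savez_compressed(_masks_path(outdir),
                        **{f"v_{k}": v for k, v in vessel_masks.items()},
                        **{f"e_{k}": v for k, v in epith_masks.items()})
    component_report(report).to_csv(outdir / "segmentation_report.csv", index=False)
    return [_masks_path(outdir), outdir / "segmentation_report.csv"]


def _stage_register(cfg: Mapping, outdir: Path) -> list[Path]:
    series = read_section_series(outdir / "series.tif")
    reg = cfg["registration"]
    anchor = len(series) // 2 if reg["anchor"] == "middle" else int(reg["anchor"])
    chain = register_series(series, anchor=anchor, max_shift=reg["max_shift"])
    write_transforms(chain, outdir / "transforms.csv")
    return [outdir / "transforms.csv"]


def _stage_reconstruct(cfg: Mapping, outdir: Path) -> list[Path]:
    series = read_section_series(outdir / "series.tif")
    chain = read_transforms(outdir / "transforms.csv")
    with np.load(_masks_path(outdir)) as data:
        vessel_masks = {int(k[2:]): data[k] for k in data.files if k.startswith("v_")}
        epith_masks = {int(k[2:]): data[k] for k in data.files if k.startswith("e_")}
    volume = stack(series, chain, vessel_masks, epith_masks)
    save_volume(volume, outdir / "volume")
    rec = cfg["reconstruction"]
    surface = extract_surface(volume, smoothing_window=rec["smoothing_window"])
    field = compute_depth_field(volume, surface, mode=rec["depth_mode"])
    np.save(outdir / "surface_height.npy", surface.height)
    import pandas as pd

    pd.DataFrame(
        [{"component_id": cid,
          "x_um": field.centroids_um[cid][2], "y_um": field.centroids_um[cid][1],
          "z_um": field.centroids_um[cid][0], "depth_um": d}
         for cid, d in field.component_depths]
    ).to_csv(outdir / "component_depths.csv", index=False)
    return [outdir / "volume" / "epithelium.tif", outdir / "volume" / "vessel.tif",
            outdir / "volume" / "volume.json", outdir / "surface_height.npy",
            outdir / "component_depths.csv"]


def _recompute_field(cfg: Mapping, outdir: Path):
    rec = cfg["reconstruction"]
    volume = load_volume(outdir / "volume")
    surface = extract_surface(volume, smoothing_window=rec["smoothing_window"])
    field = compute_depth_field(volume, surface, mode=rec["depth_mode"])
    return volume, surface, field


def _stage_project(cfg: Mapping, outdir: Path) -> list[Path]:
    volume, _surface, field = _recompute_field(cfg, outdir)
    outputs = []
    for w in cfg["reconstruction"]["windows"]:
        proj = depth_window_projection(volume, field, window=w)
        path = outdir / f"projection_{int(w)}um.png"
        save_projection(proj, path)
        outputs.append(path)
    return outputs


def _stage_analyze(cfg: Mapping, outdir: Path) -> list[Path]:
    volume, _surface, field = _recompute_field(cfg, outdir)
    ana = cfg["analysis"]
    dy, dx = volume.voxel_size[1], volume.voxel_size[2]
    ny, nx = volume.vessel.shape[1:]
    roi = ana["roi"]
    if roi is None:
        band = 0.2 * ny * dy
        y_mid = 0.5 * ny * dy
        roi = (y_mid - band / 2, 0.0, y_mid + band / 2, nx * dx)
    grid = divide_roi(tuple(roi), ana["n_areas"], pixel_size=dx)
    records = measure_area_depths(grid, field, volume, max_depth=ana["max_depth"])
    if ana["visibility_source"] == "manual_label":
        if not ana["labels_csv"]:
            raise ValueError("analysis.labels_csv is required for manual labelling")
        records = label_visibility(records, grid, ana["labels_csv"])
    else:
        bli = np.load(outdir / "virtual_bli.npy")
        records = label_visibility(records, grid, bli, volume=volume,
                                   contrast_threshold=ana["contrast_threshold"])
    if ana["reconcile"]:
        records = reconcile_gaps(records, grid, field, volume,
                                 lateral_tolerance=ana["lateral_tolerance"],
                                 max_depth=ana["max_depth"])
    records_to_frame(records).to_csv(outdir / "area_records.csv", index=False)
    vis = [r.nearest_depth for r in records
           if r.visible and not r.excluded and r.nearest_depth is not None]
    inv = [r.nearest_depth for r in records
           if r.visible is False and not r.excluded and r.nearest_depth is not None]
    result: dict[str, Any] = {}
    if vis and inv:
        mwu = mann_whitney_u(vis, inv)
        summary = summarize(records)
        result = {
            "mann_whitney": {"U": mwu.U, "n_visible": mwu.n1, "n_invisible": mwu.n2,
                             "p_two_sided": mwu.p_two_sided, "method": mwu.method},
            "summary": {
                "median_visible_um": summary.median_visible,
                "median_invisible_um": summary.median_invisible,
                "range_visible_um": list(summary.range_visible),
                "range_invisible_um": list(summary.range_invisible),
                "boundary_estimate_um": summary.boundary_estimate,
                "n_corrected": summary.n_corrected,
                "n_excluded": summary.n_excluded,
                "n_censored": summary.n_censored,
            },
        }
    else:
        result = {"warning": "one visibility group is empty; no test performed"}
    (outdir / "analysis.json").write_text(json.dumps(result, indent=1))
    plot_area_depths(records, outdir / "area_depths.png")
    return [outdir / "area_records.csv", outdir / "analysis.json", outdir / "area_depths.png"]


_STAGE_FN = {
    "simulate": _stage_simulate,
    "segment": _stage_segment,
    "register": _stage_register,
    "reconstruct": _stage_reconstruct,
    "project": _stage_project,
    "analyze": _stage_analyze,
}


def run_stage(stage: str, cfg: Mapping, manifest: _Manifest | None = None) -> list[Path]:
    outdir = Path(cfg["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    outputs = _STAGE_FN[stage](cfg, outdir)
    dt = time.perf_counter() - t0
    log.info("stage %-11s %6.1f s  (%d outputs)", stage, dt, len(outputs))
    if manifest is not None:
        manifest.record(stage, outputs, dt)
    return outputs


def run_pipeline(cfg: Mapping, stages=STAGES) -> Path:
    """Run the requested stages in order and write the manifest; returns the
    manifest path."""
    outdir = Path(cfg["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(cfg, outdir)
    for stage in STAGES:
        if stage in stages:
            run_stage(stage, cfg, manifest)
    return manifest.write()
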