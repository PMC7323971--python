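"""File formats: section series, volumes, transforms, ground truth.

Serial-section series travel as a multi-page float32 TIFF plus a sidecar
JSON manifest carrying the per-slice stain schedule, true transforms and
the pixel size; nothing is inferred from file names.  A directory of
16-bit PNGs with an index CSV is supported as an interchange fallback
(intensities are quantised to 1/65535).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .phantom import PhantomGroundTruth, SectionSeries, SectionSlice
from .reconstruction import LabeledVolume, Projection
from .registration import RigidTransform2D, TransformChain

__all__ = [
    "write_section_series",
    "read_section_series",
    "write_section_series_png",
    "read_section_series_png",
    "save_volume",
    "load_volume",
    "save_projection",
    "write_transforms",
    "read_transforms",
    "write_ground_truth",
    "sha256_file",
]


def _series_manifest(series: SectionSeries) -> dict:
    return {
        "pixel_size_um": series.slices[0].pixel_size,
        "epithelium_stain_period": series.epithelium_stain_period,
        "period_offset": series.period_offset,
        "sectioning_axis": series.sectioning_axis,
        "slice_thickness_um": series.slice_thickness,
        "slices": [
            {
                "index": s.index,
                "stain": s.stain,
                "transform": {"dx": s.true_transform.dx, "dy": s.true_transform.dy,
                              "theta": s.true_transform.theta},
            }
            for s in series.slices
        ],
    }


def _series_from_manifest(man: dict, images: Iterable[np.ndarray]) -> SectionSeries:
    images = list(images)
    if len(images) != len(man["slices"]):
        raise ValueError(
            f"manifest lists {len(man['slices'])} slices but the stack holds {len(images)}"
        )
    px = float(man["pixel_size_um"])
    slices = []
    for img, entry in zip(images, man["slices"]):
        t = entry["transform"]
        slices.append(
            SectionSlice(
                index=int(entry["index"]),
                stain=str(entry["stain"]),
                image=np.asarray(img, dtype=np.float32),
                true_transform=RigidTransform2D(float(t["dx"]), float(t["dy"]), float(t["theta"])),
                pixel_size=px,
            )
        )
    series = SectionSeries(
        slices=slices,
        epithelium_stain_period=int(man["epithelium_stain_period"]),
        period_offset=int(man["period_offset"]),
        sectioning_axis=str(man["sectioning_axis"]),
        slice_thickness=float(man["slice_thickness_um"]),
    )
    series.validate()  # rejects schedule/shape inconsistencies
    return series


def write_section_series(series: SectionSeries, tiff_path, manifest_path=None) -> None:
    tiff_path = Path(tiff_path)
    manifest_path = Path(manifest_path) if manifest_path else tiff_path.with_suffix(".json")
    stack = np.stack([s.image.astype(np.float32) for s in series.slices])
    tifffile.imwrite(tiff_path, stack, photometric="minisblack")
    manifest_path.write_text(json.dumps(_series_manifest(series), indent=1))


def read_section_series(tiff_path, manifest_path=None) -> SectionSeries:
    tiff_path = Path(tiff_path)
    manifest_path = Path(manifest_path) if manifest_path else tiff_path.with_suffix(".json")
    man = json.loads(Path(manifest_path).read_text())
    stack = tifffile.imread(tiff_path)
    if stack.ndim == 2:
        stack = stack[None]
    return _series_from_manifest(man, stack)


def write_section_series_png(series: SectionSeries, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in series.slices:
        fname = f"slice_{s.index:04d}.png"
        img = np.clip(s.image, 0.0, 1.0)
        iio.imwrite(directory / fname, (img * 65535 + 0.5).astype(np.uint16))
        rows.append(
            {"index": s.index, "stain": s.stain, "filename": fname,
             "dx": s.true_transform.dx, "dy": s.true_transform.dy,
             "theta": s.true_transform.theta, "pixel_size_um": s.pixel_size}
        )
    pd.DataFrame(rows).to_csv(directory / "index.csv", index=False)
    meta = {
        "epithelium_stain_period": series.epithelium_stain_period,
        "period_offset": series.period_offset,
        "sectioning_axis": series.sectioning_axis,
        "slice_thickness_um": series.slice_thickness,
    }
    (directory / "series.json").write_text(json.dumps(meta, indent=1))


def read_section_series_png(directory) -> SectionSeries:
    directory = Path(directory)
    idx = pd.read_csv(directory / "index.csv").sort_values("index")
    meta = json.loads((directory / "series.json").read_text())
    slices = []
    for row in idx.itertuples():
        img = iio.imread(directory / row.filename).astype(np.float32) / 65535.0
        slices.append(
            SectionSlice(
                index=int(row.index), stain=str(row.stain), image=img,
                true_transform=RigidTransform2D(float(row.dx), float(row.dy), float(row.theta)),
                pixel_size=float(row.pixel_size_um),
            )
        )
    series = SectionSeries(
        slices=slices,
        epithelium_stain_period=int(meta["epithelium_stain_period"]),
        period_offset=int(meta["period_offset"]),
        sectioning_axis=str(meta["sectioning_axis"]),
        slice_thickness=float(meta["slice_thickness_um"]),
    )
    series.validate()
    return series


def save_volume(volume: LabeledVolume, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(directory / "epithelium.tif",
                     volume.epithelium.astype(np.uint8) * 255, photometric="minisblack")
    tifffile.imwrite(directory / "vessel.tif",
                     volume.vessel.astype(np.uint8) * 255, photometric="minisblack")
    meta = {"voxel_size_um": list(volume.voxel_size), "orientation": volume.orientation}
    (directory / "volume.json").write_text(json.dumps(meta, indent=1))


def load_volume(directory) -> LabeledVolume:
    directory = Path(directory)
    meta = json.loads((directory / "volume.json").read_text())
    return LabeledVolume(
        epithelium=tifffile.imread(directory / "epithelium.tif") > 0,
        vessel=tifffile.imread(directory / "vessel.tif") > 0,
        voxel_size=tuple(meta["voxel_size_um"]),
        orientation=meta["orientation"],
    )


def save_projection(proj: Projection, path) -> None:
    path = Path(path)
    if proj.kind == "binary":
        iio.imwrite(path, proj.image.astype(np.uint8) * 255)
    else:
        tifffile.imwrite(path, proj.image.astype(np.int32))


def write_transforms(chain: TransformChain, path) -> None:
    pd.DataFrame(
        [{"slice_index": i, "dx": t.dx, "dy": t.dy, "theta": t.theta}
         for i, t in enumerate(chain.absolute)]
    ).to_csv(path, index=False)


def read_transforms(path, anchor: int | None = None) -> TransformChain:
    frame = pd.read_csv(path).sort_values("slice_index")
    transforms = [RigidTransform2D(float(r.dx), float(r.dy), float(r.theta))
                  for r in frame.itertuples()]
    if anchor is None:
        anchor = next(i for i, t in enumerate(transforms) if t.is_identity(tol=1e-9))
    return TransformChain(absolute=transforms, anchor=anchor)


def write_ground_truth(truth: PhantomGroundTruth, csv_path, surface_tiff=None) -> None:
    pd.DataFrame(
        [{"component_id": cid, "x_um": p[0], "y_um": p[1], "z_um": p[2],
          "true_depth_um": d}
         for cid, p, d in truth.vessel_components]
    ).to_csv(csv_path, index=False)
    if surface_tiff is not None:
        tifffile.imwrite(surface_tiff, truth.surface_height.astype(np.float32))


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
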