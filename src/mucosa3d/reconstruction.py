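"""Anisotropic 3D stacking, mucosal-surface extraction and vessel depth.

Aligned per-slice masks are stacked into a two-channel labelled volume
(epithelium, vessel) with anisotropic voxels (in-plane pixel size vs. slice
thickness).  The mucosal surface is read off per column as the first
foreground voxel from the luminal side; every vessel voxel and every
3D-connected vessel component then gets a depth in micrometres below that
surface, measured to the component centroid ("centre of the vessel lumen").
Depth-windowed top-view projections emulate the en-face view an endoscopist
sees, restricted to vasculature within a chosen distance of the surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage as ndi

from .phantom import LABELS, SectionSeries, TissueVolume
from .registration import TransformChain, apply_transform, assign_epithelium

__all__ = [
    "LabeledVolume",
    "SurfaceMap",
    "DepthField",
    "Projection",
    "stack",
    "extract_surface",
    "compute_depth_field",
    "depth_window_projection",
    "cross_section",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class LabeledVolume:
    """Registered two-channel volume, stored depth-first as ``(z, y, x)``.

    ``voxel_size`` is μm per voxel along ``(z, y, x)``; axis 0 is always the
    depth axis regardless of how the block was sectioned.
    """

    epithelium: np.ndarray
    vessel: np.ndarray
    voxel_size: tuple[float, float, float]
    orientation: str  # "vertical_section" | "horizontal_section"
    depth_axis: int = 0

    def __post_init__(self) -> None:
        if self.epithelium.shape != self.vessel.shape:
            raise ValueError("channel shapes differ")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        if self.depth_axis != 0:
            raise ValueError("volumes are stored depth-first; depth_axis must be 0")

    @classmethod
    def from_tissue_volume(cls, tv: TissueVolume) -> "LabeledVolume":
        """Channels straight from a phantom's label field (no sectioning)."""
        lab = tv.labels
        return cls(
            epithelium=lab == LABELS["epithelium"],
            vessel=(lab == LABELS["vessel_wall"]) | (lab == LABELS["vessel_lumen"]),
            voxel_size=tv.voxel_size,
            orientation=tv.sectioning_axis,
        )


@dataclass
class SurfaceMap:
    """Per-column mucosal surface position (μm along the depth axis) over
    the two non-depth axes; ``valid`` marks columns containing tissue."""

    height: np.ndarray  # (ny, nx) float μm
    valid: np.ndarray  # (ny, nx) bool


@dataclass
class DepthField:
    """Depth below the mucosal surface, μm, defined on vessel voxels.

    ``component_depths`` lists ``(component_id, lumen_centre_depth_um)`` per
    26-connected vessel component; ``labels`` is the component id volume and
    ``centroids_um`` the component centroids in ``(z, y, x)`` μm.
    """

    depth: np.ndarray  # 3D float32, NaN off-vessel
    component_depths: list[tuple[int, float]]
    labels: np.ndarray = field(repr=False)
    centroids_um: dict[int, tuple[float, float, float]] = field(repr=False)
    n_excluded: int = 0


@dataclass
class Projection:
    image: np.ndarray
    window: float  # μm
    kind: str  # "binary" | "count"

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be positive")
        if self.kind not in ("binary", "count"):
            raise ValueError(f"unknown projection kind {self.kind!r}")


def _nearest_slice(indices: Sequence[int], i: int) -> int:
    """Nearest index in ``indices`` to ``i``; ties go to the lower index."""
    arr = np.asarray(indices)
    return int(arr[int(np.argmin(np.abs(arr - i)))])


def stack(
    series: SectionSeries,
    chain: TransformChain,
    vessel_masks: Mapping[int, np.ndarray],
    epithelium_masks: Mapping[int, np.ndarray],
) -> LabeledVolume:
    """Assemble aligned per-slice masks into a labelled volume.

    ``vessel_masks`` maps vessel-stain slice indices to their *filled*
    vessel masks, ``epithelium_masks`` maps epithelium-stain indices to
    epithelium masks, both in the raw (unaligned) slice frame.  Each channel
    is propagated to the other stain's slice positions by nearest-slice copy
    (ties toward the lower index), matching the superimposition of adjacent
    sections.
    """
    n = len(series)
    if len(chain) != n:
        raise ValueError("transform chain length does not match slice count")
    shape = series.slices[0].image.shape
    for idx, m in list(vessel_masks.items()) + list(epithelium_masks.items()):
        if np.shape(m) != shape:
            raise ValueError(f"mask for slice {idx} has shape {np.shape(m)}, expected {shape}")
    v_idx = sorted(vessel_masks)
    e_idx = sorted(epithelium_masks)
    if not v_idx or not e_idx:
        raise ValueError("need at least one vessel-stain and one epithelium-stain mask")

    aligned_v = {i: apply_transform(np.asarray(vessel_masks[i], dtype=bool), chain[i], "nearest")
                 for i in v_idx}
    aligned_e = {i: apply_transform(np.asarray(epithelium_masks[i], dtype=bool), chain[i], "nearest")
                 for i in e_idx}
    vessel = np.stack([aligned_v[_nearest_slice(v_idx, i)] for i in range(n)])
    epith = np.stack([aligned_e[_nearest_slice(e_idx, i)] for i in range(n)])

    px = series.slices[0].pixel_size
    dt = series.slice_thickness
    if series.sectioning_axis == "horizontal_section":
        # stack axis is depth already: (z, y, x)
        vox = (dt, px, px)
    elif series.sectioning_axis == "vertical_section":
        # slices are (z, x) stacked along y -> permute to (z, y, x)
        vessel = np.transpose(vessel, (1, 0, 2))
        epith = np.transpose(epith, (1, 0, 2))
        vox = (px, dt, px)
    else:
        raise ValueError(f"unknown orientation {series.sectioning_axis!r}")
    return LabeledVolume(epithelium=epith, vessel=vessel, voxel_size=vox,
                         orientation=series.sectioning_axis)


def reconstruct_from_series(
    series: SectionSeries,
    chain: TransformChain,
    vessel_masks: Mapping[int, np.ndarray],
    epithelium_masks: Mapping[int, np.ndarray],
) -> LabeledVolume:
    """Convenience wrapper: pair epithelium slices via the nearest-index rule
    and stack (kept separate from :func:`stack` for symmetry with manual
    pipelines)."""
    # assign_epithelium also validates that epithelium slices exist
    assign_epithelium(series, chain, epithelium_masks)
    return stack(series, chain, vessel_masks, epithelium_masks)


def extract_surface(volume: LabeledVolume, smoothing_window: int = 15) -> SurfaceMap:
    """Mucosal surface per (y, x) column: depth-axis coordinate (μm) of the
    first foreground voxel (epithelium or vessel) from the luminal side,
    median-smoothed over ``smoothing_window`` pixels.  Crypt orifices, where
    a column enters an open gland lumen, are bridged by the median filter.
    """
    fg = volume.epithelium | volume.vessel
    if not fg.any():
        raise ValueError("volume is empty; no surface to extract")
    valid = fg.any(axis=0)
    idx = fg.argmax(axis=0)
    dz = volume.voxel_size[0]
    height = idx.astype(float) * dz
    if not valid.all():
        # fill invalid columns from the nearest valid one before smoothing
        _, (iy, ix) = ndi.distance_transform_edt(~valid, return_indices=True)
        height = height[iy, ix]
    if smoothing_window and smoothing_window > 1:
        height = ndi.median_filter(height, size=smoothing_window, mode="nearest")
    return SurfaceMap(height=height, valid=valid)


def compute_depth_field(
    volume: LabeledVolume,
    surface: SurfaceMap,
    mode: str = "axis",
) -> DepthField:
    """Depth of every vessel voxel and every vessel component below the
    mucosal surface.

    ``axis`` mode measures straight down the depth axis (the way a vertical
    section is read under the microscope): depth = z coordinate minus the
    surface height in the voxel's column.  ``euclidean`` mode measures the
    3D distance to the nearest valid surface point, for strongly tilted
    surfaces.  Component depth is evaluated at the component centroid
    (anisotropy respected); vessel voxels in columns without valid surface
    are excluded and counted.
    """
    if mode not in ("axis", "euclidean"):
        raise ValueError(f"unknown depth mode {mode!r}")
    vessel = volume.vessel
    dz, dy, dx = volume.voxel_size
    nz, ny, nx = vessel.shape
    z_um = np.arange(nz, dtype=np.float32) * dz

    comp, n = ndi.label(vessel, structure=_CONN26)

    if mode == "axis":
        depth3 = z_um[:, None, None] - surface.height[None, :, :].astype(np.float32)
        depth3 = np.maximum(depth3, 0.0)
    else:
        sheet = np.zeros_like(vessel, dtype=bool)
        iy, ix = np.nonzero(surface.valid)
        sheet[np.clip(np.round(surface.height[iy, ix] / dz).astype(int), 0, nz - 1), iy, ix] = True
        depth3 = ndi.distance_transform_edt(~sheet, sampling=(dz, dy, dx)).astype(np.float32)

    depth = np.full(vessel.shape, np.nan, dtype=np.float32)
    depth[vessel] = depth3[vessel]
    n_excluded = 0
    if mode == "axis" and not surface.valid.all():
        bad = vessel & ~surface.valid[None, :, :]
        n_excluded = int(bad.sum())
        depth[bad] = np.nan

    # nearest valid column lookup for centroids that land on invalid columns
    if not surface.valid.all():
        _, (jy, jx) = ndi.distance_transform_edt(~surface.valid, return_indices=True)
    else:
        jy = jx = None

    component_depths: list[tuple[int, float]] = []
    centroids: dict[int, tuple[float, float, float]] = {}
    if n:
        coms = ndi.center_of_mass(vessel, comp, index=range(1, n + 1))
        for cid, (zc, yc, xc) in enumerate(coms, start=1):
            centroids[cid] = (zc * dz, yc * dy, xc * dx)
            iyc = min(int(round(yc)), ny - 1)
            ixc = min(int(round(xc)), nx - 1)
            if jy is not None and not surface.valid[iyc, ixc]:
                iyc, ixc = int(jy[iyc, ixc]), int(jx[iyc, ixc])
            if mode == "axis":
                d = zc * dz - float(surface.height[iyc, ixc])
            else:
                izc = min(int(round(zc)), nz - 1)
                d = float(depth3[izc, iyc, ixc])
            component_depths.append((cid, float(max(d, 0.0))))
    return DepthField(depth=depth, component_depths=component_depths,
                      labels=comp, centroids_um=centroids, n_excluded=n_excluded)


def depth_window_projection(
    volume: LabeledVolume,
    depth_field: DepthField,
    window: float,
    kind: str = "binary",
) -> Projection:
    """Top view of the vasculature within ``window`` μm of the surface.

    The standard triplet used for comparison with en-face endoscopy is
    windows of 50, 100 and 150 μm.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    d = np.nan_to_num(depth_field.depth, nan=np.inf)
    sel = volume.vessel & (d <= window)
    img = sel.any(axis=0) if kind == "binary" else sel.sum(axis=0, dtype=np.int32)
    return Projection(image=img, window=float(window), kind=kind)


def cross_section(
    volume: LabeledVolume,
    line: Sequence[tuple[float, float]],
    thickness: int = 1,
) -> np.ndarray:
    """Vertical cross-section of both channels along a top-view polyline.

    ``line`` is a sequence of ``(y, x)`` pixel coordinates in the top view;
    ``thickness`` pixels are unioned perpendicular to the line.  Returns a
    ``(2, nz, n_samples)`` boolean array (channel 0 epithelium, channel 1
    vessel): depth axis × arc length.
    """
    pts = np.asarray(line, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise ValueError("line must contain at least two (y, x) points")
    seg_len = np.hypot(*(np.diff(pts, axis=0).T))
    if seg_len.sum() <= 0:
        raise ValueError("degenerate (zero-length) line")
    if thickness < 1:
        raise ValueError("thickness must be >= 1")

    samples: list[np.ndarray] = []
    normals: list[np.ndarray] = []
    for (p0, p1), L in zip(zip(pts[:-1], pts[1:]), seg_len):
        if L == 0:
            continue
        n_samp = max(int(np.ceil(L)) + 1, 2)
        t = np.linspace(0.0, 1.0, n_samp)
        if samples:  # avoid duplicating the joint
            t = t[1:]
        seg = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
        d = (p1 - p0) / L
        normal = np.array([-d[1], d[0]])
        samples.append(seg)
        normals.append(np.tile(normal, (len(seg), 1)))
    path = np.concatenate(samples)
    norm = np.concatenate(normals)

    nz, ny, nx = volume.vessel.shape
    offsets = np.arange(thickness) - (thickness - 1) / 2.0
    out = np.zeros((2, nz, len(path)), dtype=bool)
    for off in offsets:
        yy = np.clip(np.round(path[:, 0] + off * norm[:, 0]).astype(int), 0, ny - 1)
        xx = np.clip(np.round(path[:, 1] + off * norm[:, 1]).astype(int), 0, nx - 1)
        out[0] |= volume.epithelium[:, yy, xx]
        out[1] |= volume.vessel[:, yy, xx]
    return out
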