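"""Synthetic colonic-mucosa phantoms with known 3D geometry.

The generator builds a labelled tissue volume (crypt glands, stroma,
microvessels with walls and lumens, optional erythrocyte extravasation),
virtually sections it into an immunostain-like serial-section series, and
renders a virtual magnifying narrow-band (blue-light) endoscopy top view.
Because every structure is placed programmatically, the true mucosal
surface and the true depth of every vessel are known exactly, so each
downstream stage (segmentation, registration, reconstruction, visibility
statistics) can be validated by parameter recovery.

Geometry conventions
--------------------
Volumes are stored depth-first as ``(z, y, x)`` with ``z = 0`` at the
luminal side; the voxel at index ``k`` along an axis with spacing ``s`` sits
at coordinate ``k * s`` micrometres.  ``vertical_section`` means the
mucosal surface lies inside each 2D slice (slices are ``(z, x)`` planes
stacked along ``y``); ``horizontal_section`` means depth accumulates across
the stack (slices are ``(y, x)`` planes stacked along ``z``).

Two vessel layouts are provided.  ``honeycomb`` arranges capillaries on the
edges of the crypt lattice, emulating the capillary mesh that wraps around
the mucosal glands of normal mucosa; the ``adenoma``/``carcinoma`` classes
distort crypt positions and calibres and add vertically standing vessels
between the crypts.  ``straight`` lays disjoint tubes perpendicular to the
slicing plane at controlled depths, which gives clean ring cross-sections
and a dense, independent sample of ground-truth depths for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi

from .registration import RigidTransform2D, apply_transform

__all__ = [
    "LABELS",
    "PhantomSpec",
    "TissueVolume",
    "PhantomGroundTruth",
    "SectionSlice",
    "SectionSeries",
    "build_phantom",
    "section_volume",
    "render_virtual_bli",
]

# tissue class labels of the voxel model
LABELS = {
    "background": 0,
    "epithelium": 1,
    "stroma": 2,
    "vessel_wall": 3,
    "vessel_lumen": 4,
    "erythrocyte_extravasation": 5,
}
_BG = LABELS["background"]
_EPI = LABELS["epithelium"]
_STROMA = LABELS["stroma"]
_WALL = LABELS["vessel_wall"]
_LUMEN = LABELS["vessel_lumen"]
_EXTRA = LABELS["erythrocyte_extravasation"]

#: intensity of unstained (counterstained) tissue in rendered sections
COUNTERSTAIN = 0.2

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class PhantomSpec:
    """Parameters of a synthetic mucosa block.

    ``volume_extent`` and ``voxel_size`` are given in ``(x, y, z)`` order
    (z is depth below the lumen).  The serial-sectioning protocol defaults
    to 100 consecutive slices of 3 μm with the epithelium stain on every
    third slice, the vessel stain elsewhere.
    """

    volume_extent: tuple[int, int, int] = (600, 100, 168)
    voxel_size: tuple[float, float, float] = (2.0, 3.0, 2.0)
    tissue_class: str = "normal"
    n_slices: int = 100
    slice_thickness: float = 3.0
    epithelium_stain_period: int = 3
    period_offset: int = 0
    crypt_pitch: float = 100.0
    crypt_radius: float = 25.0
    crypt_distortion: float = 0.0
    vessel_radius_mean: float = 5.0
    vessel_radius_sd: float = 1.0
    vessel_wall_thickness: float = 3.0
    vessel_depth_range: tuple[float, float] = (15.0, 250.0)
    broken_wall_fraction: float = 0.0
    jitter_max_translation: float = 0.0  # px
    jitter_max_rotation: float = 0.0  # deg
    noise_sd: float = 0.0
    rng_seed: int = 0
    sectioning_axis: str = "vertical_section"
    # layout extras (free parameters of the phantom, not of the protocol)
    vessel_layout: str = "straight"
    n_vessels: int = 40
    include_crypts: bool = True
    surface_margin_um: float = 16.0
    surface_amplitude_um: float = 0.0
    surface_wavelength_um: float = 200.0
    epithelium_band_um: float = 9.0
    crypt_position_jitter_um: float = 4.0
    n_extravasation: int = 0
    stroma_texture_sd: float = 0.05

    def validate(self) -> None:
        if any(e <= 0 for e in self.volume_extent):
            raise ValueError("volume_extent entries must be positive")
        if any(s <= 0 for s in self.voxel_size):
            raise ValueError("voxel_size entries must be positive")
        if self.tissue_class not in ("normal", "adenoma", "carcinoma"):
            raise ValueError(f"unknown tissue_class {self.tissue_class!r}")
        if self.sectioning_axis not in ("vertical_section", "horizontal_section"):
            raise ValueError(f"unknown sectioning_axis {self.sectioning_axis!r}")
        if self.vessel_layout not in ("honeycomb", "straight"):
            raise ValueError(f"unknown vessel_layout {self.vessel_layout!r}")
        if self.epithelium_stain_period < 1:
            raise ValueError("epithelium_stain_period must be >= 1")
        if not (0.0 <= self.broken_wall_fraction <= 1.0):
            raise ValueError("broken_wall_fraction must lie in [0, 1]")
        if not (0.0 <= self.crypt_distortion <= 1.0):
            raise ValueError("crypt_distortion must lie in [0, 1]")
        if self.slice_thickness <= 0 or self.n_slices < 1:
            raise ValueError("n_slices and slice_thickness must be positive")
        for name in ("crypt_pitch", "crypt_radius", "vessel_radius_mean",
                     "vessel_wall_thickness"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.vessel_depth_range
        if lo < 0 or hi < lo:
            raise ValueError("vessel_depth_range must be 0 <= lo <= hi")
        span = self.n_slices * self.slice_thickness
        if span > self.section_axis_extent_um() + 1e-6:
            raise ValueError(
                f"{self.n_slices} slices x {self.slice_thickness} um exceed the "
                f"{self.section_axis_extent_um():g} um extent along the sectioning axis"
            )

    # --- derived geometry -------------------------------------------------
    def shape_zyx(self) -> tuple[int, int, int]:
        nx, ny, nz = self.volume_extent
        return (nz, ny, nx)

    def vox_zyx(self) -> tuple[float, float, float]:
        sx, sy, sz = self.voxel_size
        return (sz, sy, sx)

    def section_axis(self) -> int:
        """Canonical (z, y, x) axis index along which sections are cut."""
        return 1 if self.sectioning_axis == "vertical_section" else 0

    def section_axis_extent_um(self) -> float:
        ax = self.section_axis()
        return self.shape_zyx()[ax] * self.vox_zyx()[ax]


@dataclass
class TissueVolume:
    """Voxelised tissue model: ``labels`` is a (z, y, x) uint8 array over
    :data:`LABELS`; ``voxel_size`` is (z, y, x) μm per voxel."""

    labels: np.ndarray
    voxel_size: tuple[float, float, float]
    sectioning_axis: str


@dataclass
class PhantomGroundTruth:
    """Exact bookkeeping of the generated geometry.

    ``vessel_components`` holds ``(component_id, (x_um, y_um, z_um),
    true_depth_um)`` per 26-connected vessel component; the depth runs from
    the (designed) mucosal surface to the centre of the vessel lumen.
    """

    surface_height: np.ndarray  # (ny, nx) μm
    vessel_components: list[tuple[int, tuple[float, float, float], float]]
    crypt_orifices: list[tuple[float, float]]  # (x_um, y_um)
    component_labels: np.ndarray | None = field(default=None, repr=False)


@dataclass
class SectionSlice:
    index: int
    stain: str  # "vessel_stain" | "epithelium_stain"
    image: np.ndarray  # 2D float32 in [0, 1]
    true_transform: RigidTransform2D
    pixel_size: float  # μm


@dataclass
class SectionSeries:
    """Ordered serial-section images with per-slice stain and jitter truth."""

    slices: list[SectionSlice]
    epithelium_stain_period: int
    period_offset: int
    sectioning_axis: str
    slice_thickness: float

    def __len__(self) -> int:
        return len(self.slices)

    def stains(self) -> list[str]:
        return [s.stain for s in self.slices]

    def validate(self) -> None:
        shapes = {s.image.shape for s in self.slices}
        if len(shapes) > 1:
            raise ValueError("slice images differ in shape")
        for i, s in enumerate(self.slices):
            if s.index != i:
                raise ValueError("slice indices must be consecutive from 0")
            want = (
                "epithelium_stain"
                if i % self.epithelium_stain_period == self.period_offset
                else "vessel_stain"
            )
            if s.stain != want:
                raise ValueError(
                    f"slice {i} has stain {s.stain!r}, expected {want!r} for "
                    f"period {self.epithelium_stain_period}"
                )


# --------------------------------------------------------------------------
# volume construction
# --------------------------------------------------------------------------

def _paint_tube(
    labels: np.ndarray,
    axis: int,
    perp_centers_um: tuple[float, float],
    radius_um: float,
    wall_um: float,
    span_um: tuple[float, float],
    vox: tuple[float, float, float],
) -> None:
    """Paint a capped cylindrical vessel (wall annulus + lumen) whose axis is
    the given canonical axis.  Caps of wall material close both ends so the
    lumen is fully enclosed, as a blind-ending capillary segment."""
    shape = labels.shape
    perp_axes = [a for a in range(3) if a != axis]
    ro = radius_um + wall_um
    lo_ax = max(0, int(np.floor((span_um[0] - wall_um) / vox[axis])))
    hi_ax = min(shape[axis] - 1, int(np.ceil((span_um[1] + wall_um) / vox[axis])))
    if hi_ax < lo_ax:
        return
    bounds = []
    for a, c in zip(perp_axes, perp_centers_um):
        lo = max(0, int(np.floor((c - ro) / vox[a])) - 1)
        hi = min(shape[a] - 1, int(np.ceil((c + ro) / vox[a])) + 1)
        if hi < lo:
            return
        bounds.append((lo, hi))
    (l0, h0), (l1, h1) = bounds
    c0 = np.arange(l0, h0 + 1) * vox[perp_axes[0]] - perp_centers_um[0]
    c1 = np.arange(l1, h1 + 1) * vox[perp_axes[1]] - perp_centers_um[1]
    d = np.hypot(c0[:, None], c1[None, :])
    lumen2d = d <= radius_um
    wall2d = (d <= ro) & ~lumen2d
    ax_coords = np.arange(lo_ax, hi_ax + 1) * vox[axis]
    inside = (ax_coords >= span_um[0]) & (ax_coords <= span_um[1])

    sl: list[slice] = [slice(None)] * 3
    sl[perp_axes[0]] = slice(l0, h0 + 1)
    sl[perp_axes[1]] = slice(l1, h1 + 1)
    for k, a_um in zip(range(lo_ax, hi_ax + 1), ax_coords):
        sl[axis] = slice(k, k + 1)
        region = labels[tuple(sl)]
        plane = np.moveaxis(region, axis, 0)[0]
        if inside[k - lo_ax]:
            plane[wall2d] = _WALL
            plane[lumen2d] = _LUMEN
        else:  # cap: wall material over the full disk
            plane[wall2d | lumen2d] = _WALL


def _snap(value: float, step: float) -> float:
    return round(value / step) * step


def build_phantom(spec: PhantomSpec) -> tuple[TissueVolume, PhantomGroundTruth]:
    """Generate a labelled tissue volume and its exact ground truth.

    Deterministic given ``spec.rng_seed``.  Raises ``ValueError`` when the
    lateral footprint cannot hold a single crypt (with ``include_crypts``).
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    nz, ny, nx = spec.shape_zyx()
    sz, sy, sx = spec.vox_zyx()
    vox = (sz, sy, sx)
    x_um, y_um, z_um = nx * sx, ny * sy, nz * sz

    labels = np.zeros((nz, ny, nx), dtype=np.uint8)
    zc = np.arange(nz) * sz

    # designed mucosal surface height h(y, x), then voxelised
    xs = np.arange(nx) * sx
    if spec.surface_amplitude_um > 0:
        h_design = spec.surface_margin_um + spec.surface_amplitude_um * np.sin(
            2 * np.pi * xs / spec.surface_wavelength_um
        )
    else:
        h_design = np.full(nx, spec.surface_margin_um)
    h_design = np.broadcast_to(h_design[None, :], (ny, nx)).astype(float)
    surf_idx = np.ceil(h_design / sz - 1e-9).astype(int)
    surf_idx = np.clip(surf_idx, 0, nz - 1)
    surface_height = surf_idx * sz  # the voxelised truth surface

    tissue = zc[:, None, None] >= surface_height[None, :, :] - 1e-9
    labels[tissue] = _STROMA
    epi_band = tissue & (
        zc[:, None, None] < (surface_height + spec.epithelium_band_um)[None, :, :]
    )
    labels[epi_band] = _EPI

    distorted = spec.tissue_class != "normal"
    dist = spec.crypt_distortion

    # --- crypt glands ------------------------------------------------------
    crypt_orifices: list[tuple[float, float]] = []
    crypt_xs: np.ndarray = np.array([])
    crypt_ys: np.ndarray = np.array([])
    if spec.include_crypts:
        if min(x_um, y_um) < 2 * spec.crypt_radius:
            raise ValueError(
                "volume footprint too small to hold one crypt of radius "
                f"{spec.crypt_radius:g} um"
            )
        p = spec.crypt_pitch
        margin = spec.crypt_radius + 4.0

        def _lattice(extent: float) -> np.ndarray:
            pos = np.arange(margin + p / 2, extent - margin + 1e-9, p)
            return pos if pos.size else np.array([extent / 2])

        crypt_xs = _lattice(x_um)
        crypt_ys = _lattice(y_um)
        gland_bottom = min(0.75 * (z_um - spec.surface_margin_um), 220.0)
        jit = spec.crypt_position_jitter_um + (0.35 * p * dist if distorted else 0.0)
        yy_idx = np.arange(ny) * sy
        xx_idx = np.arange(nx) * sx
        for cy0 in crypt_ys:
            for cx0 in crypt_xs:
                cx = cx0 + rng.uniform(-jit, jit)
                cy = cy0 + rng.uniform(-jit, jit)
                r = spec.crypt_radius * (1 + (dist * rng.uniform(-0.3, 0.8) if distorted else 0))
                rho = np.hypot(yy_idx[:, None] - cy, xx_idx[None, :] - cx)
                ring = (rho <= r) & (rho > 0.55 * r)
                hole = rho <= 0.55 * r
                h_loc = surface_height[
                    min(int(round(cy / sy)), ny - 1), min(int(round(cx / sx)), nx - 1)
                ]
                zmask = (zc >= h_loc - 1e-9) & (zc <= h_loc + gland_bottom)
                region = np.ix_(np.where(zmask)[0], np.arange(ny), np.arange(nx))
                sub = labels[region]
                sub[:, ring] = _EPI
                sub[:, hole] = _BG
                labels[region] = sub
                crypt_orifices.append((float(cx), float(cy)))

    # --- vessels -----------------------------------------------------------
    dlo, dhi = spec.vessel_depth_range
    r_scale = 1.0 + (0.8 * dist if distorted else 0.0)

    def _radius(cap: float = np.inf) -> float:
        """Radius draw; ``cap`` keeps straight-layout tubes clear of their
        neighbours so components stay separated, as that layout promises."""
        r = rng.normal(spec.vessel_radius_mean, spec.vessel_radius_sd) * r_scale
        r = max(r, 1.2 * max(sx, sz))
        return float(min(r, cap)) if np.isfinite(cap) else float(r)

    tube_axis = spec.section_axis()  # tubes run perpendicular to slice planes
    if spec.vessel_layout == "straight":
        n = spec.n_vessels
        if tube_axis == 1:  # vertical sections: tubes along y at (z=depth, x)
            xmargin = 12.0
            usable = x_um - 2 * xmargin
            slot = usable / max(n, 1)
            # keep neighbouring tubes separated by >6 px of stroma in the
            # worst case so lumen filling can never bridge two vessels
            r_cap = 0.45 * slot - spec.vessel_wall_thickness - 3.5 * max(sx, sz)
            for i in range(n):
                x0 = xmargin + (i + 0.5) * slot + rng.uniform(-0.05, 0.05) * slot
                d = dlo if dhi == dlo else rng.uniform(dlo, dhi)
                z0 = _snap(spec.surface_margin_um + d, sz)
                x0 = _snap(x0, sx)
                r = _radius(cap=r_cap)
                _paint_tube(labels, 1, (z0, x0), r, spec.vessel_wall_thickness,
                            (8.0, y_um - 8.0), vox)
        else:  # horizontal sections: tubes along z at (y, x)
            cols = int(np.ceil(np.sqrt(n)))
            rows = int(np.ceil(n / cols))
            half_len = 30.0
            r_cap = (0.5 * min(y_um / rows, x_um / cols)
                     - spec.vessel_wall_thickness - 3.5 * max(sx, sy))
            k = 0
            for iy in range(rows):
                for ix in range(cols):
                    if k >= n:
                        break
                    y0 = _snap((iy + 0.5) * y_um / rows, sy)
                    x0 = _snap((ix + 0.5) * x_um / cols, sx)
                    d = dlo if dhi == dlo else rng.uniform(dlo, dhi)
                    zc0 = _snap(spec.surface_margin_um + d, sz)
                    r = _radius(cap=r_cap)
                    _paint_tube(labels, 0, (y0, x0), r, spec.vessel_wall_thickness,
                                (max(zc0 - half_len, spec.surface_margin_um + 2.0),
                                 min(zc0 + half_len, z_um - 8.0)), vox)
                    k += 1
    else:  # honeycomb: capillaries on crypt-lattice edges
        if not spec.include_crypts:
            raise ValueError("honeycomb layout requires include_crypts=True")
        mid_x = (crypt_xs[:-1] + crypt_xs[1:]) / 2 if crypt_xs.size > 1 else np.array([])
        mid_y = (crypt_ys[:-1] + crypt_ys[1:]) / 2 if crypt_ys.size > 1 else np.array([])
        w = spec.vessel_wall_thickness
        # tubes along y between crypt columns
        for mx in mid_x:
            d = dlo if dhi == dlo else rng.uniform(dlo, dhi)
            _paint_tube(labels, 1,
                        (_snap(spec.surface_margin_um + d, sz), _snap(mx, sx)),
                        _radius(), w, (8.0, y_um - 8.0), vox)
        # tubes along x between crypt rows
        for my in mid_y:
            d = dlo if dhi == dlo else rng.uniform(dlo, dhi)
            _paint_tube(labels, 2,
                        (_snap(spec.surface_margin_um + d, sz), _snap(my, sy)),
                        _radius(), w, (8.0, x_um - 8.0), vox)
        if distorted:
            # vertically standing, thickened vessels between the crypts
            for mx in mid_x:
                for my in mid_y:
                    if rng.random() > 0.5 + 0.5 * dist:
                        continue
                    d = dlo if dhi == dlo else rng.uniform(dlo, dhi)
                    top = spec.surface_margin_um + min(d, 30.0)
                    _paint_tube(labels, 0, (_snap(my, sy), _snap(mx, sx)),
                                _radius() * 1.3, w,
                                (top, min(top + 120.0, z_um - 8.0)), vox)

    # --- erythrocyte extravasation patches ---------------------------------
    for _ in range(spec.n_extravasation):
        cyp = rng.uniform(0.2, 0.8) * y_um
        cxp = rng.uniform(0.2, 0.8) * x_um
        czp = spec.surface_margin_um + rng.uniform(20.0, 60.0)
        rz, ry, rx = 12.0, rng.uniform(25.0, 45.0), rng.uniform(25.0, 45.0)
        zz = (zc[:, None, None] - czp) / rz
        yy = (np.arange(ny)[None, :, None] * sy - cyp) / ry
        xx = (np.arange(nx)[None, None, :] * sx - cxp) / rx
        blob = (zz**2 + yy**2 + xx**2) <= 1.0
        labels[blob & (labels == _STROMA)] = _EXTRA

    volume = TissueVolume(labels=labels, voxel_size=(sz, sy, sx),
                          sectioning_axis=spec.sectioning_axis)
    truth = _ground_truth(volume, surface_height, crypt_orifices)
    return volume, truth


def _ground_truth(
    volume: TissueVolume,
    surface_height: np.ndarray,
    crypt_orifices: list[tuple[float, float]],
) -> PhantomGroundTruth:
    labels = volume.labels
    sz, sy, sx = volume.voxel_size
    ny, nx = labels.shape[1:]
    vessel = (labels == _WALL) | (labels == _LUMEN)
    comp, n = ndi.label(vessel, structure=_CONN26)
    components: list[tuple[int, tuple[float, float, float], float]] = []
    if n:
        lumen = labels == _LUMEN
        for cid in range(1, n + 1):
            mask = comp == cid
            core = mask & lumen
            if not core.any():
                core = mask
            zc, yc, xc = (np.asarray(c, dtype=float).mean() for c in np.nonzero(core))
            z_mu, y_mu, x_mu = zc * sz, yc * sy, xc * sx
            iy = min(int(round(yc)), ny - 1)
            ix = min(int(round(xc)), nx - 1)
            depth = float(z_mu - surface_height[iy, ix])
            components.append((cid, (float(x_mu), float(y_mu), float(z_mu)), depth))
    return PhantomGroundTruth(
        surface_height=surface_height.astype(float),
        vessel_components=components,
        crypt_orifices=crypt_orifices,
        component_labels=comp,
    )


# --------------------------------------------------------------------------
# virtual sectioning
# --------------------------------------------------------------------------

def _break_walls(plane_wall: np.ndarray, fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Erase an angular arc of wall from a random subset of in-plane wall
    components, emulating weakly stained / undetectable thin walls."""
    if fraction <= 0 or not plane_wall.any():
        return plane_wall
    out = plane_wall.copy()
    comp, n = ndi.label(plane_wall, structure=np.ones((3, 3), dtype=bool))
    for cid in range(1, n + 1):
        if rng.random() >= fraction:
            continue
        rr, cc = np.nonzero(comp == cid)
        cy, cx = rr.mean(), cc.mean()
        ang = np.degrees(np.arctan2(rr - cy, cc - cx))
        theta0 = rng.uniform(-180.0, 180.0)
        arc = rng.uniform(60.0, 110.0)
        dist = np.abs((ang - theta0 + 180.0) % 360.0 - 180.0)
        erase = dist <= arc / 2
        out[rr[erase], cc[erase]] = False
    return out


def section_volume(volume: TissueVolume, spec: PhantomSpec) -> SectionSeries:
    """Cut the volume into a stained serial-section series.

    Each slice is one voxel plane along the sectioning axis (the volume must
    therefore be built at sectioning resolution: ``slice_thickness`` equal
    to the voxel size along that axis).  Vessel-stain slices render the
    vessel wall as stain-positive and the lumen at counterstain level, so
    vessels appear as rings; epithelium-stain slices render the epithelium.
    Per-slice rigid jitter and additive Gaussian noise are applied and the
    true transforms recorded.
    """
    spec.validate()
    axis = spec.section_axis()
    vox = volume.voxel_size
    if abs(spec.slice_thickness - vox[axis]) > 1e-9:
        raise ValueError(
            f"slice_thickness {spec.slice_thickness:g} um must equal the voxel "
            f"size {vox[axis]:g} um along the sectioning axis"
        )
    if spec.n_slices > volume.labels.shape[axis]:
        raise ValueError("volume extent along the sectioning axis is too small")
    in_plane = tuple(v for a, v in enumerate(vox) if a != axis)
    if abs(in_plane[0] - in_plane[1]) > 1e-9:
        raise ValueError("in-plane voxel sizes must be isotropic for sectioning")
    pixel_size = in_plane[0]

    rng = np.random.default_rng(np.random.SeedSequence([spec.rng_seed, 1]))
    # 3D stromal texture (nuclei / ECM inhomogeneity): smooth in all axes so
    # adjacent sections share counterstain structure, as real tissue does
    texture = None
    if spec.stroma_texture_sd > 0:
        tex_rng = np.random.default_rng(np.random.SeedSequence([spec.rng_seed, 2]))
        texture = ndi.gaussian_filter(
            tex_rng.standard_normal(volume.labels.shape).astype(np.float32), sigma=2.0
        )
        texture /= max(float(texture.std()), 1e-9)
    slices: list[SectionSlice] = []
    for i in range(spec.n_slices):
        plane = np.take(volume.labels, i, axis=axis)
        is_epi = i % spec.epithelium_stain_period == spec.period_offset
        img = np.where(plane != _BG, COUNTERSTAIN, 0.0).astype(np.float32)
        if texture is not None:
            tex = np.take(texture, i, axis=axis)
            img = np.where(
                plane != _BG,
                np.clip(COUNTERSTAIN + spec.stroma_texture_sd * tex, 0.12, 0.35),
                0.0,
            ).astype(np.float32)
        if is_epi:
            img[plane == _EPI] = 1.0
            stain = "epithelium_stain"
        else:
            wall = _break_walls(plane == _WALL, spec.broken_wall_fraction, rng)
            img[wall] = 1.0
            stain = "vessel_stain"
        if spec.jitter_max_translation > 0 or spec.jitter_max_rotation > 0:
            t = RigidTransform2D(
                dx=float(rng.uniform(-spec.jitter_max_translation, spec.jitter_max_translation)),
                dy=float(rng.uniform(-spec.jitter_max_translation, spec.jitter_max_translation)),
                theta=float(rng.uniform(-spec.jitter_max_rotation, spec.jitter_max_rotation)),
            )
            img = apply_transform(img, t, "linear")
        else:
            t = RigidTransform2D()
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, img.shape).astype(np.float32)
        img = np.clip(img, 0.0, 1.0, out=img)
        slices.append(SectionSlice(index=i, stain=stain, image=img,
                                   true_transform=t, pixel_size=pixel_size))
    series = SectionSeries(
        slices=slices,
        epithelium_stain_period=spec.epithelium_stain_period,
        period_offset=spec.period_offset,
        sectioning_axis=spec.sectioning_axis,
        slice_thickness=spec.slice_thickness,
    )
    series.validate()
    return series


# --------------------------------------------------------------------------
# virtual magnifying-BLI rendering
# --------------------------------------------------------------------------

def render_virtual_bli(
    volume: TissueVolume,
    truth: PhantomGroundTruth,
    visibility_scale: float = 40.0,
    hard_cutoff: float = 80.0,
    render_crypt_orifices: bool = False,
) -> np.ndarray:
    """Render a top-view virtual narrow-band endoscopy image.

    Short-wavelength (~410 nm) light is strongly absorbed by haemoglobin,
    so superficial vessels darken the mucosal surface.  We use a
    phenomenological contrast model: each vessel component darkens its
    top-view footprint by ``exp(-true_depth / visibility_scale)`` and
    contributes nothing beyond ``hard_cutoff`` μm.  Erythrocyte
    extravasation renders as a diffuse dark patch.  Returns a float32
    ``(ny, nx)`` image in [0, 1] (1 = bright mucosa, lower = darker).
    """
    if visibility_scale <= 0:
        raise ValueError("visibility_scale must be positive")
    if hard_cutoff <= 0:
        raise ValueError("hard_cutoff must be positive")
    labels = volume.labels
    ny, nx = labels.shape[1:]
    comp = truth.component_labels
    if comp is None:
        vessel = (labels == _WALL) | (labels == _LUMEN)
        comp, _ = ndi.label(vessel, structure=_CONN26)
    dark = np.zeros((ny, nx), dtype=np.float32)
    objects = ndi.find_objects(comp)
    for cid, _pos, depth in truth.vessel_components:
        if depth > hard_cutoff:
            continue
        sl = objects[cid - 1]
        if sl is None:
            continue
        foot = (comp[sl] == cid).any(axis=0)
        contrib = float(np.exp(-max(depth, 0.0) / visibility_scale))
        sub = dark[sl[1], sl[2]]
        np.maximum(sub, contrib * foot, out=sub)
    extra = (labels == _EXTRA).any(axis=0)
    if extra.any():
        diffuse = ndi.gaussian_filter(extra.astype(np.float32), sigma=3.0)
        if diffuse.max() > 0:
            diffuse = 0.5 * diffuse / diffuse.max()
        np.maximum(dark, diffuse, out=dark)
    if render_crypt_orifices and truth.crypt_orifices:
        sy, sx = volume.voxel_size[1], volume.voxel_size[2]
        yy, xx = np.mgrid[:ny, :nx]
        for cx_um, cy_um in truth.crypt_orifices:
            rho = np.hypot(yy * sy - cy_um, xx * sx - cx_um)
            ringish = np.abs(rho - 10.0) <= max(sy, sx)
            np.maximum(dark, np.where(ringish, 0.15, 0.0).astype(np.float32), out=dark)
    return np.clip(1.0 - dark, 0.0, 1.0).astype(np.float32)
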