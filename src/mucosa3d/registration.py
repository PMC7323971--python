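"""Rigid slice-to-slice registration for serial-section stacks.

Consecutive histological sections are nearly identical in content but each
is digitised with its own arbitrary in-plane placement on the slide.  This
module recovers rigid (translation + optional rotation) transforms between
slice pairs and solves for one absolute transform per slice relative to an
anchor slice.

Conventions
-----------
Images are ``(row, col)`` arrays.  A :class:`RigidTransform2D` ``t`` acts on
an image through :func:`apply_transform`: the content is rotated by
``t.theta`` degrees about the image centre and then shifted by
``(t.dy, t.dx)`` pixels (row, col).  :func:`estimate_pairwise` returns the
transform that maps *moving* onto *fixed*, i.e.
``apply_transform(moving, t) ≈ fixed``.

Estimator
---------
Translation is found by cross-correlation restricted to a window of
plausible shifts (consecutive sections cannot jump far — the continuity
assumption), with the candidate peaks re-ranked by their true normalised
cross-correlation over the overlap region (periodic structures such as a
crypt lattice or a field of vessel rings produce ghost correlation peaks
that plain cross-correlation can mistake for the true one), and refined to
subpixel precision by a clamped parabolic fit on the NCC surface.

Chain solver
------------
Alternating stains light up different structures, so a single sequential
chain of pairwise estimates accumulates content-driven error.
:func:`register_series` instead measures redundant links — same-stain pairs
on the stain-positive channel, all near neighbours on the counterstain
(tissue texture) channel with the stain signal capped — and solves the
overdetermined system for per-slice absolute translations by iteratively
reweighted least squares, which suppresses the occasional ghost-locked
link.  :func:`propagate` provides the plain sequential composition for
callers that bring their own pairwise estimates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
from scipy import ndimage as ndi

if TYPE_CHECKING:  # pragma: no cover
    from .phantom import SectionSeries

__all__ = [
    "RigidTransform2D",
    "TransformChain",
    "apply_transform",
    "compose",
    "invert",
    "estimate_pairwise",
    "propagate",
    "register_series",
    "pair_epithelium_indices",
    "assign_epithelium",
]

#: default half-width (px) of the translation search window
DEFAULT_MAX_SHIFT = 15

#: intensity cap isolating the counterstain/tissue texture from stain signal
COUNTERSTAIN_CAP = 0.35

#: threshold separating stain-positive pixels from counterstain
STAIN_THRESHOLD = 0.5


@dataclass(frozen=True)
class RigidTransform2D:
    """In-plane rigid transform: rotation ``theta`` (degrees, about the image
    centre) followed by a translation ``(dx, dy)`` in pixels (col, row)."""

    dx: float = 0.0
    dy: float = 0.0
    theta: float = 0.0

    def is_identity(self, tol: float = 1e-12) -> bool:
        return abs(self.dx) <= tol and abs(self.dy) <= tol and abs(self.theta) <= tol


@dataclass
class TransformChain:
    """Absolute transform per slice, mapping each slice into the frame of the
    ``anchor`` slice (whose own transform is the identity)."""

    absolute: list[RigidTransform2D]
    anchor: int

    def __post_init__(self) -> None:
        if not (0 <= self.anchor < len(self.absolute)):
            raise ValueError("anchor index out of range")
        if not self.absolute[self.anchor].is_identity(tol=1e-9):
            raise ValueError("anchor transform must be the identity")

    def __len__(self) -> int:
        return len(self.absolute)

    def __getitem__(self, i: int) -> RigidTransform2D:
        return self.absolute[i]


def _rot(theta_deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(theta_deg)), math.sin(math.radians(theta_deg))
    # acts on (row, col) vectors
    return np.array([[c, -s], [s, c]])


def compose(outer: RigidTransform2D, inner: RigidTransform2D) -> RigidTransform2D:
    """Transform equivalent to applying ``inner`` first, then ``outer``."""
    r = _rot(outer.theta)
    v = r @ np.array([inner.dy, inner.dx]) + np.array([outer.dy, outer.dx])
    return RigidTransform2D(dx=float(v[1]), dy=float(v[0]), theta=inner.theta + outer.theta)


def invert(t: RigidTransform2D) -> RigidTransform2D:
    r = _rot(-t.theta)
    v = -(r @ np.array([t.dy, t.dx]))
    return RigidTransform2D(dx=float(v[1]), dy=float(v[0]), theta=-t.theta)


def apply_transform(
    image: np.ndarray,
    t: RigidTransform2D,
    interpolation: str = "linear",
) -> np.ndarray:
    """Resample ``image`` under the forward rigid map of ``t``.

    Out-of-frame regions are filled with 0 (background).  Binary masks should
    use ``interpolation="nearest"``; boolean input is returned boolean.
    """
    if interpolation not in ("nearest", "linear"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    was_bool = image.dtype == bool
    if t.is_identity():
        return image.copy()
    order = 0 if interpolation == "nearest" else 1
    h, w = image.shape
    c = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    rinv = _rot(-t.theta)
    offset = c - rinv @ (c + np.array([t.dy, t.dx]))
    out = ndi.affine_transform(
        image.astype(np.uint8) if was_bool else image.astype(np.float32),
        matrix=rinv,
        offset=offset,
        order=order,
        mode="constant",
        cval=0,
        prefilter=False,
    )
    return out.astype(bool) if was_bool else out


# --------------------------------------------------------------------------
# pairwise estimation
# --------------------------------------------------------------------------

def _ncc_at(f: np.ndarray, m: np.ndarray, dy: int, dx: int) -> float:
    """Normalised cross-correlation of f and m shifted by (dy, dx), over the
    overlap region only."""
    h, w = f.shape
    ay0, ay1 = max(dy, 0), min(h + dy, h)
    ax0, ax1 = max(dx, 0), min(w + dx, w)
    if ay1 - ay0 < 8 or ax1 - ax0 < 8:
        return -1.0
    a = f[ay0:ay1, ax0:ax1]
    b = m[ay0 - dy:ay1 - dy, ax0 - dx:ax1 - dx]
    a = a - a.mean()
    b = b - b.mean()
    den = math.sqrt(float((a * a).sum()) * float((b * b).sum()))
    return float((a * b).sum() / den) if den > 0 else -1.0


def _parabolic(cm: float, c0: float, cp: float) -> float:
    den = cm - 2 * c0 + cp
    if den >= 0:
        return 0.0
    return float(np.clip(0.5 * (cm - cp) / den, -0.75, 0.75))


def _translation(f: np.ndarray, m: np.ndarray, max_shift: int,
                 n_candidates: int = 8) -> tuple[float, float, float]:
    """Windowed cross-correlation translation with NCC candidate re-ranking
    and clamped parabolic subpixel refinement.  Returns (dy, dx, ncc)."""
    f0 = f - f.mean()
    m0 = m - m.mean()
    corr = np.fft.irfft2(np.fft.rfft2(f0) * np.conj(np.fft.rfft2(m0)), s=f.shape)
    h, w = f.shape
    dys = np.fft.fftfreq(h, 1 / h).astype(int)
    dxs = np.fft.fftfreq(w, 1 / w).astype(int)
    wy = np.where(np.abs(dys) <= max_shift)[0]
    wx = np.where(np.abs(dxs) <= max_shift)[0]
    sub = corr[np.ix_(wy, wx)]
    order = np.argsort(sub.ravel())[::-1][:n_candidates]
    best, best_ncc = (0, 0), -2.0
    for flat in order:
        iy, ix = np.unravel_index(flat, sub.shape)
        dy, dx = int(dys[wy[iy]]), int(dxs[wx[ix]])
        v = _ncc_at(f, m, dy, dx)
        if v > best_ncc:
            best, best_ncc = (dy, dx), v
    dy, dx = best
    c = {(a, b): _ncc_at(f, m, dy + a, dx + b) for a in (-1, 0, 1) for b in (-1, 0, 1)}
    fy = dy + _parabolic(c[(-1, 0)], c[(0, 0)], c[(1, 0)])
    fx = dx + _parabolic(c[(0, -1)], c[(0, 0)], c[(0, 1)])
    return fy, fx, best_ncc


def _feature(image: np.ndarray, feature: str) -> np.ndarray:
    img = np.asarray(image, dtype=np.float32)
    if feature == "intensity":
        return img
    if feature == "counterstain":
        return np.minimum(img, COUNTERSTAIN_CAP)
    if feature == "stain":
        return ndi.gaussian_filter((img >= STAIN_THRESHOLD).astype(np.float32), 1.0)
    raise ValueError(f"unknown feature {feature!r}")


def estimate_pairwise(
    fixed: np.ndarray,
    moving: np.ndarray,
    max_rotation: float = 0.0,
    rotation_step: float = 0.5,
    max_shift: int = DEFAULT_MAX_SHIFT,
    feature: str = "intensity",
) -> RigidTransform2D:
    """Estimate the rigid transform aligning ``moving`` onto ``fixed``.

    When ``max_rotation`` > 0 a deterministic grid of rotations in
    ``[-max_rotation, +max_rotation]`` (step ``rotation_step`` degrees) is
    searched; the rotation with the best NCC wins (ties favour the smaller
    \\|theta\\|).  Empty or constant inputs yield the identity with a warning.
    """
    if fixed.shape != moving.shape:
        raise ValueError("fixed and moving must have the same shape")
    f = _feature(fixed, feature)
    m = _feature(moving, feature)
    if np.ptp(f) == 0 or np.ptp(m) == 0:
        warnings.warn("empty or constant input; returning identity transform")
        return RigidTransform2D()
    if max_rotation <= 0:
        dy, dx, _ = _translation(f, m, max_shift)
        return RigidTransform2D(dx=dx, dy=dy, theta=0.0)
    n_steps = int(math.floor(max_rotation / rotation_step + 1e-9))
    thetas = sorted(
        {round(k * rotation_step, 10) for k in range(-n_steps, n_steps + 1)} | {0.0},
        key=lambda t: (abs(t), t),
    )
    best: tuple[float, float, float, float] | None = None  # (ncc, theta, dy, dx)
    for theta in thetas:
        rotated = apply_transform(m, RigidTransform2D(theta=theta), "linear")
        dy, dx, ncc = _translation(f, rotated, max_shift)
        if best is None or ncc > best[0] + 1e-12:
            best = (ncc, theta, dy, dx)
    assert best is not None
    _, theta, dy, dx = best
    return RigidTransform2D(dx=dx, dy=dy, theta=theta)


def propagate(pairwise: Sequence[RigidTransform2D], anchor: int) -> TransformChain:
    """Chain pairwise transforms into absolute ones relative to ``anchor``.

    ``pairwise[i]`` must align slice ``i + 1`` onto slice ``i`` (i.e.
    ``estimate_pairwise(fixed=slice_i, moving=slice_{i+1})``).
    """
    n = len(pairwise) + 1
    if not (0 <= anchor < n):
        raise ValueError(f"anchor {anchor} out of range for {n} slices")
    absolute: list[RigidTransform2D | None] = [None] * n
    absolute[anchor] = RigidTransform2D()
    for j in range(anchor + 1, n):
        absolute[j] = compose(absolute[j - 1], pairwise[j - 1])
    for j in range(anchor - 1, -1, -1):
        absolute[j] = compose(absolute[j + 1], invert(pairwise[j]))
    return TransformChain(absolute=list(absolute), anchor=anchor)  # type: ignore[arg-type]


#: per-link measurement noise (px) used as inverse-variance weights
_LINK_SIGMA = {
    ("counterstain", 1): 0.35,
    ("counterstain", 2): 0.7,
    ("stain", "vessel_stain"): 0.25,
    ("stain", "epithelium_stain"): 0.6,
}


def register_series(
    series: "SectionSeries",
    anchor: int | None = None,
    max_shift: int = DEFAULT_MAX_SHIFT,
    offsets: Sequence[int] = (1, 2, 3),
    irls_iterations: int = 4,
    irls_scale: float = 0.5,
) -> TransformChain:
    """Solve per-slice absolute translations for a serial-section series.

    Measures redundant pairwise links — counterstain-texture links between
    near neighbours (offsets 1 and 2) and stain-channel links between
    same-stain slices (all requested offsets) — and solves the
    overdetermined difference system by iteratively reweighted least squares
    (Cauchy weights with scale ``irls_scale`` px).  The anchor slice
    (default: middle) maps to the identity.  Rotation is not solved by the
    chain; section jitter about the slide normal is assumed negligible.
    """
    sl = series.slices
    n = len(sl)
    if n < 2:
        raise ValueError("need at least two slices")
    anchor = n // 2 if anchor is None else anchor
    if not (0 <= anchor < n):
        raise ValueError("anchor index out of range")
    f_counter = [_feature(s.image, "counterstain") for s in sl]
    f_stain = [_feature(s.image, "stain") for s in sl]

    links: list[tuple[int, int, float, float, float]] = []  # i, j, dy, dx, sigma
    for off in offsets:
        for i in range(n - off):
            j = i + off
            if off <= 2 and np.ptp(f_counter[i]) > 0 and np.ptp(f_counter[j]) > 0:
                dy, dx, _ = _translation(f_counter[i], f_counter[j], max_shift)
                links.append((i, j, dy, dx, _LINK_SIGMA[("counterstain", off)]))
            if sl[i].stain == sl[j].stain and np.ptp(f_stain[i]) > 0 and np.ptp(f_stain[j]) > 0:
                dy, dx, _ = _translation(f_stain[i], f_stain[j], max_shift)
                links.append((i, j, dy, dx, _LINK_SIGMA[("stain", sl[i].stain)]))
    if not links:
        warnings.warn("no usable registration links; returning identity chain")
        return TransformChain([RigidTransform2D() for _ in range(n)], anchor)

    a_mat = np.zeros((len(links) + 1, n))
    b_vec = np.zeros((len(links) + 1, 2))
    w0 = np.zeros(len(links) + 1)
    for k, (i, j, dy, dx, sigma) in enumerate(links):
        # link measures the shift aligning slice j onto slice i:
        # p_j - p_i = measured  =>  p_i - p_j = -measured
        a_mat[k, i] = 1.0
        a_mat[k, j] = -1.0
        b_vec[k] = (-dy, -dx)
        w0[k] = 1.0 / sigma
    a_mat[-1, anchor] = 1.0
    w0[-1] = 1e3  # gauge constraint
    w = w0.copy()
    p = np.zeros((n, 2))
    for _ in range(irls_iterations):
        p, *_ = np.linalg.lstsq(a_mat * w[:, None], b_vec * w[:, None], rcond=None)
        resid = a_mat @ p - b_vec
        rn = np.hypot(resid[:, 0], resid[:, 1])
        w = w0 / (1.0 + (rn / irls_scale) ** 2)
        w[-1] = 1e3
    p = p - p[anchor]
    return TransformChain(
        [RigidTransform2D(dx=float(v[1]), dy=float(v[0])) for v in p], anchor
    )


def pair_epithelium_indices(stains: Sequence[str]) -> dict[int, int]:
    """Map every vessel-stain slice index to its nearest epithelium-stain
    slice index (ties broken toward the lower index)."""
    epi = [i for i, s in enumerate(stains) if s == "epithelium_stain"]
    if not epi:
        raise ValueError("series contains no epithelium-stain slices")
    epi_arr = np.array(epi)
    pairs: dict[int, int] = {}
    for i, s in enumerate(stains):
        if s == "epithelium_stain":
            continue
        d = np.abs(epi_arr - i)
        pairs[i] = int(epi_arr[int(np.argmin(d))])  # argmin takes first (lower) on ties
    return pairs


def assign_epithelium(
    series: "SectionSeries",
    chain: TransformChain,
    epithelium_masks: Mapping[int, np.ndarray],
) -> dict[int, tuple[int, np.ndarray]]:
    """Pair each vessel-stain slice with its nearest epithelium mask, both
    resampled into the aligned (anchor) frame.

    Returns ``{vessel_index: (epithelium_index, aligned_epithelium_mask)}``.
    """
    stains = [s.stain for s in series.slices]
    pairs = pair_epithelium_indices(stains)
    aligned_epi: dict[int, np.ndarray] = {}
    out: dict[int, tuple[int, np.ndarray]] = {}
    for v_idx, e_idx in pairs.items():
        if e_idx not in aligned_epi:
            aligned_epi[e_idx] = apply_transform(
                np.asarray(epithelium_masks[e_idx], dtype=bool), chain[e_idx], "nearest"
            )
        out[v_idx] = (e_idx, aligned_epi[e_idx])
    return out
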