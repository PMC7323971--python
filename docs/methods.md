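# Methods

## Problem and model

Magnifying narrow-band (blue-light) endoscopy visualises colonic mucosal
microvessels as brown lines because haemoglobin strongly absorbs ~410 nm
light; only vessels in the most superficial tissue remain visible.
`mucosa3d` reconstructs a mucosal block from serially sectioned,
immunostained slides and quantifies vessel visibility as a function of the
depth *d* from the mucosal surface to the centre of the vessel lumen.

The serial-section protocol modelled throughout is: 100 consecutive
sections of 3 μm, with the epithelium stain (cytokeratin, marking crypt
glands) on every third slice and the vessel-endothelium stain (which marks
the vessel *wall*, leaving the lumen unstained) on the rest. Sections may
be cut perpendicular to the mucosal surface (`vertical_section`: depth is
an in-slice axis, the stack axis is lateral) or parallel to it
(`horizontal_section`: depth accumulates across the stack).

The pipeline is: stain segmentation with lumen filling → rigid
slice-to-slice registration → anisotropic stacking → surface extraction →
per-vessel depth → depth-windowed en-face projections → per-area
visible-vs-invisible depth statistics (Mann–Whitney U, visibility-boundary
estimate).

## Synthetic phantom

No histology is distributed with the study this pipeline operationalises,
so a phantom generator provides inputs with exact ground truth. It builds a
labelled voxel volume (background, epithelium, stroma, vessel wall, vessel
lumen, erythrocyte extravasation) at sectioning resolution:

* **Surface.** Flat at `surface_margin_um` (default 16 μm of background
  above the tissue), optionally sinusoidal. The ground-truth surface is the
  voxelised design surface; all true depths are measured against it, so the
  bookkeeping is exact by construction.
* **Crypts.** Vertical glands on a square lattice (`crypt_pitch`, default
  100 μm; radius 25 μm) with an open orifice (lumen radius 0.55 R), an
  epithelial annulus, a thin surface epithelium band, and small positional
  jitter. The `adenoma`/`carcinoma` classes perturb positions and calibres
  by `crypt_distortion` and scale vessel radii up.
* **Vessels.** Two layouts. `honeycomb` places capillaries on the crypt
  lattice edges (the mesh that wraps around the glands in normal mucosa),
  plus vertically standing vessels between crypts for the neoplastic
  classes. `straight` lays disjoint capped tubes perpendicular to the
  slicing plane at controlled depths drawn from `vessel_depth_range`; tube
  ends are capped with wall so every lumen is enclosed in any section.
  Radii are Gaussian (mean 5 μm, SD 1 μm) around a 3 μm wall; in the
  straight layout draws are capped so neighbouring tubes always keep >6 px
  of stroma between their walls — the layout exists to provide separated
  components with independent known depths, and the broken-wall rescue
  cannot distinguish an inter-vessel gap from a wall gap.
* **Ground truth.** Per 26-connected vessel component: lumen-voxel centroid
  (in μm, anisotropy respected) and its depth below the design surface.
  For a flat surface with a collapsed depth range the recorded depths equal
  the requested value exactly.

**Virtual sectioning** cuts one voxel plane per section (the volume is
built so the voxel pitch along the sectioning axis equals the 3 μm slice
thickness), renders stain-positive structures at intensity 1.0 and all
other tissue at a counterstain level of 0.2 modulated by a smooth 3D
stromal-texture field (SD 0.05, correlation length ~2 voxels). The texture
is what makes consecutive sections of *different* stains registrable at
sub-pixel precision, exactly as shared counterstain texture does on real
slides. Each section receives a rigid jitter (uniform translation up to
`jitter_max_translation` px, optional rotation) and additive Gaussian
noise; true transforms are recorded. A `broken_wall_fraction` of in-plane
wall rings lose a random 60–110° arc, emulating undetectably thin walls.

**Virtual endoscopy render.** Each vessel component darkens its top-view
footprint by `exp(-d / visibility_scale)` and contributes nothing beyond
`hard_cutoff`; extravasation renders as a diffuse dark patch. Defaults:
scale 40 μm, cutoff 80 μm — a phenomenological contrast model with the
cutoff at the empirically reported visible-range boundary, not a light-
transport model. Because darkening is per *component*, the render is
meaningful for disjoint-tube phantoms; a fully connected capillary network
collapses to one component and one depth.

## Segmentation

Stain extraction is a global threshold (`fixed`, default 0.5, or Otsu
`automatic`; a constant image yields an empty mask with a warning, not an
error). The vessel stain marks walls only, so vessels appear as rings;
`fill_vessel_lumens` converts them to filled vessels by dilating with a
disk of `closing_radius` px (default 2), filling every hole not connected
to the image border, and eroding back — a morphological closing applied to
the *filled* shape. The order matters: for one- or two-pixel walls the
bridge formed by a plain closing is destroyed by its own erosion, whereas
the filled lumen survives. The operator seals wall gaps narrower than
twice the radius, is extensive (output ⊇ input), idempotent on vessel-like
shapes, and pixel-exact on intact digitised rings (verified over radii
2.5–9 px and thicknesses 1–3 px). Epithelium segmentation adds small-object
removal (`min_object_area`, default 4 px²) and hole filling within the
bands.

## Registration

Sections are aligned by recovering one rigid transform per slice relative
to an anchor (default: the middle slice). The pairwise estimator computes
a windowed cross-correlation (default ±15 px — consecutive sections cannot
jump far), re-ranks the top candidate peaks by their true normalised
cross-correlation over the overlap region, and refines to sub-pixel
precision with a clamped parabolic fit on the NCC surface. The re-ranking
is essential: quasi-periodic structure (crypt lattices, fields of similar
vessel rings) produces ghost correlation peaks that plain or phase
correlation mistakes for the true one.

A single sequential chain of pairwise estimates accumulates content-driven
error (alternating stains light up different structures, and crypt
cross-sections genuinely move between sections), so `register_series`
measures redundant links — same-stain pairs on the smoothed stain channel
at offsets 1–3 (vessel rings persist across sections; link noise ≈0.2 px),
and all near neighbours on the counterstain texture with the stain signal
capped at 0.35 (link noise ≈0.35 px at offset 1) — and solves the
overdetermined difference system for absolute translations by iteratively
reweighted least squares (Cauchy weights, scale 0.5 px, four iterations),
which suppresses occasional ghost-locked links. Rotation is searched on a
deterministic grid in `estimate_pairwise` when requested but is not solved
by the chain; slide jitter about the normal is assumed negligible by
default. On 100-section phantoms with jitter up to 5 px this recovers
absolute translations with RMSE ≈0.3 px and end-to-end drift well under
1 px.

## Reconstruction and depth

Filled vessel masks and epithelium masks are resampled into the anchor
frame (nearest-neighbour for masks) and stacked; each channel is propagated
to the other stain's slice positions by nearest-slice copy (ties to the
lower index), the discrete analogue of superimposing adjacent sections.
Volumes are stored depth-first (`(z, y, x)`, anisotropic voxel sizes kept
explicit).

The mucosal surface is the first foreground voxel (epithelium or vessel)
per column from the luminal side, median-smoothed over 15 px — just wider
than a crypt orifice, so open gland mouths are bridged. Depth is computed
in `axis` mode (straight down the depth axis, the way a vertical section is
read under a microscope; the default) or `euclidean` mode (3D distance to
the nearest surface point, for strongly tilted surfaces); both agree
exactly on a flat surface. Component depth is evaluated at the component
centroid — the "centre of the vessel lumen" — with anisotropy respected;
vessel voxels over invalid columns are excluded and counted.

Depth-windowed projections collapse vessel voxels with depth ≤ w along the
depth axis (binary or per-column count); 50/100/150 μm is the standard
triplet. Nesting (w₁ ≤ w₂ ⇒ projection ⊆ projection) holds by
construction. Cross-sections sample both channels along a top-view
polyline with a perpendicular thickness union.

## Visibility analysis

The matched region of interest is divided into `n_areas` equal cells along
its long axis (the validation geometry is a 0.86 mm line in 50 cells of
17.2 μm). Per cell, the nearest-vessel depth is the minimum lumen-centre
depth over components whose top-view footprint touches the cell, up to
`max_depth` (400 μm); cells without such a vessel are censored and excluded
from the test. Visibility comes either from a manual label CSV (one 0/1
flag per area) or from the virtual endoscopy image (visible iff the mean
vessel contrast over the cell's vessel pixels exceeds
`contrast_threshold`, default 0.01).

The two depth samples are compared with a two-sided Mann–Whitney U test:
full enumeration of rank assignments (midranks for ties) when n₁+n₂ ≤ 12,
otherwise the normal approximation with tie and continuity correction
(simulated type-I error 0.042–0.051 at α = 0.05, n₁ = n₂ = 25, 5000
replicates). The visibility boundary is the midpoint between the deepest
visible and the shallowest invisible vessel; when the groups overlap, the
estimate falls back to the depth threshold minimising visible/invisible
misclassification, with a warning.

A small lateral offset between the endoscopic and histological frames can
make single cells discordant (visible but deep, or invisible but shallow);
the pipeline reproduces this when the reconstruction's anchor frame is
jittered relative to the phantom frame. `reconcile_gaps` re-assigns a
discordant cell to the laterally nearest component within
`lateral_tolerance` μm of its boundary when that resolves the discordance,
and flags and excludes it otherwise. It is off by default and its effect is
always reported (`n_corrected`, `n_excluded`).

## Defaults and problem sizes

The default pipeline phantom is a vertical-section block of
1200 × 300 × 336 μm (600 × 100 × 168 voxels at 2 × 3 × 2 μm), 100 sections,
straight layout with 40 tubes at depths 15–250 μm among a normal crypt
lattice, jitter 3 px, noise SD 0.02, 10% broken walls — the straight layout
gives the dense, independent depth sample the per-area statistic needs.
Parameter-recovery experiments use 36 tubes spanning 10–300 μm (depth
recovery), and a 4 mm-wide, 220-tube block with 220 analysis cells
(boundary recovery at cutoffs 50/80/120 μm). Vessel density and calibre
distributions are free phantom parameters chosen for plausibility; they are
not calibrated to any specimen.

## What the phantom does and does not show

Passing recovery tests shows the pipeline's operators are correct and
well-conditioned under known geometry, jitter, noise and wall breakage.
The phantom does not emulate: tissue deformation and shrinkage between
slides (nonrigid effects the rigid model cannot absorb), staining
variability beyond global thresholdability, real DAB/hematoxylin colour
(single-channel intensities throughout), optical light transport (the
exponential contrast model is phenomenological), or connected capillary
network topology in the depth statistics (component-based depths are
meaningful for disjoint segments; a fully connected honeycomb collapses to
one component). Horizontal-section stacks carry the depth axis at
slice-thickness resolution plus nearest-slice channel propagation, so their
depth errors are of order the slice pitch (~4–5 μm) rather than the ~2 μm
(one in-plane voxel) of vertical stacks — consistent with vertical
sectioning being the mode of choice for superficial-depth analysis.

## Numerical choices

Voxel coordinates put index k at k·(voxel size) μm; the surface voxelises
by ceiling, and recovered depths inherit at most one voxel of surface
quantisation plus the anchor frame's sub-voxel offset. Component labelling
uses 26-connectivity; 2D operations use 8-connectivity. Mask resampling is
nearest-neighbour, intensity resampling bilinear, out-of-frame regions are
background. The IRLS gauge is fixed by a high-weight identity row on the
anchor. Parabolic sub-pixel refinements are clamped to ±0.75 px and
degenerate (non-concave) fits fall back to the integer peak. All
randomness flows from the single `rng_seed`; stage-specific generators are
spawned from it with fixed offsets, so every artefact is bit-reproducible
given the seed.
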