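# mucosa3d

3D reconstruction of serially sectioned colonic mucosa and depth-resolved
analysis of which microvessels are visible on magnifying narrow-band
(blue-light) endoscopy.

Narrow-band endoscopy accentuates superficial mucosal capillaries — they
absorb the ~410 nm light and appear as brown lines — but how deep a vessel
can lie and still be seen is not directly observable endoscopically. The
way to measure it is histological: cut the resected mucosa into ~100
consecutive 3 μm sections, stain the vessel endothelium (CD34-like; the
wall stains, the lumen does not, so vessels appear as rings) on most
sections and the crypt epithelium (CAM5.2-like) on every third, align the
sections, stack them into a 3D block, and read off the depth from the
mucosal surface to the centre of each vessel lumen. Dividing a matched
stretch of mucosa into equal areas, scoring each area visible/invisible on
the endoscopic image and measuring each area's nearest-vessel depth on the
reconstruction turns "how deep can I see?" into a two-sample problem: the
visible and invisible depth distributions are compared with a Mann–Whitney
U test, and the visibility boundary is estimated from the deepest visible
and shallowest invisible vessel.

`mucosa3d` implements that entire pipeline — stain segmentation with
ring-to-lumen filling, rigid slice-to-slice registration, anisotropic
stacking, mucosal-surface extraction, per-vessel depth, depth-windowed
en-face projections (50/100/150 μm), and the per-area visibility
statistics — together with a synthetic phantom generator that builds
mucosa blocks (crypts, capillaries, broken walls, slide jitter, stain
noise) with exact ground truth, and a virtual narrow-band renderer
(per-vessel darkening `exp(-depth/scale)` with a hard cutoff, default
80 μm). Every stage is therefore testable by parameter recovery without
any external data. It is aimed at endoscopic-imaging and digital-pathology
researchers who want a reproducible, scriptable stand-in for the manual
Photoshop-and-commercial-renderer workflow such studies have used.

## Worked example

Run the default experiment — a 1.2 × 0.3 mm phantom block sectioned into
100 slices of 3 μm, segmented, registered, reconstructed, projected and
analysed over 50 areas:

```bash
mucosa3d pipeline --seed 1 --out runs/demo
```

This writes the section series (`series.tif` + JSON manifest), per-slice
masks, recovered transforms (`transforms.csv`), the reconstructed volume,
50/100/150 μm projections, `area_records.csv` and `analysis.json`. With
seed 1:

```json
{
 "mann_whitney": {"U": 55.0, "n_visible": 17, "n_invisible": 33,
                  "p_two_sided": 4.04e-06},
 "summary": {"median_visible_um": 48.3, "median_invisible_um": 176.3,
             "boundary_estimate_um": 70.2, ...}
}
```

Read: areas whose vessels are visible on the virtual endoscopy image have
a median nearest-vessel depth of 48.3 μm, invisible areas 176.3 μm, and
the difference is highly significant (p ≈ 4×10⁻⁶) — vessels visible on
narrow-band imaging are the superficial ones. A few areas are discordant
because the endoscopic view and the reconstruction sit in laterally
offset frames (a few-micrometre gap, as happens with real material);
enabling the lateral-gap correction

```yaml
# rec.yaml
analysis:
  reconcile: true
```

```bash
mucosa3d pipeline --config rec.yaml --seed 1 --out runs/demo_rec
```

re-assigns 4 areas, excludes 5 unresolvable ones, and the two depth ranges
separate cleanly: visible 14.2–78.3 μm, invisible 128.3–248.4 μm
(p ≈ 4×10⁻⁸) — i.e. the visible range ends at roughly 80 μm below the
surface, which is exactly where this phantom's renderer cutoff was set.

Stages can be re-run individually against the same directory
(`mucosa3d register --out runs/demo ...`), and `--orientation`,
`--windows`, `--n-areas`, `--max-depth` override the config from the
command line.

## Layout

```
src/mucosa3d/
  phantom.py         synthetic mucosa volumes, virtual sectioning, BLI render
  segmentation.py    stain thresholding, ring-to-lumen filling
  registration.py    rigid transforms, pairwise NCC estimator, chain solver
  reconstruction.py  stacking, surface map, depth field, projections
  visibility.py      area grid, nearest-vessel depths, Mann–Whitney U, summary
  io.py / config.py / runner.py / cli.py   formats, config, pipeline, CLI
docs/methods.md      model, assumptions, parameter rationale, limitations
```
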