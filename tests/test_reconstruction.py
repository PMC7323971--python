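"""Stacking, surface extraction, depth fields, projections, cross-sections."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from mucosa3d import (
    LabeledVolume,
    SurfaceMap,
    build_phantom,
    compute_depth_field,
    cross_section,
    depth_window_projection,
    extract_surface,
    register_series,
    section_volume,
    stack,
)

from conftest import match_to_truth, segment_series, small_spec

CONN26 = np.ones((3, 3, 3), dtype=bool)


def _flat_volume(nz=40, ny=12, nx=20, vox=(2.0, 2.0, 2.0)):
    epi = np.zeros((nz, ny, nx), dtype=bool)
    ves = np.zeros((nz, ny, nx), dtype=bool)
    epi[0] = True  # surface sheet at depth coordinate 0
    return LabeledVolume(epithelium=epi, vessel=ves, voxel_size=vox,
                         orientation="vertical_section")


class TestStack:
    def test_hundred_slices_span_300_um_horizontal(self):
        spec = small_spec(volume_extent=(120, 60, 100), voxel_size=(3.0, 3.0, 3.0),
                          sectioning_axis="horizontal_section", n_slices=100,
                          n_vessels=4, crypt_pitch=150.0)
        volume, _ = build_phantom(spec)
        series = section_volume(volume, spec)
        chain = register_series(series)
        vm, em = segment_series(series)
        out = stack(series, chain, vm, em)
        assert out.vessel.shape[0] == 100
        assert out.vessel.shape[0] * out.voxel_size[0] == pytest.approx(300.0)

    def test_millimetre_block_dimensions_representable(self):
        # a 1.5 mm x 1.0 mm x 0.4 mm mucosal block at 10 um voxels
        vol = LabeledVolume(
            epithelium=np.zeros((40, 100, 150), dtype=bool),
            vessel=np.zeros((40, 100, 150), dtype=bool),
            voxel_size=(10.0, 10.0, 10.0),
            orientation="horizontal_section",
        )
        nz, ny, nx = vol.vessel.shape
        extent_mm = (nx * 10 / 1000, ny * 10 / 1000, nz * 10 / 1000)
        assert extent_mm == (1.5, 1.0, 0.4)

    def test_empty_masks_give_empty_channels(self):
        spec = small_spec(n_slices=6)
        volume, _ = build_phantom(spec)
        series = section_volume(volume, spec)
        chain = register_series(series)
        shape = series.slices[0].image.shape
        empty = np.zeros(shape, dtype=bool)
        vm = {s.index: empty for s in series.slices if s.stain == "vessel_stain"}
        em = {s.index: empty for s in series.slices if s.stain == "epithelium_stain"}
        out = stack(series, chain, vm, em)
        assert not out.vessel.any() and not out.epithelium.any()

    def test_shape_mismatch_rejected(self):
        spec = small_spec(n_slices=6)
        volume, _ = build_phantom(spec)
        series = section_volume(volume, spec)
        chain = register_series(series)
        vm, em = segment_series(series)
        bad = dict(vm)
        bad[min(bad)] = np.zeros((3, 3), dtype=bool)
        with pytest.raises(ValueError, match="shape"):
            stack(series, chain, bad, em)


class TestExtractSurface:
    def test_flat_surface_recovered_exactly(self):
        vol = _flat_volume()
        surf = extract_surface(vol, smoothing_window=0)
        assert np.all(surf.valid)
        assert np.all(surf.height == 0.0)

    def test_sinusoidal_surface_recovered_within_one_voxel(self):
        spec = small_spec(include_crypts=False, surface_amplitude_um=12.0,
                          surface_wavelength_um=200.0, n_vessels=0)
        volume, truth = build_phantom(spec)
        lv = LabeledVolume.from_tissue_volume(volume)
        surf = extract_surface(lv, smoothing_window=3)
        err = np.abs(surf.height - truth.surface_height)
        assert err.max() <= lv.voxel_size[0]

    def test_background_column_marked_invalid(self):
        vol = _flat_volume()
        vol.epithelium[:, :, 5] = False  # a column of pure background
        surf = extract_surface(vol, smoothing_window=0)
        assert not surf.valid[:, 5].any()
        assert surf.valid[:, 6].all()

    def test_empty_volume_rejected(self):
        vol = _flat_volume()
        vol.epithelium[:] = False
        with pytest.raises(ValueError):
            extract_surface(vol)


class TestComputeDepthField:
    def test_flat_surface_component_depth_is_axis_coordinate(self):
        vol = _flat_volume()
        vol.vessel[14:17, 4:8, 4:16] = True  # centroid at z index 15 -> 30 um
        surf = extract_surface(vol, smoothing_window=0)
        field = compute_depth_field(vol, surf, mode="axis")
        assert len(field.component_depths) == 1
        assert field.component_depths[0][1] == pytest.approx(30.0)

    def test_axis_and_euclidean_agree_on_flat_surface(self):
        vol = _flat_volume()
        vol.vessel[10:13, 2:6, 3:9] = True
        vol.vessel[25:28, 7:11, 12:18] = True
        surf = extract_surface(vol, smoothing_window=0)
        ax = compute_depth_field(vol, surf, mode="axis")
        eu = compute_depth_field(vol, surf, mode="euclidean")
        for (cid_a, da), (cid_e, de) in zip(ax.component_depths, eu.component_depths):
            assert cid_a == cid_e
            assert da == pytest.approx(de, abs=1e-6)

    def test_phantom_component_depths_recovered(self):
        spec = small_spec(noise_sd=0.0, jitter_max_translation=0.0, n_slices=15)
        volume, truth = build_phantom(spec)
        series = section_volume(volume, spec)
        chain = register_series(series)
        vm, em = segment_series(series)
        lv = stack(series, chain, vm, em)
        surf = extract_surface(lv)
        field = compute_depth_field(lv, surf)
        errors = match_to_truth(field, truth)
        # tolerance: one slice thickness + one pixel, as the bookkeeping allows
        assert errors.max() <= spec.slice_thickness + 2.0

    def test_invalid_columns_excluded_and_counted(self):
        vol = _flat_volume()
        vol.vessel[20:22, 4:6, 4:8] = True
        vol.epithelium[:, 4:6, 4:8] = False  # no tissue above that vessel
        fg_valid = (vol.epithelium | vol.vessel).any(axis=0)
        surf = SurfaceMap(height=np.zeros(fg_valid.shape), valid=vol.epithelium.any(axis=0))
        field = compute_depth_field(vol, surf, mode="axis")
        assert field.n_excluded == int(vol.vessel[:, 4:6, 4:8].sum())


class TestProjections:
    def test_nesting_50_100_150(self, serial_reconstruction):
        volume, _, field = serial_reconstruction
        p50 = depth_window_projection(volume, field, 50.0).image
        p100 = depth_window_projection(volume, field, 100.0).image
        p150 = depth_window_projection(volume, field, 150.0).image
        assert not (p50 & ~p100).any()
        assert not (p100 & ~p150).any()

    def test_window_beyond_max_depth_is_full_top_view(self, serial_reconstruction):
        volume, _, field = serial_reconstruction
        full = depth_window_projection(volume, field, 10000.0).image
        assert np.array_equal(full, volume.vessel.any(axis=0))

    def test_projection_components_bounded_by_preimage_components(self, serial_reconstruction):
        # projecting the depth-selected voxels can merge pieces but never
        # create components beyond those of its 3D preimage
        volume, _, field = serial_reconstruction
        d = np.nan_to_num(field.depth, nan=np.inf)
        for w in (50.0, 100.0, 150.0):
            pre = volume.vessel & (d <= w)
            _, n_pre = ndi.label(pre, structure=CONN26)
            img = depth_window_projection(volume, field, w).image
            _, n2d = ndi.label(img, structure=np.ones((3, 3), dtype=bool))
            assert n2d <= n_pre

    def test_nonpositive_window_rejected(self, serial_reconstruction):
        volume, _, field = serial_reconstruction
        with pytest.raises(ValueError):
            depth_window_projection(volume, field, 0.0)


class TestCrossSection:
    def test_axis_aligned_line_reproduces_volume_plane(self):
        vol = _flat_volume()
        vol.vessel[10:14, :, 8:12] = True
        out = cross_section(vol, [(3, 0), (3, 19)], thickness=1)
        assert out.shape == (2, vol.vessel.shape[0], 20)
        assert np.array_equal(out[1], vol.vessel[:, 3, :])

    def test_vessel_appears_at_its_depth_row(self):
        vol = _flat_volume()
        z = 17  # depth 34 um at 2 um/voxel
        vol.vessel[z - 1:z + 2, 5:8, 6:10] = True
        out = cross_section(vol, [(6, 0), (6, 19)])
        rows = np.nonzero(out[1].any(axis=1))[0]
        assert abs(rows.mean() - z) <= 1.0

    def test_thick_section_is_union_of_thin_ones(self):
        vol = _flat_volume()
        rng = np.random.default_rng(4)
        vol.vessel[rng.random(vol.vessel.shape) < 0.05] = True
        thick = cross_section(vol, [(5, 0), (5, 19)], thickness=3)
        union = np.zeros_like(thick)
        for y in (4, 5, 6):
            union |= cross_section(vol, [(y, 0), (y, 19)], thickness=1)
        assert np.array_equal(thick, union)

    def test_degenerate_line_rejected(self):
        vol = _flat_volume()
        with pytest.raises(ValueError):
            cross_section(vol, [(3, 3), (3, 3)])
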