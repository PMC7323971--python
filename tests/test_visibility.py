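"""Area grid, nearest-vessel depths, Mann-Whitney U, gap reconciliation
and the visibility summary."""

import math
from itertools import combinations

import numpy as np
import pytest
from scipy.stats import mannwhitneyu, rankdata

from mucosa3d import (
    AreaRecord,
    LabeledVolume,
    build_phantom,
    compute_depth_field,
    divide_roi,
    extract_surface,
    label_visibility,
    mann_whitney_u,
    measure_area_depths,
    reconcile_gaps,
    render_virtual_bli,
    summarize,
)
from mucosa3d.visibility import nearest_vessel_depth, records_to_frame

from conftest import small_spec


class TestDivideRoi:
    def test_paper_geometry_860um_line_into_50_cells(self):
        grid = divide_roi((0.0, 0.0, 20.0, 860.0), 50)
        widths = [hi - lo for lo, hi in grid.cells]
        assert all(w == pytest.approx(17.2) for w in widths)
        assert sum(widths) == pytest.approx(860.0, abs=1e-9)

    def test_two_cells_on_100um(self):
        grid = divide_roi((0.0, 0.0, 10.0, 100.0), 2)
        assert grid.cells == ((0.0, 50.0), (50.0, 100.0))

    def test_partition_is_exact(self):
        grid = divide_roi((0.0, 0.0, 5.0, 333.0), 7)
        assert sum(hi - lo for lo, hi in grid.cells) == pytest.approx(333.0, abs=1e-9)
        for (_, hi), (lo, _) in zip(grid.cells[:-1], grid.cells[1:]):
            assert hi == lo

    def test_too_few_areas_or_too_narrow_rejected(self):
        with pytest.raises(ValueError):
            divide_roi((0, 0, 10, 100), 1)
        with pytest.raises(ValueError):
            divide_roi((0, 0, 10, 100), 60, pixel_size=2.0)


def _two_tube_scene():
    """Volume with tubes at 30 and 120 um in the same top-view cell and a
    tube at 450 um elsewhere."""
    nz, ny, nx = 260, 10, 60
    ves = np.zeros((nz, ny, nx), dtype=bool)
    epi = np.zeros_like(ves)
    epi[0] = True
    for z_um, x0 in ((30, 5), (120, 15), (450, 40)):
        z = z_um // 2
        ves[z - 1:z + 2, 2:8, x0:x0 + 4] = True
    vol = LabeledVolume(epithelium=epi, vessel=ves, voxel_size=(2.0, 2.0, 2.0),
                        orientation="vertical_section")
    surf = extract_surface(vol, smoothing_window=0)
    field = compute_depth_field(vol, surf)
    return vol, field


class TestNearestVesselDepth:
    def test_minimum_over_components_in_cell(self):
        vol, field = _two_tube_scene()
        grid = divide_roi((0.0, 0.0, 20.0, 120.0), 2)  # cells [0,60) and [60,120)
        d = nearest_vessel_depth(grid.cells[0], grid, field, vol, max_depth=400)
        assert d == pytest.approx(30.0, abs=2.0)

    def test_component_beyond_max_depth_censored(self):
        vol, field = _two_tube_scene()
        grid = divide_roi((0.0, 0.0, 20.0, 120.0), 2)
        assert nearest_vessel_depth(grid.cells[1], grid, field, vol, max_depth=400) is None

    def test_exact_recovery_one_component_per_cell(self):
        spec = small_spec(noise_sd=0.0, include_crypts=False, n_vessels=8,
                          vessel_depth_range=(20.0, 200.0), rng_seed=21)
        volume, truth = build_phantom(spec)
        lv = LabeledVolume.from_tissue_volume(volume)
        surf = extract_surface(lv, smoothing_window=0)
        field = compute_depth_field(lv, surf)
        ny, nx = lv.vessel.shape[1:]
        roi = (0.0, 0.0, ny * lv.voxel_size[1], nx * lv.voxel_size[2])
        grid = divide_roi(roi, 8, pixel_size=lv.voxel_size[2])
        records = measure_area_depths(grid, field, lv, max_depth=400)
        truth_by_x = sorted(truth.vessel_components, key=lambda t: t[1][0])
        got = [r.nearest_depth for r in records if r.nearest_depth is not None]
        assert len(got) == len(truth_by_x)
        for g, (_, _, want) in zip(got, truth_by_x):
            assert g == pytest.approx(want, abs=1e-6)


class TestLabelVisibility:
    def test_zero_contrast_image_all_invisible(self):
        vol, field = _two_tube_scene()
        grid = divide_roi((0.0, 0.0, 20.0, 120.0), 4)
        records = measure_area_depths(grid, field, vol)
        out = label_visibility(records, grid, np.ones(vol.vessel.shape[1:]), volume=vol)
        assert all(r.visible is False for r in out)

    def test_manual_labels_round_trip(self, tmp_path):
        records = [AreaRecord(i, 10.0 * i) for i in range(6)]
        flags = [1, 0, 1, 1, 0, 0]
        csv = tmp_path / "labels.csv"
        csv.write_text("area_id,visible\n" + "\n".join(f"{i},{f}" for i, f in enumerate(flags)))
        out = label_visibility(records, None, str(csv))
        assert [int(r.visible) for r in out] == flags
        assert all(r.visibility_source == "manual_label" for r in out)

    def test_label_count_mismatch_rejected(self):
        records = [AreaRecord(i, 10.0) for i in range(4)]
        with pytest.raises(ValueError, match="counts"):
            label_visibility(records, None, [1, 0])

    def test_renderer_cutoff_segregates_shallow_from_deep(self):
        spec = small_spec(volume_extent=(640, 30, 170), n_slices=10, n_vessels=16,
                          vessel_depth_range=(10.0, 300.0), include_crypts=False,
                          rng_seed=8)
        volume, truth = build_phantom(spec)
        lv = LabeledVolume.from_tissue_volume(volume)
        surf = extract_surface(lv, smoothing_window=0)
        field = compute_depth_field(lv, surf)
        ny, nx = lv.vessel.shape[1:]
        roi = (0.0, 0.0, ny * lv.voxel_size[1], nx * lv.voxel_size[2])
        grid = divide_roi(roi, 16, pixel_size=lv.voxel_size[2])
        records = measure_area_depths(grid, field, lv)
        bli = render_virtual_bli(volume, truth, visibility_scale=40.0, hard_cutoff=80.0)
        out = label_visibility(records, grid, bli, volume=lv)
        for r in out:
            if r.nearest_depth is None:
                assert r.visible is False
            elif abs(r.nearest_depth - 80.0) > 2.0:  # off the cutoff knife-edge
                assert r.visible == (r.nearest_depth <= 80.0)


def _enumeration_p(a, b):
    """Independent oracle: full enumeration over rank splits."""
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    n1 = len(a)
    mu = n1 * len(b) / 2
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    stats = [
        abs(sum(ranks[list(idx)]) - n1 * (n1 + 1) / 2 - mu)
        for idx in combinations(range(len(pooled)), n1)
    ]
    target = abs(u_obs - mu)
    return sum(s >= target - 1e-9 for s in stats) / len(stats)


class TestMannWhitneyU:
    def test_fully_separated_triples(self):
        res = mann_whitney_u([1, 2, 3], [10, 11, 12])
        assert res.U == 0
        assert res.p_two_sided == pytest.approx(0.1)  # 2 / C(6,3)
        assert res.method == "exact"

    def test_identical_samples_give_central_u_and_p_one(self):
        res = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.U == pytest.approx(res.n1 * res.n2 / 2)
        assert res.p_two_sided == pytest.approx(1.0)

    @pytest.mark.parametrize("n1,n2", [(1, 3), (2, 4), (3, 3), (4, 4), (3, 5)])
    def test_exact_path_equals_full_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(20):
            a = rng.standard_normal(n1)
            b = rng.standard_normal(n2)
            res = mann_whitney_u(a, b)
            assert res.method == "exact"
            assert res.p_two_sided == pytest.approx(_enumeration_p(a, b), abs=1e-12)

    def test_normal_approximation_close_to_exact_at_n20(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            a = rng.standard_normal(20)
            b = rng.standard_normal(20) + 0.3
            ours = mann_whitney_u(a, b)
            assert ours.method == "normal_approx_tie_corrected"
            exact = mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
            assert ours.p_two_sided == pytest.approx(exact, abs=0.02)

    def test_symmetry_and_u_range(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=15)
        b = rng.normal(size=18)
        r1 = mann_whitney_u(a, b)
        r2 = mann_whitney_u(b, a)
        assert r1.p_two_sided == pytest.approx(r2.p_two_sided, abs=1e-12)
        assert 0 <= r1.U <= r1.n1 * r1.n2
        assert r1.U + r2.U == pytest.approx(r1.n1 * r1.n2)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


def _reconcile_scene():
    """One cell [0, 40) um holding a 220 um component; a 30 um component
    5 um beyond its right boundary (in the neighbour cell)."""
    nz, ny, nx = 150, 6, 60  # 2 um pixels -> x spans 120 um
    ves = np.zeros((nz, ny, nx), dtype=bool)
    epi = np.zeros_like(ves)
    epi[0] = True
    ves[109:112, 1:5, 5:15] = True   # depth 220 um, inside cell [0, 40)
    ves[14:17, 1:5, 22:26] = True    # depth 30 um, starts at x = 44 um
    vol = LabeledVolume(epithelium=epi, vessel=ves, voxel_size=(2.0, 2.0, 2.0),
                        orientation="vertical_section")
    surf = extract_surface(vol, smoothing_window=0)
    field = compute_depth_field(vol, surf)
    grid = divide_roi((0.0, 0.0, 12.0, 120.0), 3)  # cells of 40 um
    return vol, field, grid


class TestReconcileGaps:
    def test_zero_tolerance_leaves_records_unchanged(self):
        vol, field, grid = _reconcile_scene()
        records = measure_area_depths(grid, field, vol)
        records = label_visibility(records, None, [1, 1, 0])
        out = reconcile_gaps(records, grid, field, vol, lateral_tolerance=0.0)
        assert [(r.nearest_depth, r.corrected) for r in out] == \
            [(r.nearest_depth, False) for r in records]

    def test_discordant_visible_cell_reassigned_to_nearby_component(self):
        vol, field, grid = _reconcile_scene()
        records = measure_area_depths(grid, field, vol)
        records = label_visibility(records, None, [1, 1, 0])
        assert records[0].nearest_depth == pytest.approx(220.0, abs=2.0)
        out = reconcile_gaps(records, grid, field, vol, lateral_tolerance=10.0,
                             depth_threshold=80.0)
        assert out[0].corrected
        assert out[0].nearest_depth == pytest.approx(30.0, abs=2.0)

    def test_concordant_records_never_modified(self):
        vol, field, grid = _reconcile_scene()
        records = measure_area_depths(grid, field, vol)
        records = label_visibility(records, None, [0, 1, 0])  # all concordant
        out = reconcile_gaps(records, grid, field, vol, lateral_tolerance=10.0,
                             depth_threshold=80.0)
        assert not any(r.corrected or r.excluded for r in out)
        assert [r.nearest_depth for r in out] == [r.nearest_depth for r in records]

    def test_unresolvable_discordance_excluded(self):
        vol, field, grid = _reconcile_scene()
        records = measure_area_depths(grid, field, vol)
        # cell 2 is censored but called visible; no shallow component nearby
        records = label_visibility(records, None, [0, 1, 1])
        out = reconcile_gaps(records, grid, field, vol, lateral_tolerance=5.0,
                             depth_threshold=80.0)
        assert out[2].excluded


class TestSummarize:
    def test_midpoint_boundary(self):
        records = [AreaRecord(i, d, visible=v) for i, (d, v) in
                   enumerate([(20, True), (40, True), (76, True), (80, False), (150, False)])]
        s = summarize(records)
        assert s.boundary_estimate == pytest.approx(78.0)
        assert s.median_visible == pytest.approx(40.0)
        assert s.range_invisible == (80.0, 150.0)

    def test_single_record_per_group(self):
        records = [AreaRecord(0, 10.0, visible=True), AreaRecord(1, 100.0, visible=False)]
        s = summarize(records)
        assert (s.median_visible, s.median_invisible) == (10.0, 100.0)
        assert s.boundary_estimate == pytest.approx(55.0)

    def test_overlapping_groups_fall_back_with_warning(self):
        records = [AreaRecord(i, d, visible=v) for i, (d, v) in enumerate(
            [(20, True), (50, True), (90, True), (60, False), (120, False), (200, False)]
        )]
        with pytest.warns(UserWarning, match="overlap"):
            s = summarize(records)
        assert 50.0 <= s.boundary_estimate <= 120.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            summarize([AreaRecord(0, 10.0, visible=True)])

    def test_records_frame_has_one_row_per_area(self):
        records = [AreaRecord(0, 10.0, visible=True), AreaRecord(1, None, visible=False)]
        frame = records_to_frame(records)
        assert len(frame) == 2
        assert math.isnan(frame.loc[1, "nearest_depth_um"])
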