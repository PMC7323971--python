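"""Shared fixtures: phantoms at the study's serial-section conditions.

The expensive fixtures (the 100-slice jittered phantom and its full
reconstruction) are session-scoped and shared between the registration,
reconstruction and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from mucosa3d import (
    PhantomSpec,
    build_phantom,
    compute_depth_field,
    extract_surface,
    register_series,
    section_volume,
    stack,
)
from mucosa3d.segmentation import fill_vessel_lumens, segment_epithelium, segment_positive


def small_spec(**overrides) -> PhantomSpec:
    """A fast vertical-section phantom used by unit tests."""
    kw = dict(
        volume_extent=(320, 45, 168),
        voxel_size=(2.0, 3.0, 2.0),
        n_slices=15,
        vessel_layout="straight",
        n_vessels=10,
        vessel_depth_range=(20.0, 200.0),
        include_crypts=True,
        rng_seed=1,
    )
    kw.update(overrides)
    return PhantomSpec(**kw)


def segment_series(series, closing_radius=2, min_object_area=4):
    """Run the segmentation stage over a series, returning the two mask maps."""
    vessel, epith = {}, {}
    for s in series.slices:
        if s.stain == "vessel_stain":
            m = segment_positive(s.image, threshold=0.5, pixel_size=s.pixel_size,
                                 stain=s.stain, slice_index=s.index)
            vessel[s.index] = fill_vessel_lumens(m, closing_radius).pixels
        else:
            epith[s.index] = segment_epithelium(
                s.image, min_object_area=min_object_area,
                pixel_size=s.pixel_size, slice_index=s.index,
            ).pixels
    return vessel, epith


def match_to_truth(field, truth, orientation="vertical_section"):
    """Pair each reconstructed component with the nearest ground-truth one
    (by centroid in the plane transverse to the tube axis) and return the
    absolute depth errors in μm."""
    errors = []
    for cid, depth in field.component_depths:
        zc, yc, xc = field.centroids_um[cid]
        if orientation == "vertical_section":
            best = min(truth.vessel_components,
                       key=lambda t: (t[1][0] - xc) ** 2 + (t[1][2] - zc) ** 2)
        else:
            best = min(truth.vessel_components,
                       key=lambda t: (t[1][0] - xc) ** 2 + (t[1][1] - yc) ** 2)
        errors.append(abs(depth - best[2]))
    return np.asarray(errors)


@pytest.fixture(scope="session")
def serial_study():
    """100 consecutive 3 μm sections of a straight-vessel phantom with
    depths spanning 10-300 μm, slide jitter up to 5 px, stain noise and a
    tenth of the vessel walls broken — the full study conditions."""
    spec = PhantomSpec(
        volume_extent=(600, 100, 170),
        voxel_size=(2.0, 3.0, 2.0),
        n_slices=100,
        vessel_layout="straight",
        n_vessels=36,
        vessel_depth_range=(10.0, 300.0),
        jitter_max_translation=5.0,
        noise_sd=0.02,
        broken_wall_fraction=0.1,
        include_crypts=True,
        rng_seed=7,
    )
    volume, truth = build_phantom(spec)
    series = section_volume(volume, spec)
    return spec, volume, truth, series


@pytest.fixture(scope="session")
def serial_chain(serial_study):
    _, _, _, series = serial_study
    return register_series(series)


@pytest.fixture(scope="session")
def serial_reconstruction(serial_study, serial_chain):
    _, _, _, series = serial_study
    vessel_masks, epith_masks = segment_series(series)
    volume = stack(series, serial_chain, vessel_masks, epith_masks)
    surface = extract_surface(volume)
    field = compute_depth_field(volume, surface, mode="axis")
    return volume, surface, field
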