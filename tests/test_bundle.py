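"""Bundle geometry, rasterization and honeycomb forward-simulation tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fibersr.bundle import (
    DEFAULT_ANGLES,
    CoreMask,
    DegenerateFieldError,
    FiberBundleLayout,
    InvalidParameterError,
    build_dataset,
    build_stack,
    generate_layout,
    precompute_masks,
    rasterize_mask,
    rotate_layout,
    simulate_frame,
)

PX = 0.316  # um per pixel used throughout


def _naive_simulate(gt, labels):
    """Double-loop oracle for core-averaged frame painting."""
    out = np.zeros_like(gt, dtype=float)
    for lab in np.unique(labels):
        if lab == 0:
            continue
        sel = labels == lab
        out[sel] = gt[sel].mean()
    return out


class TestGenerateLayout:
    def test_unjittered_lattice_has_exact_pitch_neighbours(self):
        layout = generate_layout(3.3, 0.0, (1.5, 1.75), (128, 128), PX, seed=0)
        centers = layout.core_centers
        h_um, w_um = layout.field_size_um
        interior = (
            (centers[:, 0] > 3.3)
            & (centers[:, 0] < w_um - 3.3)
            & (centers[:, 1] > 3.3)
            & (centers[:, 1] < h_um - 3.3)
        )
        d = np.linalg.norm(centers[None] - centers[:, None], axis=-1)
        np.fill_diagonal(d, np.inf)
        nn = d.min(axis=1)
        assert np.all(np.abs(nn[interior] - 3.3) < 1e-9)

    def test_core_count_matches_hexagonal_density(self):
        # hexagonal lattice density: 2 / (sqrt(3) * pitch^2) cores per unit area
        layout = generate_layout(3.3, 0.3, (1.5, 2.0), (256, 256), PX, seed=1)
        area = np.prod(layout.field_size_um)
        expected = 2.0 * area / (np.sqrt(3.0) * 3.3**2)
        assert abs(layout.n_cores - expected) < 0.10 * expected

    def test_mean_core_diameter_in_3_4_um_band(self):
        layout = generate_layout(3.3, 0.0, (1.75, 1.75), (256, 256), PX, seed=0)
        assert np.isclose(2 * layout.core_radii.mean(), 3.5)
        layout = generate_layout(3.3, 0.3, (1.5, 2.0), (256, 256), PX, seed=2)
        assert 3.0 < 2 * layout.core_radii.mean() < 4.0

    def test_centers_inside_field_and_radii_positive(self):
        layout = generate_layout(3.3, 1.0, (1.5, 2.0), (64, 64), PX, seed=3)
        h_um, w_um = layout.field_size_um
        assert np.all(layout.core_radii > 0)
        assert np.all((layout.core_centers[:, 0] >= 0) & (layout.core_centers[:, 0] <= w_um))
        assert np.all((layout.core_centers[:, 1] >= 0) & (layout.core_centers[:, 1] <= h_um))

    def test_seeded_determinism_is_bit_identical(self):
        a = generate_layout(3.3, 0.3, (1.5, 2.0), (64, 64), PX, seed=42)
        b = generate_layout(3.3, 0.3, (1.5, 2.0), (64, 64), PX, seed=42)
        assert np.array_equal(a.core_centers, b.core_centers)
        assert np.array_equal(a.core_radii, b.core_radii)

    @pytest.mark.parametrize("kwargs", [
        {"pitch": 0.0}, {"pitch": -1.0},
        {"core_radius_range": (0.0, 1.0)},
        {"pixel_size": 0.0},
    ])
    def test_invalid_parameters_raise(self, kwargs):
        args = dict(pitch=3.3, jitter_sd=0.0, core_radius_range=(1.5, 2.0),
                    field_shape=(64, 64), pixel_size=PX, seed=0)
        args.update(kwargs)
        if "pixel_size" in kwargs:
            args["pixel_size"] = kwargs["pixel_size"]
        with pytest.raises(InvalidParameterError):
            generate_layout(**args)

    def test_degenerate_field_raises(self):
        with pytest.raises(DegenerateFieldError):
            generate_layout(500.0, 0.0, (1.0, 1.0), (4, 4), PX, seed=0)


class TestRotateLayout:
    def test_zero_angle_is_identity(self, small_layout):
        rot = rotate_layout(small_layout, 0.0)
        assert np.allclose(rot.core_centers, small_layout.core_centers, atol=1e-12)

    @given(angle=st.floats(-180, 180, allow_nan=False))
    @settings(max_examples=25, deadline=None)
    def test_rotation_is_an_isometry(self, angle):
        # cores clustered near the field center so none are dropped
        rng = np.random.default_rng(7)
        centers = 10.1 + rng.uniform(-4, 4, size=(12, 2))
        layout = FiberBundleLayout(centers, np.full(12, 1.6), 0.316, (64, 64))
        rot = rotate_layout(layout, angle)
        assert rot.n_cores == layout.n_cores
        d_old = np.linalg.norm(centers[:, None] - centers[None], axis=-1)
        d_new = np.linalg.norm(
            rot.core_centers[:, None] - rot.core_centers[None], axis=-1
        )
        assert np.allclose(d_old, d_new, atol=1e-9)
        assert np.array_equal(rot.core_radii, layout.core_radii)

    def test_default_angle_set_enumerates_eleven_layouts(self, small_layout):
        layouts = [rotate_layout(small_layout, a) for a in DEFAULT_ANGLES]
        assert len(layouts) == 11
        assert DEFAULT_ANGLES == tuple(float(a) for a in range(-10, 11, 2))

    def test_center_outside_field_rejected(self, small_layout):
        with pytest.raises(InvalidParameterError):
            rotate_layout(small_layout, 5.0, center=(-10.0, 0.0))


class TestRasterizeMask:
    def test_single_core_disc_area(self):
        # one core of radius 5 px at the field center
        layout = FiberBundleLayout(
            core_centers=np.array([[16.5, 16.5]]),
            core_radii=np.array([5.0]),
            pixel_size=1.0,
            field_shape=(32, 32),
        )
        mask = rasterize_mask(layout)
        area = int((mask.label_raster == 1).sum())
        assert abs(area - np.pi * 25.0) < 4.0
        # brute-force oracle: pixel centers within radius
        yy, xx = np.mgrid[0:32, 0:32]
        oracle = ((xx + 0.5 - 16.5) ** 2 + (yy + 0.5 - 16.5) ** 2) <= 25.0
        assert np.array_equal(mask.label_raster > 0, oracle)

    def test_empty_layout_gives_all_zero_raster(self):
        layout = FiberBundleLayout(
            core_centers=np.empty((0, 2)),
            core_radii=np.empty(0),
            pixel_size=1.0,
            field_shape=(16, 16),
        )
        assert not rasterize_mask(layout).label_raster.any()

    def test_default_layout_has_partial_cladding(self, small_masks):
        frac = small_masks[0].cladding_fraction
        assert 0.0 < frac < 1.0

    def test_labels_subset_of_core_indices(self, small_layout, small_masks):
        for mask in small_masks:
            labs = mask.labels_present
            assert labs.min() >= 1 and labs.max() <= small_layout.n_cores

    def test_overlap_resolved_to_nearest_center(self):
        layout = FiberBundleLayout(
            core_centers=np.array([[10.0, 16.0], [20.0, 16.0]]),
            core_radii=np.array([8.0, 8.0]),
            pixel_size=1.0,
            field_shape=(32, 32),
        )
        labels = rasterize_mask(layout).label_raster
        # pixel column 12 is closer to core 1, column 18 closer to core 2
        assert labels[16, 12] == 1 and labels[16, 18] == 2


class TestSimulateFrame:
    def test_constant_ground_truth_paints_constant(self, small_masks):
        gt = np.full((64, 64), 0.7)
        frame = simulate_frame(gt, small_masks[0])
        labels = small_masks[0].label_raster
        assert np.allclose(frame[labels > 0], 0.7, atol=1e-6)
        assert np.all(frame[labels == 0] == 0.0)

    def test_matches_double_loop_oracle_exactly(self, rng):
        labels = rng.integers(0, 4, size=(24, 24)).astype(np.int32)
        gt = rng.uniform(0, 1, (24, 24))
        frame = simulate_frame(gt, CoreMask(labels))
        assert np.allclose(frame, _naive_simulate(gt, labels), atol=1e-7)

    def test_painted_value_is_footprint_mean_on_ramp(self):
        layout = FiberBundleLayout(
            core_centers=np.array([[16.5, 16.5]]),
            core_radii=np.array([5.0]),
            pixel_size=1.0,
            field_shape=(32, 32),
        )
        mask = rasterize_mask(layout)
        ramp = np.tile(np.linspace(0, 1, 32), (32, 1))
        frame = simulate_frame(ramp, mask)
        sel = mask.label_raster == 1
        assert np.allclose(frame[sel], ramp[sel].mean(), atol=1e-6)

    @given(seed=st.integers(0, 2**16))
    @settings(max_examples=20, deadline=None)
    def test_painted_values_bounded_by_footprint_range(self, small_masks, seed):
        gt = np.random.default_rng(seed).uniform(0, 1, (64, 64))
        mask = small_masks[3]
        frame = simulate_frame(gt, mask)
        labels = mask.label_raster
        for lab in np.unique(labels)[1:][:10]:
            sel = labels == lab
            vals = frame[sel]
            assert np.all(vals == vals[0])  # constant within the footprint
            assert gt[sel].min() - 1e-6 <= vals[0] <= gt[sel].max() + 1e-6

    def test_shape_mismatch_raises(self, small_masks):
        with pytest.raises(InvalidParameterError):
            simulate_frame(np.zeros((32, 32)), small_masks[0])


class TestBuildStack:
    def test_default_angles_give_eleven_frames(self, fixtures):
        assert fixtures["stack"].n_frames == 11

    def test_single_angle_equals_simulate_frame(self, small_layout, small_masks, rng):
        gt = rng.uniform(0, 1, (64, 64))
        stack = build_stack(gt, small_layout, angles=[0.0], masks=[small_masks[5]])
        assert np.array_equal(stack.frames[0], simulate_frame(gt, small_masks[5]))

    def test_rotation_reveals_cladding_hidden_pixels(self, small_layout, small_masks):
        gt = np.full((64, 64), 1.0)
        stack = build_stack(gt, small_layout, masks=small_masks)
        union = (stack.frames > 0).any(axis=0)
        for i in range(stack.n_frames):
            single = stack.frames[i] > 0
            assert np.all(single <= union)
            assert union.sum() > single.sum()

    def test_monotone_coverage_as_angles_accumulate(self, small_layout, small_masks):
        gt = np.full((64, 64), 1.0)
        stack = build_stack(gt, small_layout, masks=small_masks)
        covered = np.zeros((64, 64), dtype=bool)
        last = 0
        for i in range(stack.n_frames):
            covered |= stack.frames[i] > 0
            assert covered.sum() >= last
            last = covered.sum()

    def test_duplicate_or_unsorted_angles_raise(self, small_layout):
        gt = np.zeros((64, 64))
        with pytest.raises(InvalidParameterError):
            build_stack(gt, small_layout, angles=[0.0, 0.0])
        with pytest.raises(InvalidParameterError):
            build_stack(gt, small_layout, angles=[2.0, -2.0])


class TestBuildDataset:
    def test_split_counts_floor_with_remainder_to_training(self, small_layout, small_masks):
        tiles = [np.zeros((64, 64)) for _ in range(100)]
        splits = build_dataset(tiles, small_layout, masks=small_masks, seed=0)
        assert (len(splits["train"]), len(splits["val"]), len(splits["test"])) == (64, 16, 20)

    def test_degenerate_split_puts_all_in_training(self, small_layout, small_masks):
        tiles = [np.zeros((64, 64)) for _ in range(7)]
        splits = build_dataset(
            tiles, small_layout, split_fractions=(1.0, 0.0, 0.0),
            masks=small_masks, seed=0,
        )
        assert len(splits["train"]) == 7 and len(splits["test"]) == 0

    def test_seeded_membership_is_reproducible(self, small_layout, small_masks):
        tiles = [np.full((64, 64), i / 100.0) for i in range(30)]
        a = build_dataset(tiles, small_layout, masks=small_masks, seed=9)
        b = build_dataset(tiles, small_layout, masks=small_masks, seed=9)
        for name in ("train", "val", "test"):
            assert np.array_equal(a[name].tile_indices, b[name].tile_indices)
            assert np.array_equal(a[name].stacks, b[name].stacks)

    def test_empty_tile_list_raises(self, small_layout):
        with pytest.raises(InvalidParameterError):
            build_dataset([], small_layout)
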