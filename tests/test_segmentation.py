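"""Contour morphing, rasterization and compartment-mask construction."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ivdmorph.image_io import Contour, ContourSet, ImageStack
from ivdmorph.preprocess import median_filter
from ivdmorph.segmentation import (
    CompartmentMasks,
    LowSeparabilityWarning,
    SegmentationError,
    build_masks,
    dice,
    interpolate_contours,
    rasterize_polygon,
    resample_polygon,
    suggest_nc_threshold,
)
from ivdmorph.phantom import truth_contours

from conftest import brute_force_rasterize, regular_polygon


def contour_pair(label, poly0, poly30):
    return ContourSet((Contour(label, 0, poly0), Contour(label, 30, poly30)))


class TestInterpolateContours:
    def test_equal_endpoint_circles_interpolate_to_themselves(self):
        circ = regular_polygon(20.0, (30, 30))
        cs = contour_pair("disc_outer", circ, circ)
        mid = interpolate_contours(cs, "disc_outer", [15])[15]
        ref = resample_polygon(circ)
        assert np.allclose(mid, ref)

    def test_concentric_circles_blend_radius_linearly(self):
        cs = contour_pair(
            "disc_outer", regular_polygon(10.0, (0, 0)), regular_polygon(20.0, (0, 0))
        )
        mid = interpolate_contours(cs, "disc_outer", [15])[15]
        radii = np.linalg.norm(mid, axis=1)
        assert np.all(np.abs(radii - 15.0) < 0.15)  # 1% resampling tolerance

    def test_translated_squares_blend_centroid_linearly(self):
        sq = np.array([[-0.5, -0.5], [0.5, -0.5], [0.5, 0.5], [-0.5, 0.5]])
        cs = contour_pair("disc_outer", sq + [5, 5], sq + [35, 5])
        mid = interpolate_contours(cs, "disc_outer", [15])[15]
        assert np.allclose(mid.mean(axis=0), [20.0, 5.0], atol=0.15)

    def test_annotated_slices_return_their_own_polygon(self):
        a, b = regular_polygon(10.0, (20, 20)), regular_polygon(20.0, (20, 20))
        cs = contour_pair("disc_outer", a, b)
        dense = interpolate_contours(cs, "disc_outer", [0, 30])
        assert np.allclose(dense[0], resample_polygon(a))
        assert np.allclose(dense[30], resample_polygon(b))

    def test_continuity_in_slice_index(self):
        cs = contour_pair(
            "disc_outer", regular_polygon(10.0, (0, 0)), regular_polygon(25.0, (3, 0))
        )
        dense = interpolate_contours(cs, "disc_outer", range(31))
        steps = [
            np.abs(dense[s + 1] - dense[s]).max() for s in range(30)
        ]
        assert max(steps) < 1.0  # no jumps anywhere, including annotated ends

    def test_single_contour_and_out_of_span_requests_rejected(self):
        single = ContourSet((Contour("disc_outer", 0, regular_polygon(10, (20, 20))),))
        with pytest.raises(SegmentationError, match=">=2"):
            interpolate_contours(single, "disc_outer", [0])
        cs = contour_pair(
            "disc_outer", regular_polygon(10, (20, 20)), regular_polygon(12, (20, 20))
        )
        with pytest.raises(SegmentationError, match="span"):
            interpolate_contours(cs, "disc_outer", [31])


class TestRasterizePolygon:
    def test_axis_aligned_square_sets_exactly_100_voxels(self):
        sq = np.array([[0, 0], [10, 0], [10, 10], [0, 10]], float)
        mask = rasterize_polygon(sq, (20, 20), (1.0, 1.0))
        assert mask.sum() == 100
        assert mask[:10, :10].all()

    def test_edge_through_voxel_centres_counts_as_inside(self):
        sq = np.array([[0.5, 0.5], [9.5, 0.5], [9.5, 9.5], [0.5, 9.5]])
        mask = rasterize_polygon(sq, (20, 20), (1.0, 1.0))
        assert mask.sum() == 100  # boundary centres included on all four edges

    def test_two_vertex_polygon_rejected(self):
        with pytest.raises(SegmentationError):
            rasterize_polygon(np.array([[0.0, 0.0], [5.0, 5.0]]), (10, 10), (1, 1))

    def test_circle_area_within_2pct(self):
        circ = regular_polygon(20.0, (25, 25), n=256)
        mask = rasterize_polygon(circ, (50, 50), (1.0, 1.0))
        assert mask.sum() == pytest.approx(np.pi * 400, rel=0.02)

    def test_polygon_exiting_grid_rejected_with_vertices(self):
        with pytest.raises(SegmentationError, match="exits the grid"):
            rasterize_polygon(regular_polygon(30.0, (25, 25)), (40, 40), (1.0, 1.0))

    def test_matches_brute_force_point_in_polygon(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            pts = rng.uniform(2, 18, (12, 2))
            hull = _convex_hull(pts)
            mask = rasterize_polygon(hull, (20, 20), (1.0, 1.0))
            oracle = brute_force_rasterize(hull, (20, 20), (1.0, 1.0))
            assert np.array_equal(mask, oracle)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_brute_force_equivalence_property(self, seed):
        rng = np.random.default_rng(seed)
        spacing = float(rng.choice([0.5, 1.0, 2.0]))
        extent = 16 * spacing
        pts = rng.uniform(0.05, 0.9, (rng.integers(4, 10), 2)) * extent
        hull = _convex_hull(pts)
        mask = rasterize_polygon(hull, (16, 16), (spacing, spacing))
        oracle = brute_force_rasterize(hull, (16, 16), (spacing, spacing))
        assert np.array_equal(mask, oracle)


def _convex_hull(pts: np.ndarray) -> np.ndarray:
    from scipy.spatial import ConvexHull

    return pts[ConvexHull(pts).vertices]


class TestBuildMasks:
    def test_noise_free_phantom_recovers_truth_exactly(self, clean_phantom):
        spec, stack, truth = clean_phantom
        masks = build_masks(stack, truth_contours(spec), nc_threshold=130.0)
        assert np.array_equal(masks.whole_disc, truth.masks.whole_disc)
        assert np.array_equal(masks.np_, truth.masks.np_)
        assert np.array_equal(masks.nc, truth.masks.nc)
        assert np.array_equal(masks.af, truth.masks.af)

    def test_threshold_above_maximum_warns_and_yields_empty_nc(self, clean_phantom):
        spec, stack, _ = clean_phantom
        with pytest.warns(UserWarning, match="empty"):
            masks = build_masks(stack, truth_contours(spec), nc_threshold=1e9)
        assert not masks.nc.any()

    def test_noisy_phantom_nc_dice_above_090(self, noisy_phantom):
        spec, stack, truth = noisy_phantom
        filtered = median_filter(stack, radius=5)
        masks = build_masks(filtered, truth_contours(spec), nc_threshold=130.0)
        assert dice(masks.nc, truth.masks.nc) >= 0.90

    def test_raising_threshold_never_enlarges_nc(self, noisy_phantom):
        spec, stack, truth = noisy_phantom
        cs = truth_contours(spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            masks = [build_masks(stack, cs, thr) for thr in (110.0, 130.0, 150.0, 1e9)]
        for lo, hi in zip(masks, masks[1:]):
            assert not np.any(hi.nc & ~lo.nc)

    def test_mask_invariants_enforced_on_construction(self):
        disc = np.zeros((4, 8, 8), bool)
        disc[1:3, 2:6, 2:6] = True
        np_m = np.zeros_like(disc)
        np_m[1:3, 3:5, 3:5] = True
        with pytest.raises(SegmentationError, match="AF"):
            CompartmentMasks(disc, disc.copy(), np_m, np.zeros_like(disc), (1, 1, 1))
        outside = np.zeros_like(disc)
        outside[0, 0, 0] = True
        with pytest.raises(SegmentationError, match="NP"):
            CompartmentMasks(disc, disc & ~outside, outside, np.zeros_like(disc), (1, 1, 1))

    def test_label_volume_round_trip(self, clean_phantom):
        _, _, truth = clean_phantom
        labels = truth.masks.label_volume()
        back = CompartmentMasks.from_label_volume(labels, truth.masks.spacing_um)
        assert np.array_equal(back.nc, truth.masks.nc)
        assert np.array_equal(back.whole_disc, truth.masks.whole_disc)


class TestSuggestNcThreshold:
    def test_bimodal_interior_threshold_lies_between_modes(self):
        vol = np.full((4, 10, 10), 40.0)
        vol[:, 5:, :] = 200.0
        stack = ImageStack(vol, (1, 1, 1))
        np_mask = np.ones_like(vol, bool)
        suggestion = suggest_nc_threshold(stack, np_mask)
        assert 40.0 < suggestion.value < 200.0
        assert not suggestion.low_separability

    def test_constant_interior_flags_low_separability(self):
        stack = ImageStack(np.full((4, 10, 10), 60.0), (1, 1, 1))
        with pytest.warns(LowSeparabilityWarning):
            suggestion = suggest_nc_threshold(stack, np.ones((4, 10, 10), bool))
        assert suggestion.low_separability

    def test_suggested_threshold_recovers_nc_on_noisy_phantom(self, noisy_phantom):
        spec, stack, truth = noisy_phantom
        filtered = median_filter(stack, radius=5)
        masks = build_masks(filtered, truth_contours(spec), nc_threshold=130.0)
        suggestion = suggest_nc_threshold(filtered, masks.np_)
        nc = masks.np_ & (filtered.voxels >= suggestion.value)
        assert dice(nc, truth.masks.nc) >= 0.85
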