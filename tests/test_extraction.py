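"""Centerline extraction: skeleton, segments, concatenation, pair selection."""

import numpy as np
import pytest

from canalkit.curve_metrics import symmetric_mean_curve_distance as smcd
from canalkit.extraction import (
    ExtractionConfig,
    Route,
    RouteSegment,
    concatenate_segments,
    extract_canals,
    extract_route_segments,
    filter_anatomical,
    mean_absolute_curvature,
    select_symmetric_pair,
    skeletonize_volume,
)
from canalkit.synthetic import PhantomSpec, SystemModel, generate_ground_truth, simulate_system_volume
from canalkit.types import LabelVolume


def vol_from_grid(grid, spacing=1.0):
    return LabelVolume(np.asarray(grid, bool), np.full(3, spacing))


def seg_from_indices(indices, spacing=1.0):
    vox = np.asarray(indices, int)
    return RouteSegment(vox, vox.astype(float) * spacing)


class TestSkeletonize:
    def test_straight_tube_skeleton_near_axis(self):
        grid = np.zeros((40, 9, 9), bool)
        jj, kk = np.meshgrid(np.arange(9), np.arange(9), indexing="ij")
        disc = (jj - 4) ** 2 + (kk - 4) ** 2 <= 9
        grid[:, disc] = True
        skel = skeletonize_volume(vol_from_grid(grid))
        assert skel.shape[0] > 0
        mid = skel[(skel[:, 0] > 5) & (skel[:, 0] < 34)]
        off_axis = np.linalg.norm(mid[:, 1:] - 4, axis=1)
        assert off_axis.max() <= np.sqrt(2) + 1e-9  # within one voxel of the axis

    def test_single_voxel(self):
        grid = np.zeros((5, 5, 5), bool)
        grid[2, 2, 2] = True
        skel = skeletonize_volume(vol_from_grid(grid))
        assert np.array_equal(skel, [[2, 2, 2]])

    def test_empty_volume(self):
        skel = skeletonize_volume(vol_from_grid(np.zeros((5, 5, 5), bool)))
        assert skel.shape == (0, 3)

    def test_skeleton_subset_of_foreground(self, clean_phantom):
        _, _, _, vol = clean_phantom
        skel = skeletonize_volume(vol)
        assert vol.grid[skel[:, 0], skel[:, 1], skel[:, 2]].all()


class TestRouteSegments:
    def test_single_simple_path(self):
        idx = [(i, 0, 0) for i in range(10)]
        grid = np.zeros((12, 3, 3), bool)
        for v in idx:
            grid[v] = True
        segs = extract_route_segments(np.array(idx), vol_from_grid(grid), 2.0, prune_len_mm=0)
        assert len(segs) == 1
        assert segs[0].voxels.shape[0] == 10

    def test_y_shape_splits_into_three(self):
        trunk = [(i, 5, 0) for i in range(6)]
        arm1 = [(6 + i, 6 + i, 0) for i in range(5)]
        arm2 = [(6 + i, 4 - i, 0) for i in range(5)]
        idx = np.array(trunk + arm1 + arm2)
        grid = np.zeros((15, 15, 3), bool)
        for v in idx:
            grid[tuple(v)] = True
        segs = extract_route_segments(idx, vol_from_grid(grid), 2.0, prune_len_mm=0)
        assert len(segs) == 3

    def test_disconnected_paths(self):
        a = [(i, 0, 0) for i in range(6)]
        b = [(i, 8, 0) for i in range(6)]
        idx = np.array(a + b)
        grid = np.zeros((10, 10, 3), bool)
        for v in idx:
            grid[tuple(v)] = True
        segs = extract_route_segments(idx, vol_from_grid(grid), 2.0, prune_len_mm=0)
        assert len(segs) == 2

    def test_short_spur_pruned(self):
        main = [(i, 5, 0) for i in range(12)]
        spur = [(6, 6, 0), (6, 7, 0)]
        idx = np.array(main + spur)
        grid = np.zeros((15, 10, 3), bool)
        for v in idx:
            grid[tuple(v)] = True
        segs = extract_route_segments(idx, vol_from_grid(grid), 2.0, prune_len_mm=3.0)
        assert len(segs) == 1
        assert segs[0].voxels.shape[0] == 12


class TestConcatenate:
    def test_collinear_gap_bridged(self):
        a = seg_from_indices([(i, 0, 0) for i in range(5)])
        b = seg_from_indices([(i + 6, 0, 0) for i in range(5)])
        routes = concatenate_segments([a, b], gap_tol_mm=4.0)
        assert len(routes) == 1
        assert routes[0].arc_length == pytest.approx(10.0)

    def test_distant_segments_stay_separate(self):
        a = seg_from_indices([(i, 0, 0) for i in range(5)])
        b = seg_from_indices([(i + 15, 0, 0) for i in range(5)])
        assert len(concatenate_segments([a, b], gap_tol_mm=4.0)) == 2

    def test_single_segment_passthrough(self):
        a = seg_from_indices([(i, 0, 0) for i in range(5)])
        routes = concatenate_segments([a], gap_tol_mm=4.0)
        assert len(routes) == 1
        assert np.array_equal(routes[0].points, a.points)

    def test_perpendicular_segments_not_joined(self):
        a = seg_from_indices([(i, 0, 0) for i in range(8)])
        b = seg_from_indices([(9, i + 2, 0) for i in range(8)])
        assert len(concatenate_segments([a, b], gap_tol_mm=4.0, angle_gate_deg=60.0)) == 2

    def test_midline_guard_blocks_cross_bridge(self):
        a = seg_from_indices([(i, 0, 0) for i in range(5)])
        b = seg_from_indices([(i + 6, 0, 0) for i in range(5)])
        routes = concatenate_segments([a, b], gap_tol_mm=4.0, forbid_plane_x=5.0)
        assert len(routes) == 2


class TestFilterAnatomical:
    def _route(self, length, n=100):
        x = np.linspace(0, length, n)
        return Route(np.stack([x, np.zeros(n), np.zeros(n)], axis=1))

    def test_keeps_canal_length_smooth_route(self):
        assert len(filter_anatomical([self._route(60.0)])) == 1

    def test_drops_short_blob_route(self):
        assert len(filter_anatomical([self._route(5.0)])) == 0

    def test_min_length_boundary_inclusive(self):
        assert len(filter_anatomical([self._route(30.0)], min_route_len_mm=30.0)) == 1

    def test_drops_high_curvature(self):
        # tight coil: radius-of-curvature ~1.1 mm, curvature ~0.9 per mm
        t = np.linspace(0, 16 * np.pi, 800)
        coil = np.stack([1.1 * np.cos(t), 1.1 * np.sin(t), 0.7 * t / (2 * np.pi)], axis=1)
        r = Route(coil)
        assert 30 <= r.arc_length <= 120
        assert mean_absolute_curvature(r.points) > 0.5
        assert len(filter_anatomical([r])) == 0


class TestSymmetricPair:
    def _mirror_setup(self):
        t = np.linspace(0, 1, 80)
        left = np.stack([10 + 5 * t, 40 * t, 10 - 3 * t], axis=1)
        right = left * np.array([-1, 1, 1])
        grid = np.zeros((100, 120, 40), bool)
        vol = LabelVolume(grid, np.full(3, 0.5), np.array([-25.0, -2.0, 0.0]))
        for pts in (left, right):
            idx = np.round(vol.world_to_voxel(pts)).astype(int)
            vol.grid[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        return left, right, vol

    def test_perfect_mirror_pair_scores_zero(self):
        left, right, vol = self._mirror_setup()
        pair = select_symmetric_pair([Route(left), Route(right)], vol)
        assert pair.status == "ok"
        assert pair.symmetry_score == pytest.approx(0.0, abs=1e-6)

    def test_mirror_pair_beats_distractor(self):
        left, right, vol = self._mirror_setup()
        distractor = Route(right + np.array([0.0, 6.0, 4.0]))
        pair = select_symmetric_pair([Route(left), distractor, Route(right)], vol)
        assert pair.status == "ok"
        assert np.allclose(np.abs(pair.right.points[:, 0]), np.abs(left[:, 0]), atol=1e-6)

    def test_single_route_partial(self):
        left, _, vol = self._mirror_setup()
        pair = select_symmetric_pair([Route(left)], vol)
        assert pair.status == "partial"
        assert (pair.left is None) != (pair.right is None)

    def test_no_routes_failed(self, clean_phantom):
        _, _, _, vol = clean_phantom
        pair = select_symmetric_pair([], vol)
        assert pair.status == "failed"


class TestExtractCanals:
    def test_clean_phantom_recovered_within_one_voxel(self, clean_phantom):
        spec, left, right, vol = clean_phantom
        pair = extract_canals(vol)
        assert pair.status == "ok"
        assert smcd(pair.left, left.points) <= 0.4
        assert smcd(pair.right, right.points) <= 0.4

    def test_curves_ordered_posterior_first(self, clean_phantom):
        _, _, _, vol = clean_phantom
        pair = extract_canals(vol)
        for c in (pair.left, pair.right):
            assert c.points[0, 2] > c.points[-1, 2]

    def test_gap_is_bridged(self):
        spec = PhantomSpec()
        left, right = generate_ground_truth(spec, 3)
        model = SystemModel(boundary_flip_prob=0.0, gap_rate=1.0, gap_length_mm=3.0,
                            spurious_rate=0.0)
        vol = simulate_system_volume((left, right), model, spec.grid_spec(), 3)
        pair = extract_canals(vol)
        assert pair.status == "ok"
        assert smcd(pair.left, left.points) <= 0.4
        assert smcd(pair.right, right.points) <= 0.4

    def test_empty_volume_failed(self):
        vol = LabelVolume(np.zeros((10, 10, 10), bool), np.full(3, 0.4))
        assert extract_canals(vol).status == "failed"

    def test_deterministic(self, clean_phantom):
        _, _, _, vol = clean_phantom
        p1 = extract_canals(vol)
        p2 = extract_canals(vol)
        assert np.array_equal(p1.left.points, p2.left.points)
        assert np.array_equal(p1.right.points, p2.right.points)
        assert p1.symmetry_score == p2.symmetry_score

    def test_extracted_points_stay_inside_foreground(self, clean_phantom):
        # no gaps in this phantom, so every point must lie within one voxel
        # (dilated) of the segmented tube
        from scipy.spatial import cKDTree

        _, _, _, vol = clean_phantom
        pair = extract_canals(vol)
        fg = vol.voxel_to_world(np.argwhere(vol.grid))
        tree = cKDTree(fg)
        for c in (pair.left, pair.right):
            d, _ = tree.query(c.points)
            assert d.max() <= np.linalg.norm(vol.spacing) + 1e-9
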