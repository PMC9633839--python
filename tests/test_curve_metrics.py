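"""Curve distance metrics: hand-checked values, identities, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from canalkit.curve_metrics import (
    dice_coefficient,
    harmonize_endpoints,
    interpolating_spline,
    mean_curve_distance,
    point_to_curve_distance,
    positional_profile,
    resample_uniform,
    spline_densify,
    symmetric_mean_curve_distance,
    within_margin_proportion,
)
from canalkit.types import Curve3D, LabelVolume

from conftest import make_random_curve


def brute_mcd(T, E):
    """Independent exhaustive oracle for the directed mean curve distance."""
    T, E = np.atleast_2d(T), np.atleast_2d(E)
    return np.mean([min(np.linalg.norm(t - e) for e in E) for t in T])


class TestPointToCurve:
    @pytest.mark.parametrize(
        "x, S, expected",
        [
            ((0, 0, 0), [(0, 0, 0), (5, 0, 0)], 0.0),
            ((0, 1, 0), [(0, 0, 0), (4, 0, 0), (8, 0, 0)], 1.0),
            ((3, 4, 0), [(0, 0, 0), (6, 0, 0)], 5.0),
        ],
    )
    def test_hand_examples(self, x, S, expected):
        assert point_to_curve_distance(np.array(x, float), S) == pytest.approx(expected)

    def test_empty_curve_rejected(self):
        with pytest.raises(ValueError):
            point_to_curve_distance(np.zeros(3), np.empty((0, 3)))


class TestMeanCurveDistance:
    def test_identity_is_zero(self, rng):
        pts = make_random_curve(rng)
        assert mean_curve_distance(pts, pts) == 0.0
        assert symmetric_mean_curve_distance(pts, pts) == 0.0

    def test_parallel_offset(self):
        T = [(0, 0, 0), (1, 0, 0)]
        E = [(0, 2, 0), (1, 2, 0)]
        assert mean_curve_distance(T, E) == pytest.approx(2.0)

    def test_hand_example_asymmetric(self):
        T = [(0, 0, 0), (4, 0, 0), (8, 0, 0)]
        E = [(0, 1, 0)]
        expected = (1 + np.sqrt(17) + np.sqrt(65)) / 3
        assert mean_curve_distance(T, E) == pytest.approx(expected, abs=1e-12)

    def test_smcd_hand_example(self):
        T = [(0, 0, 0)]
        E = [(0, 3, 0), (0, 4, 0)]
        assert symmetric_mean_curve_distance(T, E) == pytest.approx(3.25, abs=1e-12)

    def test_smcd_symmetric_bit_exact(self, rng):
        for _ in range(20):
            T, E = make_random_curve(rng), make_random_curve(rng)
            assert symmetric_mean_curve_distance(T, E) == symmetric_mean_curve_distance(E, T)

    def test_smcd_bounded_by_directed(self, rng):
        for _ in range(20):
            T, E = make_random_curve(rng), make_random_curve(rng)
            a, b = mean_curve_distance(T, E), mean_curve_distance(E, T)
            s = symmetric_mean_curve_distance(T, E)
            assert min(a, b) - 1e-12 <= s <= max(a, b) + 1e-12

    def test_matches_brute_force(self, rng):
        for _ in range(25):
            T = make_random_curve(rng, n=int(rng.integers(2, 15)))
            E = make_random_curve(rng, n=int(rng.integers(2, 15)))
            assert mean_curve_distance(T, E) == pytest.approx(brute_mcd(T, E), abs=1e-9)

    def test_rigid_motion_invariance(self, rng):
        from scipy.spatial.transform import Rotation

        T, E = make_random_curve(rng), make_random_curve(rng)
        base = symmetric_mean_curve_distance(T, E)
        for _ in range(5):
            q = rng.normal(size=4)
            R = Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()
            t = rng.normal(0, 50, 3)
            assert symmetric_mean_curve_distance(T @ R.T + t, E @ R.T + t) == pytest.approx(
                base, abs=1e-9
            )


class TestWithinMargin:
    def test_identity_is_one(self, rng):
        pts = make_random_curve(rng)
        assert within_margin_proportion(pts, pts, radius=0.5) == 1.0

    def test_counted_fraction(self):
        E = [(0, 0, 0), (10, 0, 0)]
        T = [(0, 1, 0), (10, 1, 0), (0, 3, 0)]  # distances 1, 1, 3
        assert within_margin_proportion(T, E, radius=2.0) == pytest.approx(2 / 3)

    def test_far_curve_is_zero(self):
        T = np.array([(0, 5, 0), (1, 6, 0)], float)
        E = np.array([(0, 0, 0), (1, 0, 0)], float)
        assert within_margin_proportion(T, E, radius=2.0) == 0.0

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            within_margin_proportion([(0, 0, 0), (1, 0, 0)], [(0, 0, 0), (1, 0, 0)], radius=0.0)

    def test_monotone_in_offset(self, rng):
        T = make_random_curve(rng, n=30)
        prev = 1.0
        for off in (0.5, 1.5, 2.5, 4.0):
            frac = within_margin_proportion(T, T + np.array([0, 0, off]), radius=2.0)
            assert frac <= prev + 1e-12
            prev = frac


class TestSplineDensify:
    def test_collinear_stays_on_axis(self):
        curve = spline_densify(np.array([(0, 0, 0), (3, 0, 0), (6, 0, 0)], float), step=0.5)
        assert np.allclose(curve.points[:, 1:], 0.0, atol=1e-9)
        assert curve.points[:, 0].min() >= -1e-9
        assert curve.points[:, 0].max() <= 6 + 1e-9

    def test_two_points_gives_straight_segment(self):
        curve = spline_densify(np.array([(0, 0, 0), (0, 0, 5)], float), step=1.0)
        assert np.allclose(curve.points[:, :2], 0.0, atol=1e-9)
        assert curve.points[0, 2] == pytest.approx(0.0)
        assert curve.points[-1, 2] == pytest.approx(5.0)

    def test_spline_interpolates_control_points(self, rng):
        ctrl = make_random_curve(rng, n=8, scale=30.0)
        spline, u = interpolating_spline(ctrl)
        assert np.abs(spline(u) - ctrl).max() < 1e-6

    def test_sampling_step_roughly_uniform(self, rng):
        ctrl = make_random_curve(rng, n=6, scale=30.0)
        curve = spline_densify(ctrl, step=0.5)
        seg = np.linalg.norm(np.diff(curve.points, axis=0), axis=1)
        assert np.all(seg < 0.75)

    def test_single_control_point_rejected(self):
        with pytest.raises(ValueError):
            spline_densify(np.array([[0.0, 0.0, 0.0]]))


class TestHarmonizeEndpoints:
    def test_identical_curves_unchanged(self):
        c = Curve3D(np.array([(0, 0, 5), (0, 5, 3), (0, 10, 4)], float))
        out = harmonize_endpoints([c, c, c])
        for o in out:
            assert np.array_equal(o.points, c.points)

    def test_longer_posterior_is_truncated(self):
        base = np.array([(0.0, i, 10.0 - 0.1 * i) for i in range(10)])
        a = Curve3D(base)
        extra = np.array([(0.0, -3.0, 12.0), (0.0, -2.0, 11.4), (0.0, -1.0, 10.7)])
        b = Curve3D(np.vstack([extra, base]))
        fixed_a, fixed_b = harmonize_endpoints([a, b])
        assert np.array_equal(fixed_a.points, a.points)
        assert fixed_b.points.shape == a.points.shape
        assert np.allclose(fixed_b.points[0], a.points[0])

    def test_single_curve_identity_by_default(self):
        c = Curve3D(np.array([(0, 0, 0), (0, 1, 0)], float))
        assert harmonize_endpoints([c])[0] is c
        with pytest.raises(ValueError):
            harmonize_endpoints([c], single_is_error=True)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            harmonize_endpoints([])


class TestPositionalProfile:
    def test_identity_profile_is_zero(self, rng):
        # distances are measured to the reference point set, so sample at the
        # reference's own (uniformly spaced) vertices for an exact zero
        T = np.array([(float(i), 0, 0) for i in range(50)])
        prof = positional_profile(T, T, n=50)
        assert prof.n_samples == 50
        assert np.all(prof.distance < 1e-9)

    def test_identity_profile_small_at_discretisation_scale(self, rng):
        pts = resample_uniform(make_random_curve(rng, n=20), step=0.5)
        prof = positional_profile(pts, pts, n=200)
        assert prof.distance.max() <= 0.25 + 1e-9  # half the 0.5 mm step

    def test_uniform_offset_profile(self):
        T = np.array([(float(i), 0, 0) for i in range(200)])
        prof = positional_profile(T, T + np.array([0, 1.0, 0]), n=200)
        assert np.allclose(prof.distance, 1.0, atol=1e-9)

    def test_profile_mean_equals_mcd_of_resampled(self, rng):
        est, ref = make_random_curve(rng, n=15), make_random_curve(rng, n=15)
        prof = positional_profile(est, ref, n=200)
        resampled = resample_uniform(est, n=200)
        assert prof.distance.mean() == pytest.approx(mean_curve_distance(resampled, ref), abs=1e-9)

    def test_too_few_samples_rejected(self, rng):
        pts = make_random_curve(rng)
        with pytest.raises(ValueError):
            positional_profile(pts, pts, n=1)


class TestDice:
    def _vol(self, grid):
        return LabelVolume(np.asarray(grid, bool), np.full(3, 0.4))

    def test_identical_masks(self, rng):
        g = rng.random((5, 5, 5)) > 0.5
        assert dice_coefficient(self._vol(g), self._vol(g)) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0, 0, 0] = b[3, 3, 3] = True
        assert dice_coefficient(self._vol(a), self._vol(b)) == 0.0

    def test_half_overlap(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0, 0, 0] = a[0, 0, 1] = True
        b[0, 0, 1] = b[0, 0, 2] = True
        assert dice_coefficient(self._vol(a), self._vol(b)) == pytest.approx(0.5)

    def test_both_empty_defined_as_one(self):
        z = np.zeros((3, 3, 3), bool)
        assert dice_coefficient(self._vol(z), self._vol(z)) == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice_coefficient(self._vol(np.zeros((3, 3, 3), bool)),
                             self._vol(np.zeros((4, 3, 3), bool)))


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_smcd_symmetry_property(seed):
    """SMCD is invariant under argument swap for arbitrary curve pairs."""
    r = np.random.default_rng(seed)
    T, E = make_random_curve(r), make_random_curve(r)
    assert symmetric_mean_curve_distance(T, E) == symmetric_mean_curve_distance(E, T)
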