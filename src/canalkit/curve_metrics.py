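"""Curve-to-curve distance and agreement statistics.

The mean curve distance (MCD) averages, over the points of a *ground truth*
curve T, the minimum Euclidean distance to an *estimator* curve E; it is
asymmetric in its arguments.  The symmetric mean curve distance (SMCD) is the
mean of the two directed MCDs and is the summary used for interobserver
variability, where neither curve is privileged.  Distances are computed over
the discrete point sets (no segment interpolation); curves are densified to a
0.5 mm step beforehand so the discretisation error is well below the 0.4 mm
voxel size of the volumes they come from.
"""

from __future__ import annotations

from typing import Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree

from .types import (
    SUPERIOR_AXIS,
    ControlPointAnnotation,
    Curve3D,
    DistanceProfile,
    LabelVolume,
    as_points,
)

CurveLike = Union[Curve3D, np.ndarray, Sequence]

#: default densification step in mm
DENSIFY_STEP_MM = 0.5
#: clinical implant safety margin in mm
MARGIN_MM = 2.0


def _pts(curve: CurveLike) -> np.ndarray:
    if isinstance(curve, Curve3D):
        return curve.points
    return as_points(curve)


def point_to_curve_distance(x, S: CurveLike) -> float:
    """Minimum Euclidean distance (mm) from point ``x`` to the point set ``S``."""
    pts = _pts(S)
    x = np.asarray(x, dtype=float)
    if x.shape != (3,):
        raise ValueError("x must be a single 3D point")
    return float(np.min(np.linalg.norm(pts - x, axis=1)))


def _directed_distances(T: np.ndarray, E: np.ndarray) -> np.ndarray:
    """d(t, E) for every t in T, via a KD-tree on E."""
    d, _ = cKDTree(E).query(T, k=1)
    return np.atleast_1d(d)


def mean_curve_distance(T: CurveLike, E: CurveLike) -> float:
    """MCD(T, E): mean over t in T of the distance to the nearest point of E."""
    return float(np.mean(_directed_distances(_pts(T), _pts(E))))


def symmetric_mean_curve_distance(T: CurveLike, E: CurveLike) -> float:
    """SMCD(T, E) = (MCD(T, E) + MCD(E, T)) / 2; symmetric in its arguments."""
    t, e = _pts(T), _pts(E)
    return 0.5 * (
        float(np.mean(_directed_distances(t, e)))
        + float(np.mean(_directed_distances(e, t)))
    )


def within_margin_proportion(T: CurveLike, E: CurveLike, radius: float = MARGIN_MM) -> float:
    """Fraction of points of T lying within ``radius`` mm of E.

    With the default 2 mm radius this is the proportion of the canal path
    inside the clinical implant safety margin.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    d = _directed_distances(_pts(T), _pts(E))
    return float(np.mean(d <= radius))


def interpolating_spline(control_points) -> Tuple[CubicSpline, np.ndarray]:
    """Natural cubic spline through the control points.

    Chord-length parameterised; returns the vector-valued spline and the
    parameter value of each control point.  The spline reproduces every
    control point exactly at its parameter.
    """
    pts = as_points(control_points)
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 control points")
    chord = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(chord == 0):
        raise ValueError("control points must be distinct")
    u = np.concatenate([[0.0], np.cumsum(chord)])
    if pts.shape[0] == 2:
        # degenerate: straight segment
        spline = CubicSpline(u, pts, axis=0, bc_type=((2, np.zeros(3)), (2, np.zeros(3))))
    else:
        spline = CubicSpline(u, pts, axis=0, bc_type="natural")
    return spline, u


def resample_uniform(points, n: Optional[int] = None, step: Optional[float] = None) -> np.ndarray:
    """Resample a polyline at uniform arc length (linear along segments).

    Exactly one of ``n`` (sample count, endpoints included) or ``step``
    (target spacing in mm) must be given.
    """
    pts = as_points(points)
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 points to resample")
    if (n is None) == (step is None):
        raise ValueError("give exactly one of n or step")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if n is None:
        n = max(2, int(round(total / step)) + 1)
    if n < 2:
        raise ValueError("n must be >= 2")
    targets = np.linspace(0.0, total, n)
    out = np.empty((n, 3))
    for axis in range(3):
        out[:, axis] = np.interp(targets, s, pts[:, axis])
    return out


def spline_densify(
    annotation: Union[ControlPointAnnotation, np.ndarray, Sequence],
    step: float = DENSIFY_STEP_MM,
) -> Curve3D:
    """Densify sparse control points into a smooth curve sampled every ~``step`` mm.

    Fits the interpolating spline, evaluates it finely, then resamples at
    approximately uniform arc length, keeping both endpoints.
    """
    if isinstance(annotation, ControlPointAnnotation):
        pts = annotation.control_points
        label = annotation.side
    else:
        pts = as_points(annotation)
        label = None
    if step <= 0:
        raise ValueError("step must be positive")
    spline, u = interpolating_spline(pts)
    # fine evaluation: ~8 samples per requested step
    n_fine = max(int(np.ceil(u[-1] / (step / 8.0))) + 1, pts.shape[0] * 8)
    fine = spline(np.linspace(0.0, u[-1], n_fine))
    # drop any accidental duplicates before arc-length resampling
    keep = np.concatenate([[True], np.linalg.norm(np.diff(fine, axis=0), axis=1) > 1e-12])
    dense = resample_uniform(fine[keep], step=step)
    return Curve3D(dense, label=label)


def harmonize_endpoints(
    curves: Sequence[Curve3D],
    superior_axis: int = SUPERIOR_AXIS,
    single_is_error: bool = False,
) -> List[Curve3D]:
    """Truncate curves to a common posterior extent.

    Annotators disagree most about how far the canal should be traced toward
    the mandibular foramen (the superior, posterior end).  The curve whose
    posterior endpoint is most inferior — the shortest annotation in the
    superior direction — is taken as the reference, and every other curve is
    cut at its point nearest to that reference endpoint.  Anterior ends are
    untouched.  Curves must be ordered posterior-first.
    """
    curves = list(curves)
    if len(curves) == 0:
        raise ValueError("harmonize_endpoints needs at least one curve")
    if len(curves) == 1:
        if single_is_error:
            raise ValueError("harmonize_endpoints needs at least two curves")
        return curves
    post_height = [c.points[0, superior_axis] for c in curves]
    ref_idx = int(np.argmin(post_height))
    ref_point = curves[ref_idx].points[0]
    out = []
    for i, c in enumerate(curves):
        if i == ref_idx:
            out.append(c)
            continue
        cut = int(np.argmin(np.linalg.norm(c.points - ref_point, axis=1)))
        cut = min(cut, len(c) - 2)  # keep at least 2 points
        out.append(c.with_points(c.points[cut:]))
    return out


def positional_profile(
    estimator: CurveLike, reference: CurveLike, n: int = 200
) -> DistanceProfile:
    """Point-to-curve distance along the estimator at ``n`` uniform arc positions.

    The estimator is resampled to ``n`` uniformly spaced interpolation points
    for a dense representation; each is measured against the reference point
    set.  Position 0 is the posterior end.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    resampled = resample_uniform(_pts(estimator), n=n)
    d = _directed_distances(resampled, _pts(reference))
    return DistanceProfile(position=np.linspace(0.0, 1.0, n), distance=d)


def dice_coefficient(a: LabelVolume, b: LabelVolume) -> float:
    """Dice similarity 2|A∩B| / (|A|+|B|); two empty masks give 1.0."""
    if a.grid.shape != b.grid.shape:
        raise ValueError(f"shape mismatch: {a.grid.shape} vs {b.grid.shape}")
    if not np.allclose(a.spacing, b.spacing):
        raise ValueError("spacing mismatch")
    na, nb = int(a.grid.sum()), int(b.grid.sum())
    if na + nb == 0:
        return 1.0
    inter = int(np.logical_and(a.grid, b.grid).sum())
    return 2.0 * inter / (na + nb)


def brute_force_mcd(T: CurveLike, E: CurveLike) -> float:
    """Exhaustive O(|T|·|E|) MCD, kept as an independent check of the KD-tree path."""
    t, e = _pts(T), _pts(E)
    d = np.linalg.norm(t[:, None, :] - e[None, :, :], axis=2)
    return float(d.min(axis=1).mean())
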