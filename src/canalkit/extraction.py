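"""Centerline extraction from binary canal segmentations.

A segmentation volume (e.g. the output of an automatic system) is thinned to
a one-voxel skeleton, the skeleton is decomposed into branch-free route
segments, nearby segments are concatenated across small gaps, routes without
the anatomical character of a mandibular canal (length, curvature) are
dropped, and finally the left/right pair of routes that are most mirror
symmetric about the midsagittal plane is selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

from .curve_metrics import resample_uniform, symmetric_mean_curve_distance
from .types import (
    LATERAL_AXIS,
    SUPERIOR_AXIS,
    CanalPair,
    Curve3D,
    LabelVolume,
    RouteSegment,
)


@dataclass
class ExtractionConfig:
    """Tunable parameters of the extraction pipeline (all in mm or degrees)."""

    min_segment_len_mm: float = 2.0
    prune_len_mm: float = 3.0
    #: thinning retracts tube ends by roughly one tube radius per side, so the
    #: pipeline tolerance must cover gap + 2*radius plus pruning losses
    gap_tol_mm: float = 12.0
    angle_gate_deg: float = 60.0
    min_route_len_mm: float = 30.0
    max_route_len_mm: float = 120.0
    curvature_max_per_mm: float = 0.5
    #: resampling step used for curvature estimation
    curvature_step_mm: float = 2.0
    #: one-voxel morphological closing+opening before thinning; suppresses
    #: surface noise that would riddle the skeleton with junctions
    presmooth: bool = True

    def to_dict(self) -> Dict[str, float]:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def skeletonize_volume(volume: LabelVolume) -> np.ndarray:
    """Medial-axis thinning of a binary volume.

    Returns the voxel indices of the one-voxel-wide skeleton as an (n, 3)
    int array; a subset of the foreground.  Empty foreground gives an empty
    set (downstream stages then report a failed status rather than raising).
    """
    if volume.grid.sum() == 0:
        return np.empty((0, 3), dtype=int)
    skel = skeletonize(volume.grid)  # Lee-style 3D thinning for 3D input
    return np.argwhere(skel)


_NEIGHBOUR_OFFSETS = np.array(
    [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ],
    dtype=int,
)


def _adjacency(voxels: np.ndarray) -> Dict[tuple, List[tuple]]:
    vox_set = {tuple(v) for v in voxels}
    adj: Dict[tuple, List[tuple]] = {}
    for v in sorted(vox_set):
        nbrs = []
        for off in _NEIGHBOUR_OFFSETS:
            w = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
            if w in vox_set:
                nbrs.append(w)
        adj[v] = nbrs
    return adj


def _locally_connected(voxels: List[tuple]) -> bool:
    """True when the voxels form one 26-connected cluster among themselves."""
    if not voxels:
        return False
    seen = {voxels[0]}
    queue = [voxels[0]]
    rest = set(voxels[1:])
    while queue:
        v = queue.pop()
        hits = {w for w in rest if max(abs(v[0] - w[0]), abs(v[1] - w[1]), abs(v[2] - w[2])) <= 1}
        rest -= hits
        seen |= hits
        queue.extend(hits)
    return not rest


def _prune_spurs(adj: Dict[tuple, List[tuple]], spacing: np.ndarray, prune_len_mm: float) -> None:
    """Iteratively delete short endpoint-to-junction twigs (in place).

    Surface noise on the segmented tube grows short side branches off the
    medial axis; left in place they split the main path at every junction.
    """
    def step_len(a, b):
        return float(np.linalg.norm((np.array(b) - np.array(a)) * spacing))

    changed = True
    while changed:
        changed = False
        endpoints = [v for v, n in adj.items() if len(n) == 1]
        for ep in sorted(endpoints):
            if ep not in adj or len(adj[ep]) != 1:
                continue
            path = [ep]
            length = 0.0
            cur, prev = adj[ep][0], ep
            while len(adj[cur]) == 2 and length <= prune_len_mm:
                length += step_len(prev, cur)
                path.append(cur)
                nxt = adj[cur][0] if adj[cur][0] != prev else adj[cur][1]
                prev, cur = cur, nxt
            length += step_len(prev, cur)
            if len(adj[cur]) > 2 and length <= prune_len_mm:
                for v in path:  # drop the twig, keep the junction
                    for w in adj[v]:
                        adj[w].remove(v)
                    del adj[v]
                changed = True
                # thick corner: if the junction's remaining neighbours stay
                # mutually connected without it, it is redundant — drop it too
                nbrs = list(adj[cur])
                if len(nbrs) > 2 and _locally_connected(nbrs):
                    for w in nbrs:
                        adj[w].remove(cur)
                    del adj[cur]


def extract_route_segments(
    skeleton_voxels: np.ndarray,
    volume: LabelVolume,
    min_segment_len_mm: float = 2.0,
    prune_len_mm: float = 3.0,
) -> List[RouteSegment]:
    """Decompose a skeleton into simple (branch-free) paths.

    Builds the 26-connectivity graph of the skeleton voxels, prunes spurs
    shorter than ``prune_len_mm`` hanging off junctions, splits at branch
    voxels (degree > 2), and walks every branch-free path.  Segments shorter
    than ``min_segment_len_mm`` are discarded.
    """
    if skeleton_voxels.shape[0] == 0:
        return []
    adj = _adjacency(skeleton_voxels)
    if prune_len_mm > 0:
        _prune_spurs(adj, volume.spacing, prune_len_mm)
    if not adj:
        return []
    is_branch = {v: len(n) > 2 for v, n in adj.items()}
    visited_edges = set()

    def edge_key(a, b):
        return (a, b) if a <= b else (b, a)

    paths: List[List[tuple]] = []
    # walk from every endpoint (degree 1) or branch voxel along each branch
    seeds = [v for v in adj if len(adj[v]) != 2 or is_branch[v]]
    for seed in sorted(seeds):
        for start_nbr in adj[seed]:
            if edge_key(seed, start_nbr) in visited_edges:
                continue
            path = [seed, start_nbr]
            visited_edges.add(edge_key(seed, start_nbr))
            cur, prev = start_nbr, seed
            while len(adj[cur]) == 2 and not is_branch[cur]:
                nxt = adj[cur][0] if adj[cur][0] != prev else adj[cur][1]
                if edge_key(cur, nxt) in visited_edges:
                    break
                visited_edges.add(edge_key(cur, nxt))
                path.append(nxt)
                prev, cur = cur, nxt
            paths.append(path)
    # isolated simple cycles (no seed voxel) are rare; pick them up too
    for v in sorted(adj):
        if len(adj[v]) == 2 and not any(
            edge_key(v, n) in visited_edges for n in adj[v]
        ):
            path = [v]
            prev, cur = v, adj[v][0]
            visited_edges.add(edge_key(v, cur))
            while cur != v:
                path.append(cur)
                nxt = adj[cur][0] if adj[cur][0] != prev else adj[cur][1]
                if edge_key(cur, nxt) in visited_edges:
                    break
                visited_edges.add(edge_key(cur, nxt))
                prev, cur = cur, nxt
            if len(path) >= 2:
                paths.append(path)

    segments = []
    for path in paths:
        vox = np.array(path, dtype=int)
        pts = volume.voxel_to_world(vox)
        seg = RouteSegment(vox, pts)
        if seg.arc_length >= min_segment_len_mm:
            segments.append(seg)
    return segments


@dataclass
class Route:
    """Ordered world-mm polyline assembled from one or more segments."""

    points: np.ndarray

    @property
    def arc_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


def _end_tangent(points: np.ndarray, end: str, reach_mm: float = 5.0) -> np.ndarray:
    """Unit direction of travel *leaving* the route at the given end."""
    if end == "tail":
        pts = points
    else:
        pts = points[::-1]
    # walk back from the end until ~reach_mm of arc is covered
    tip = pts[-1]
    acc = 0.0
    i = pts.shape[0] - 1
    while i > 0 and acc < reach_mm:
        acc += float(np.linalg.norm(pts[i] - pts[i - 1]))
        i -= 1
    v = tip - pts[i]
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([1.0, 0.0, 0.0])


def _trim_end(pts: np.ndarray, trim_mm: float) -> np.ndarray:
    """Drop points within ``trim_mm`` arc length of the final point."""
    if trim_mm <= 0:
        return pts
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc_from_end = np.concatenate([np.cumsum(seg[::-1])[::-1], [0.0]])
    keep = arc_from_end >= trim_mm
    if keep.sum() < 2:
        return pts
    return pts[: int(np.max(np.nonzero(keep))) + 1]


def concatenate_segments(
    segments: List[RouteSegment],
    gap_tol_mm: float = 4.0,
    angle_gate_deg: float = 60.0,
    bridge_step_mm: float = 0.4,
    forbid_plane_x: Optional[float] = None,
    end_trim_fn=None,
) -> List[Route]:
    """Greedily join segments whose endpoints are close and aligned.

    Repeatedly merges the route pair with the smallest endpoint gap that is
    within ``gap_tol_mm`` and whose directions of travel across the join
    differ by at most ``angle_gate_deg``; the gap is bridged with a straight
    polyline at ``bridge_step_mm`` steps.  Ties are broken by lower route
    index for determinism.  When ``forbid_plane_x`` is given, bridges
    crossing that sagittal plane are rejected (a mandibular canal never
    crosses the midline).  ``end_trim_fn``, when given, maps the oriented
    points of a joining end (end last) to an arc length to trim before
    bridging — thinning leaves an off-axis cone tip at every cut face, and
    trimming it keeps the bridge on the tube axis.
    """
    if gap_tol_mm <= 0:
        raise ValueError("gap_tol_mm must be positive")
    routes: List[Route] = [Route(s.points.copy()) for s in segments]
    cos_gate = np.cos(np.deg2rad(angle_gate_deg))

    def oriented(route: Route, end: str) -> np.ndarray:
        """Points ordered so the joining end is last."""
        return route.points if end == "tail" else route.points[::-1]

    while True:
        best = None  # (gap, i, j, end_i, end_j)
        for i in range(len(routes)):
            for j in range(i + 1, len(routes)):
                for ei in ("head", "tail"):
                    for ej in ("head", "tail"):
                        a = oriented(routes[i], ei)
                        b = oriented(routes[j], ej)
                        gap_vec = b[-1] - a[-1]
                        gap = float(np.linalg.norm(gap_vec))
                        if gap > gap_tol_mm:
                            continue
                        if forbid_plane_x is not None and (
                            (a[-1][LATERAL_AXIS] - forbid_plane_x)
                            * (b[-1][LATERAL_AXIS] - forbid_plane_x)
                            < 0
                        ):
                            continue
                        # travel direction leaving a, and entering b (b reversed
                        # so its joining end comes first in the merged route)
                        ta = _end_tangent(a, "tail")
                        tb = _end_tangent(b[::-1], "head") * -1.0
                        if float(np.dot(ta, tb)) < cos_gate:
                            continue
                        if gap > 1.0:
                            # the bridge must continue forward, never U-turn
                            # (retracted cone tips sit off-axis, so the gap
                            # vector can dip well below the tangent pair)
                            g = gap_vec / gap
                            if float(np.dot(ta, g)) <= 0.0 or float(np.dot(g, tb)) <= 0.0:
                                continue
                        cand = (gap, i, j, ei, ej)
                        if best is None or cand < best:
                            best = cand
        if best is None:
            break
        gap, i, j, ei, ej = best
        a = oriented(routes[i], ei)
        b = oriented(routes[j], ej)
        if end_trim_fn is not None and gap > 1.0:
            a = _trim_end(a, float(end_trim_fn(a)))
            b = _trim_end(b, float(end_trim_fn(b)))
        b = b[::-1]  # joining end of b first
        gap = float(np.linalg.norm(b[0] - a[-1]))
        bridge = np.empty((0, 3))
        if gap > bridge_step_mm:
            n_b = int(np.ceil(gap / bridge_step_mm))
            t = np.linspace(0.0, 1.0, n_b + 1)[1:-1]
            bridge = a[-1] + t[:, None] * (b[0] - a[-1])
        merged_pts = np.vstack([a, bridge, b]) if gap > 0 else np.vstack([a, b[1:]])
        merged = Route(merged_pts)
        routes = [r for k, r in enumerate(routes) if k not in (i, j)]
        routes.append(merged)
    return routes


def mean_absolute_curvature(points: np.ndarray, step_mm: float = 2.0) -> float:
    """Mean discrete curvature (turning angle per arc length) of a polyline.

    The polyline is resampled at ``step_mm`` so voxel-level jaggedness does
    not dominate.
    """
    total = float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())
    if total < 2 * step_mm:
        return 0.0
    pts = resample_uniform(points, step=step_mm)
    if pts.shape[0] < 3:
        return 0.0
    v1 = np.diff(pts[:-1], axis=0)
    v2 = np.diff(pts[1:], axis=0)
    n1 = np.linalg.norm(v1, axis=1)
    n2 = np.linalg.norm(v2, axis=1)
    cosang = np.clip((v1 * v2).sum(axis=1) / (n1 * n2), -1.0, 1.0)
    angles = np.arccos(cosang)
    ds = 0.5 * (n1 + n2)
    return float(np.mean(angles / ds))


def filter_anatomical(
    routes: List[Route],
    min_route_len_mm: float = 30.0,
    max_route_len_mm: float = 120.0,
    curvature_max_per_mm: float = 0.5,
    curvature_step_mm: float = 2.0,
) -> List[Route]:
    """Keep routes whose length and smoothness match a mandibular canal.

    Length bounds form a closed interval; curvature is mean absolute
    curvature below the gate.  Thresholds reflect adult mandible dimensions
    (canal arc length roughly 50–70 mm).
    """
    kept = []
    for r in routes:
        L = r.arc_length
        if not (min_route_len_mm <= L <= max_route_len_mm):
            continue
        if mean_absolute_curvature(r.points, step_mm=curvature_step_mm) >= curvature_max_per_mm:
            continue
        kept.append(r)
    return kept


def _mirror(points: np.ndarray, plane_x: float) -> np.ndarray:
    out = points.copy()
    out[:, LATERAL_AXIS] = 2.0 * plane_x - out[:, LATERAL_AXIS]
    return out


def midsagittal_plane_x(volume: LabelVolume) -> float:
    """x-coordinate of the vertical plane through the foreground centroid."""
    idx = np.argwhere(volume.grid)
    if idx.shape[0] == 0:
        raise ValueError("empty volume has no centroid")
    centroid = volume.voxel_to_world(idx.mean(axis=0))
    return float(centroid[LATERAL_AXIS])


def _orient_posterior_first(points: np.ndarray) -> np.ndarray:
    """Posterior end (mandibular foramen) has the greater superior coordinate."""
    if points[0, SUPERIOR_AXIS] < points[-1, SUPERIOR_AXIS]:
        return points[::-1].copy()
    return points


def select_symmetric_pair(routes: List[Route], volume: LabelVolume) -> CanalPair:
    """Pick the left/right route pair that is most mirror symmetric.

    The midsagittal plane is the vertical plane through the foreground
    centroid, normal to the left–right axis.  For every route pair on
    opposite sides the symmetry score is the SMCD between one route mirrored
    across the plane and the other; the pair with the minimal score wins.
    """
    if len(routes) == 0:
        return CanalPair(status="failed", diagnostic="no candidate routes")
    plane_x = midsagittal_plane_x(volume)
    sides = []
    for r in routes:
        cx = float(r.points[:, LATERAL_AXIS].mean())
        sides.append("left" if cx >= plane_x else "right")

    def make_curve(route: Route, side: str) -> Curve3D:
        return Curve3D(_orient_posterior_first(route.points), label=side)

    lefts = [i for i, s in enumerate(sides) if s == "left"]
    rights = [i for i, s in enumerate(sides) if s == "right"]
    if not lefts or not rights:
        # one-sided: report the longest route on the populated side
        side = "left" if lefts else "right"
        pool = lefts if lefts else rights
        best = max(pool, key=lambda i: routes[i].arc_length)
        curve = make_curve(routes[best], side)
        return CanalPair(
            left=curve if side == "left" else None,
            right=curve if side == "right" else None,
            status="partial",
            diagnostic=f"candidates only on the {side} side",
        )
    best_pair = None
    best_score = np.inf
    for i in lefts:
        for j in rights:
            score = symmetric_mean_curve_distance(
                _mirror(routes[i].points, plane_x), routes[j].points
            )
            if score < best_score - 1e-12:
                best_score = score
                best_pair = (i, j)
    i, j = best_pair
    return CanalPair(
        left=make_curve(routes[i], "left"),
        right=make_curve(routes[j], "right"),
        symmetry_score=float(best_score),
        status="ok",
    )


def extract_canals(volume: LabelVolume, config: Optional[ExtractionConfig] = None) -> CanalPair:
    """Full post-processing chain from a binary segmentation to a canal pair.

    skeletonize → branch-free segments → gap concatenation → anatomical
    filtering → symmetric pair selection.  Curves are returned in world mm,
    ordered posterior→anterior.  Never raises on a valid binary volume;
    failures surface as ``status`` plus a diagnostic.
    """
    cfg = config or ExtractionConfig()
    if cfg.presmooth and volume.grid.any():
        ball = ndimage.generate_binary_structure(3, 3)
        grid = ndimage.binary_opening(ndimage.binary_closing(volume.grid, ball), ball)
        volume = LabelVolume(grid, volume.spacing, volume.origin)
    skel = skeletonize_volume(volume)
    if skel.shape[0] == 0:
        return CanalPair(status="failed", diagnostic="empty segmentation")
    segments = extract_route_segments(
        skel, volume, cfg.min_segment_len_mm, prune_len_mm=cfg.prune_len_mm
    )
    edt = ndimage.distance_transform_edt(volume.grid, sampling=volume.spacing)
    shape = np.array(volume.shape)

    def end_trim(pts_end_last: np.ndarray) -> float:
        # local tube radius sampled ~3 mm inside the joining end; the cone
        # the thinning leaves at a cut face is about that long
        probe = _trim_end(pts_end_last, 3.0)[-1]
        idx = np.clip(np.round(volume.world_to_voxel(probe)).astype(int), 0, shape - 1)
        return 1.5 * float(edt[tuple(idx)])

    routes = concatenate_segments(
        segments,
        gap_tol_mm=cfg.gap_tol_mm,
        angle_gate_deg=cfg.angle_gate_deg,
        forbid_plane_x=midsagittal_plane_x(volume),
        end_trim_fn=end_trim,
    )
    routes = filter_anatomical(
        routes,
        min_route_len_mm=cfg.min_route_len_mm,
        max_route_len_mm=cfg.max_route_len_mm,
        curvature_max_per_mm=cfg.curvature_max_per_mm,
        curvature_step_mm=cfg.curvature_step_mm,
    )
    if not routes:
        return CanalPair(status="failed", diagnostic="no route passed anatomical filters")
    return select_symmetric_pair(routes, volume)
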