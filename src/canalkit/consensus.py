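"""Majority-vote reference ("gold standard") segmentation and curve.

Each grader's annotation curve is rasterized into a fixed-diameter tube on a
common grid; per-voxel label voting assigns canal where canal votes beat
background votes, with undecided (tied) voxels marked as canal.  The vote
mask is skeletonized and, per side of the midsagittal plane, the largest
connected skeleton component becomes the reference curve.  Gaps are NOT
bridged: where graders genuinely disagree the consensus may legitimately
have missing parts, and the reference curve should show that.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .curve_metrics import spline_densify
from .extraction import _orient_posterior_first, skeletonize_volume
from .types import LATERAL_AXIS, Curve3D, LabelVolume, VoteVolume

#: default annotation-tool tube diameter in mm (typical canal calibre)
DEFAULT_DIAMETER_MM = 3.0


@dataclass(frozen=True)
class GridSpec:
    """Target voxel grid: shape, isotropic spacing and world origin (mm)."""

    shape: Tuple[int, int, int]
    spacing: float
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def empty_volume(self) -> LabelVolume:
        return LabelVolume(
            np.zeros(self.shape, dtype=bool), np.full(3, self.spacing), np.array(self.origin)
        )


def rasterize_curve(
    curve: Curve3D,
    diameter: float = DEFAULT_DIAMETER_MM,
    grid_spec: Optional[GridSpec] = None,
    grid_like: Optional[LabelVolume] = None,
) -> LabelVolume:
    """Rasterize a curve as a tube of the given diameter.

    A voxel is set when its centre lies within ``diameter / 2`` of the
    densified curve.  The curve must fit inside the grid.
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    if (grid_spec is None) == (grid_like is None):
        raise ValueError("give exactly one of grid_spec or grid_like")
    vol = grid_spec.empty_volume() if grid_spec is not None else grid_like.copy()
    vol.grid[:] = False
    spacing = vol.spacing
    # densify finer than the voxel size so the tube has no gaps
    step = min(float(spacing.min()) / 2.0, 0.5)
    dense = spline_densify(curve.points, step=step).points
    lo_w = vol.origin
    hi_w = vol.origin + (np.array(vol.shape) - 1) * spacing
    if np.any(dense.min(axis=0) < lo_w - 1e-9) or np.any(dense.max(axis=0) > hi_w + 1e-9):
        raise ValueError(
            "curve outside grid: curve extent "
            f"{dense.min(axis=0)}..{dense.max(axis=0)}, grid extent {lo_w}..{hi_w}"
        )
    r = diameter / 2.0
    lo = np.maximum(np.floor(vol.world_to_voxel(dense.min(axis=0) - r)), 0).astype(int)
    hi = np.minimum(
        np.ceil(vol.world_to_voxel(dense.max(axis=0) + r)), np.array(vol.shape) - 1
    ).astype(int)
    ii, jj, kk = np.meshgrid(
        *[np.arange(lo[a], hi[a] + 1) for a in range(3)], indexing="ij"
    )
    idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    centres = vol.origin + idx * spacing
    d, _ = cKDTree(dense).query(centres, k=1)
    inside = idx[d <= r]
    vol.grid[inside[:, 0], inside[:, 1], inside[:, 2]] = True
    return vol


def vote_counts(masks: Sequence[LabelVolume]) -> VoteVolume:
    """Stack per-grader masks into per-voxel canal vote counts."""
    if len(masks) < 2:
        raise ValueError("voting needs at least 2 masks")
    first = masks[0]
    for m in masks[1:]:
        if not first.same_grid(m):
            raise ValueError("masks must share an identical grid")
    votes = np.zeros(first.shape, dtype=np.int32)
    for m in masks:
        votes += m.grid
    return VoteVolume(votes, len(masks), first.spacing, first.origin)


def majority_vote(masks: Sequence[LabelVolume]) -> LabelVolume:
    """Per-voxel majority label; undecided (tied) voxels are marked canal.

    Canal wherever canal votes > background votes; background when the
    background wins; an exact tie (possible with an even grader count) goes
    to canal.
    """
    vv = vote_counts(masks)
    canal = 2 * vv.votes >= vv.n_graders  # tie -> canal
    return LabelVolume(canal, vv.spacing, vv.origin)


def _largest_component_path(voxels: np.ndarray) -> np.ndarray:
    """Order a 26-connected skeleton component as a path via double BFS."""
    from .extraction import _adjacency  # shared voxel-graph helper

    adj = _adjacency(voxels)

    def bfs_farthest(start):
        seen = {start: None}
        order = [start]
        queue = [start]
        while queue:
            nxt = []
            for v in queue:
                for w in adj[v]:
                    if w not in seen:
                        seen[w] = v
                        order.append(w)
                        nxt.append(w)
            queue = nxt
        return order[-1], seen

    start = tuple(voxels[0])
    a, _ = bfs_farthest(start)
    b, parents = bfs_farthest(a)
    path = [b]
    while parents[path[-1]] is not None:
        path.append(parents[path[-1]])
    return np.array(path[::-1], dtype=int)


def reference_curve(
    vote_mask: LabelVolume,
    midsagittal_x: Optional[float] = None,
) -> Dict[str, Optional[Curve3D]]:
    """Skeletonize the consensus mask and extract one curve per side.

    Per side of the midsagittal plane the largest 26-connected skeleton
    component is kept (ties by most-posterior centroid) and ordered
    posterior→anterior along its longest path.  Sides with no skeleton are
    reported as ``None`` so missing consensus is explicit, never silent.
    """
    out: Dict[str, Optional[Curve3D]] = {"left": None, "right": None}
    skel = skeletonize_volume(vote_mask)
    if skel.shape[0] == 0:
        return out
    if midsagittal_x is None:
        centroid = vote_mask.voxel_to_world(np.argwhere(vote_mask.grid).mean(axis=0))
        midsagittal_x = float(centroid[LATERAL_AXIS])
    world = vote_mask.voxel_to_world(skel)
    for side in ("left", "right"):
        if side == "left":
            sel = world[:, LATERAL_AXIS] >= midsagittal_x
        else:
            sel = world[:, LATERAL_AXIS] < midsagittal_x
        side_vox = skel[sel]
        if side_vox.shape[0] < 2:
            continue
        # label the side's skeleton voxels into 26-connected components
        lo = side_vox.min(axis=0)
        sub = np.zeros(side_vox.max(axis=0) - lo + 1, dtype=bool)
        sub[tuple((side_vox - lo).T)] = True
        labels, n = ndimage.label(sub, structure=np.ones((3, 3, 3)))
        if n == 0:
            continue
        sizes = ndimage.sum_labels(sub, labels, index=np.arange(1, n + 1))
        top = np.flatnonzero(sizes == sizes.max()) + 1
        if top.size > 1:
            # tie on voxel count: prefer the most posterior centroid (min y)
            cents = ndimage.center_of_mass(sub, labels, index=top)
            best = int(top[np.argmin([c[1] for c in cents])])
        else:
            best = int(top[0])
        comp = np.argwhere(labels == best) + lo
        if comp.shape[0] < 2:
            continue
        path = _largest_component_path(comp)
        pts = vote_mask.voxel_to_world(path)
        out[side] = Curve3D(_orient_posterior_first(pts), label=side)
    return out


def build_consensus(
    curves: Sequence[Curve3D],
    grid_spec: GridSpec,
    diameter: float = DEFAULT_DIAMETER_MM,
) -> Tuple[LabelVolume, Dict[str, Optional[Curve3D]]]:
    """Rasterize grader curves for one canal, vote, and extract the reference.

    Convenience wrapper: the returned reference dict contains the side the
    input curves carry (both sides when curves from both are supplied).
    """
    masks = [rasterize_curve(c, diameter=diameter, grid_spec=grid_spec) for c in curves]
    mask = majority_vote(masks)
    # side split is irrelevant when all curves sit on one side; pick a plane
    # far from the tube so the whole skeleton lands on a single side
    xs = np.concatenate([c.points[:, LATERAL_AXIS] for c in curves])
    sides = {c.label for c in curves if c.label}
    if sides == {"left"}:
        plane = float(xs.min()) - 10.0
    elif sides == {"right"}:
        plane = float(xs.max()) + 10.0
    else:
        plane = None
    return mask, reference_curve(mask, midsagittal_x=plane)
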