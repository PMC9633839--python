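"""Shared domain types.

Coordinate convention: right-handed world coordinates in millimetres with
x = left–right, y = posterior–anterior and z = inferior–superior (+z is
superior).  Curves are ordered polylines from the posterior end (mandibular
foramen, which sits superior to the canal mid-course) to the anterior end
(mental foramen).  Voxel index (i, j, k) maps to world position
``origin + index * spacing`` (identity direction matrix).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

#: index of the superior axis in world coordinates
SUPERIOR_AXIS = 2
#: index of the left-right axis in world coordinates
LATERAL_AXIS = 0


def as_points(points) -> np.ndarray:
    """Coerce to a float (n, 3) array, validating shape and finiteness."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1 and pts.size == 3:
        pts = pts[None, :]
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"expected (n, 3) point array, got shape {pts.shape}")
    if pts.shape[0] == 0:
        raise ValueError("empty point set (degenerate curve)")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points contain non-finite coordinates")
    return pts


@dataclass(frozen=True)
class Curve3D:
    """Ordered polyline of 3D points in mm, posterior end first.

    Parameters
    ----------
    points : array-like of shape (n, 3)
        Ordered coordinates in mm; at least two points, consecutive points
        distinct.
    label : str, optional
        Side tag, ``"left"`` or ``"right"``.
    """

    points: np.ndarray
    label: Optional[str] = None

    def __post_init__(self):
        pts = as_points(self.points)
        if pts.shape[0] < 2:
            raise ValueError("Curve3D needs at least 2 points")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg == 0.0):
            raise ValueError("consecutive curve points must be distinct")
        object.__setattr__(self, "points", pts)
        if self.label is not None and self.label not in ("left", "right"):
            raise ValueError("label must be 'left' or 'right'")

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def arc_length(self) -> float:
        """Total polyline length in mm."""
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    def reversed(self) -> "Curve3D":
        return Curve3D(self.points[::-1].copy(), label=self.label)

    def with_points(self, points) -> "Curve3D":
        return Curve3D(np.asarray(points, dtype=float), label=self.label)


@dataclass(frozen=True)
class ControlPointAnnotation:
    """Sparse expert control points (mm) plus identifying metadata.

    Control points are placed roughly 3 mm apart along the canal and are
    densified with an interpolating spline before metric computation.
    """

    control_points: np.ndarray
    grader_id: str = ""
    scan_id: str = ""
    side: str = "left"
    clarity: str = "Clear"

    #: nominal control-point spacing in mm
    NOMINAL_SPACING_MM = 3.0

    def __post_init__(self):
        pts = as_points(self.control_points)
        if pts.shape[0] < 2:
            raise ValueError("annotation needs at least 2 control points")
        object.__setattr__(self, "control_points", pts)
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        if self.clarity not in ("Clear", "Unclear"):
            raise ValueError("clarity must be 'Clear' or 'Unclear'")

    def spacing_ok(self, tol: float = 1.5) -> bool:
        """True when consecutive control points are ~3 mm apart (within tol)."""
        seg = np.linalg.norm(np.diff(self.control_points, axis=0), axis=1)
        return bool(np.all(np.abs(seg - self.NOMINAL_SPACING_MM) <= tol))


@dataclass(frozen=True)
class DistanceProfile:
    """Point-to-curve distance sampled along normalised arc-length."""

    position: np.ndarray  # in [0, 1], strictly increasing
    distance: np.ndarray  # mm, >= 0

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        dist = np.asarray(self.distance, dtype=float)
        if pos.shape != dist.shape or pos.ndim != 1:
            raise ValueError("position and distance must be 1D of equal length")
        if np.any(np.diff(pos) <= 0):
            raise ValueError("positions must be strictly increasing")
        if abs(pos[0]) > 1e-12 or abs(pos[-1] - 1.0) > 1e-12:
            raise ValueError("positions must span [0, 1]")
        if np.any(dist < 0):
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "distance", dist)

    @property
    def n_samples(self) -> int:
        return self.position.shape[0]


@dataclass
class LabelVolume:
    """3D binary grid with voxel spacing and world origin in mm.

    ``grid`` is indexed ``[i, j, k]`` along world x, y, z.
    """

    grid: np.ndarray
    spacing: np.ndarray  # (3,) mm per voxel
    origin: np.ndarray = None  # world mm of voxel (0, 0, 0)

    def __post_init__(self):
        grid = np.asarray(self.grid)
        if grid.ndim != 3:
            raise ValueError("grid must be 3D")
        self.grid = grid.astype(bool)
        spacing = np.broadcast_to(np.asarray(self.spacing, dtype=float), (3,)).copy()
        if np.any(spacing <= 0):
            raise ValueError("spacing must be positive")
        self.spacing = spacing
        self.origin = (
            np.zeros(3) if self.origin is None else np.asarray(self.origin, dtype=float)
        )

    @property
    def shape(self):
        return self.grid.shape

    @property
    def is_isotropic(self) -> bool:
        return bool(np.allclose(self.spacing, self.spacing[0], rtol=1e-3))

    def voxel_to_world(self, idx) -> np.ndarray:
        return self.origin + np.asarray(idx, dtype=float) * self.spacing

    def world_to_voxel(self, xyz) -> np.ndarray:
        return (np.asarray(xyz, dtype=float) - self.origin) / self.spacing

    def same_grid(self, other: "LabelVolume") -> bool:
        return (
            self.grid.shape == other.grid.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def copy(self) -> "LabelVolume":
        return LabelVolume(self.grid.copy(), self.spacing.copy(), self.origin.copy())


@dataclass
class VoteVolume:
    """Per-voxel canal vote counts from ``n_graders`` binary masks."""

    votes: np.ndarray  # int counts
    n_graders: int
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self):
        votes = np.asarray(self.votes)
        if votes.min(initial=0) < 0 or votes.max(initial=0) > self.n_graders:
            raise ValueError("votes must lie in [0, n_graders]")
        self.votes = votes.astype(np.int32)
        self.spacing = np.broadcast_to(np.asarray(self.spacing, dtype=float), (3,)).copy()
        self.origin = np.asarray(self.origin, dtype=float)


@dataclass(frozen=True)
class RouteSegment:
    """Branch-free skeleton path: ordered voxel indices plus world geometry."""

    voxels: np.ndarray  # (n, 3) int voxel indices, 26-connected consecutive
    points: np.ndarray  # (n, 3) world mm

    def __post_init__(self):
        vox = np.asarray(self.voxels, dtype=int)
        pts = np.asarray(self.points, dtype=float)
        if vox.ndim != 2 or vox.shape[1] != 3 or vox.shape[0] < 2:
            raise ValueError("segment needs >= 2 voxels")
        if pts.shape != vox.shape:
            raise ValueError("points/voxels shape mismatch")
        if np.any(np.abs(np.diff(vox, axis=0)).max(axis=1) > 1):
            raise ValueError("consecutive voxels must be 26-connected")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "points", pts)

    @property
    def arc_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass
class CanalPair:
    """Result of canal extraction: left/right curves plus bookkeeping."""

    left: Optional[Curve3D] = None
    right: Optional[Curve3D] = None
    symmetry_score: Optional[float] = None
    status: str = "failed"  # ok | partial | failed
    diagnostic: str = ""

    def __post_init__(self):
        if self.status not in ("ok", "partial", "failed"):
            raise ValueError("status must be ok, partial or failed")
        if self.status == "ok" and (self.left is None or self.right is None):
            raise ValueError("status=ok requires both curves")

    @property
    def curves(self) -> dict:
        out = {}
        if self.left is not None:
            out["left"] = self.left
        if self.right is not None:
            out["right"] = self.right
        return out


#: heterogeneity condition flags recorded per scan
HETEROGENEITY_FLAGS = (
    "movement_artefact",
    "metal_artefact",
    "bisagittal_osteotomy",
    "difficult_bone_structure",
    "difficult_pathology",
)

#: scanner devices of the multicenter cohort (synthetic analogues use the same names)
DEVICES = ("ProMax 3D Max/Mid", "Viso G7", "Scanora 3Dx", "DentiScan", "GiANO HR")


@dataclass
class ScanRecord:
    """Per-scan metadata: device, site, per-canal clarity, condition flags."""

    scan_id: str
    device: str
    site: str = ""
    clarity: dict = field(default_factory=lambda: {"left": "Clear", "right": "Clear"})
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in HETEROGENEITY_FLAGS:
            self.flags.setdefault(name, False)
        for side, c in self.clarity.items():
            if c not in ("Clear", "Unclear"):
                raise ValueError(f"clarity[{side}] must be Clear or Unclear")
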