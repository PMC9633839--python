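"""Synthetic phantom cohorts with known ground truth.

The real study data (CBCT scans, expert annotations, a trained CNN) is
private, so validation runs on phantoms that emulate its *structure*: paired
left/right canal curves following a mandibular-arch-like path, four expert
annotations per canal built from control points ~3 mm apart with spline
interpolation, annotator noise including rare gross errors, and
segmentation-style label volumes at 0.4 mm isotropic spacing with optional
gaps and spurious components.  Only label-level structure is emulated — no
image physics.

Every artefact is reproducible bit-for-bit from a single global seed, which
fans out to per-scan/per-component seeds through ``numpy.random.SeedSequence``
spawning.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.spatial import cKDTree

from .consensus import GridSpec
from .curve_metrics import resample_uniform, spline_densify
from .types import (
    DEVICES,
    HETEROGENEITY_FLAGS,
    ControlPointAnnotation,
    Curve3D,
    LabelVolume,
    ScanRecord,
)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of one synthetic mandible's canal pair.

    The canal pair follows a parabolic arch in the axial plane, rises
    superiorly toward the posterior end (mandibular foramen) and curves
    anteriorly near the mental region.  Defaults give canal arc lengths of
    about 54 mm, inside the adult 50–70 mm range.
    """

    arch_width_mm: float = 90.0
    arch_depth_mm: float = 32.0
    canal_dip_mm: float = 8.0
    canal_length_mm: float = 54.0  # target arc length (checked, not enforced)
    asymmetry_jitter_mm: float = 1.0
    spacing_mm: float = 0.4
    #: anterior endpoint offset from the midline (mental foramen), mm
    anterior_offset_mm: float = 6.0
    #: z of the canal's most inferior point, mm
    base_height_mm: float = 6.0
    grid_margin_mm: float = 4.0

    def __post_init__(self):
        for name in ("arch_width_mm", "arch_depth_mm", "canal_dip_mm", "spacing_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def grid_spec(self) -> GridSpec:
        """Grid enclosing the canal pair with a comfortable margin."""
        m = self.grid_margin_mm
        half = self.arch_width_mm / 2.0
        lo = np.array([-half - m, -m, self.base_height_mm - m])
        hi = np.array([half + m, self.arch_depth_mm + m,
                       self.base_height_mm + self.canal_dip_mm + m])
        shape = tuple(int(np.ceil((hi[a] - lo[a]) / self.spacing_mm)) + 1 for a in range(3))
        return GridSpec(shape=shape, spacing=self.spacing_mm, origin=tuple(lo))


@dataclass(frozen=True)
class AnnotatorModel:
    """Noise model for one expert's control-point annotation.

    Noise decomposes into a smooth systematic offset (the annotator's
    personal idea of the canal centre), independent perpendicular jitter per
    control point, rare gross errors (a control point placed outside the
    canal), and posterior-endpoint truncation variability.
    """

    jitter_sd_mm: float = 0.15
    systematic_sd_mm: float = 0.22
    systematic_corr_mm: float = 12.0
    control_spacing_mm: float = 3.0
    gross_error_rate: float = 0.024
    gross_magnitude_mm: float = 3.0
    truncation_sd_mm: float = 1.5

    def __post_init__(self):
        if not 0.0 <= self.gross_error_rate <= 1.0:
            raise ValueError("gross_error_rate must be in [0, 1]")
        for name in ("jitter_sd_mm", "systematic_sd_mm", "truncation_sd_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def scaled(self, k: float) -> "AnnotatorModel":
        """Noise amplitudes multiplied by ``k`` (spacing and rates untouched)."""
        return replace(
            self,
            jitter_sd_mm=self.jitter_sd_mm * k,
            systematic_sd_mm=self.systematic_sd_mm * k,
        )


@dataclass(frozen=True)
class SystemModel:
    """Defect model for an automatic-segmentation-style label volume."""

    tube_radius_mm: float = 1.5
    boundary_flip_prob: float = 0.1
    gap_rate: float = 0.3
    gap_length_mm: float = 3.0
    spurious_rate: float = 0.3
    spurious_size_mm: float = 8.0
    failure_rate: float = 0.0

    def __post_init__(self):
        for name in ("boundary_flip_prob", "gap_rate", "spurious_rate", "failure_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.tube_radius_mm <= 0:
            raise ValueError("tube_radius_mm must be positive")


# ---------------------------------------------------------------------------
# Ground truth geometry


def _canal_points(spec: PhantomSpec, n: int = 400) -> np.ndarray:
    """Left canal polyline, posterior (s=0) to anterior (s=1)."""
    s = np.linspace(0.0, 1.0, n)
    half = spec.arch_width_mm / 2.0
    x = half + (spec.anterior_offset_mm - half) * s
    y = spec.arch_depth_mm * (1.0 - (x / half) ** 2)
    s_min = 0.55  # arc position of the canal's most inferior point
    a = spec.canal_dip_mm / s_min**2
    z = spec.base_height_mm + a * (s - s_min) ** 2
    return np.stack([x, y, z], axis=1)


def _smooth_field(rng: np.random.Generator, arc: np.ndarray, sd: float, corr_mm: float,
                  n_dims: int = 3) -> np.ndarray:
    """Gaussian process samples along arc positions (squared-exp kernel)."""
    n = arc.shape[0]
    if sd == 0.0 or n == 0:
        return np.zeros((n, n_dims))
    d = arc[:, None] - arc[None, :]
    K = np.exp(-0.5 * (d / max(corr_mm, 1e-6)) ** 2) + 1e-9 * np.eye(n)
    L = np.linalg.cholesky(K)
    return sd * (L @ rng.standard_normal((n, n_dims)))


def generate_ground_truth(
    spec: PhantomSpec, seed: Union[int, np.random.SeedSequence]
) -> Tuple[Curve3D, Curve3D]:
    """Smooth left/right canal pair; right is the mirrored left plus jitter.

    With ``asymmetry_jitter_mm = 0`` the right canal is the exact mirror
    image of the left across the midsagittal plane x = 0.
    """
    rng = np.random.default_rng(seed)
    left_pts = _canal_points(spec)
    right_pts = left_pts.copy()
    right_pts[:, 0] *= -1.0
    if spec.asymmetry_jitter_mm > 0:
        seg = np.linalg.norm(np.diff(right_pts, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        jit = _smooth_field(rng, arc, spec.asymmetry_jitter_mm / 2.0, corr_mm=15.0)
        jit = np.clip(jit, -spec.asymmetry_jitter_mm, spec.asymmetry_jitter_mm)
        right_pts = right_pts + jit
    gs = spec.grid_spec()
    lo = np.array(gs.origin)
    hi = lo + (np.array(gs.shape) - 1) * gs.spacing
    margin = 5 * spec.spacing_mm
    for pts, side in ((left_pts, "left"), (right_pts, "right")):
        if np.any(pts.min(axis=0) - lo < margin - 1e-9) or np.any(hi - pts.max(axis=0) < margin - 1e-9):
            raise ValueError(f"{side} canal does not fit the grid with a 5-voxel margin")
    return Curve3D(left_pts, label="left"), Curve3D(right_pts, label="right")


# ---------------------------------------------------------------------------
# Annotator simulation


def simulate_annotation(
    gt: Curve3D,
    model: AnnotatorModel,
    seed: Union[int, np.random.SeedSequence],
    grader_id: str = "",
    scan_id: str = "",
    clarity: str = "Clear",
) -> ControlPointAnnotation:
    """Simulate one expert's control-point annotation of a ground-truth canal.

    Control points are placed at ~3 mm arc spacing on the (possibly
    posterior-truncated) ground truth, then displaced by a smooth correlated
    offset plus independent perpendicular jitter; each control point is
    additionally knocked a fixed gross magnitude in a random direction with
    the gross-error probability.
    """
    rng = np.random.default_rng(seed)
    pts = gt.points
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    # posterior-endpoint truncation: annotators stop short of the foramen
    cut = abs(rng.normal(0.0, model.truncation_sd_mm)) if model.truncation_sd_mm > 0 else 0.0
    cut = min(cut, 0.2 * total)
    keep = arc >= cut
    first = int(np.argmax(keep))
    trunc = pts[first:]
    ctrl = resample_uniform(trunc, step=model.control_spacing_mm)
    n = ctrl.shape[0]
    carc = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(ctrl, axis=0), axis=1))]
    )
    out = ctrl + _smooth_field(rng, carc, model.systematic_sd_mm, model.systematic_corr_mm)
    # perpendicular jitter: white noise in the plane normal to the local tangent
    if model.jitter_sd_mm > 0:
        tang = np.gradient(ctrl, axis=0)
        tang /= np.linalg.norm(tang, axis=1, keepdims=True)
        raw = rng.normal(0.0, model.jitter_sd_mm, size=(n, 3))
        raw -= (raw * tang).sum(axis=1, keepdims=True) * tang
        out = out + raw
    if model.gross_error_rate > 0:
        hit = rng.random(n) < model.gross_error_rate
        if hit.any():
            tang = np.gradient(ctrl, axis=0)
            tang /= np.linalg.norm(tang, axis=1, keepdims=True)
            dirs = rng.standard_normal((int(hit.sum()), 3))
            # displace perpendicular to the canal so the point truly leaves it
            dirs -= (dirs * tang[hit]).sum(axis=1, keepdims=True) * tang[hit]
            dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
            out[hit] = out[hit] + model.gross_magnitude_mm * dirs
    return ControlPointAnnotation(
        out, grader_id=grader_id, scan_id=scan_id, side=gt.label or "left", clarity=clarity
    )


# ---------------------------------------------------------------------------
# System (automatic segmentation) simulation


def _rasterize_tube(
    grid: np.ndarray, gs: GridSpec, dense: np.ndarray, radius: float
) -> np.ndarray:
    """Per-voxel distance field to the curve inside its bounding box; marks grid."""
    origin = np.array(gs.origin)
    spacing = gs.spacing
    lo = np.maximum(np.floor((dense.min(axis=0) - radius - origin) / spacing), 0).astype(int)
    hi = np.minimum(
        np.ceil((dense.max(axis=0) + radius - origin) / spacing),
        np.array(gs.shape) - 1,
    ).astype(int)
    ii, jj, kk = np.meshgrid(*[np.arange(lo[a], hi[a] + 1) for a in range(3)], indexing="ij")
    idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    centres = origin + idx * spacing
    d, _ = cKDTree(dense).query(centres, k=1)
    inside = idx[d <= radius]
    grid[inside[:, 0], inside[:, 1], inside[:, 2]] = True
    return idx[np.abs(d - radius) <= spacing]  # boundary shell, for noise


def simulate_system_volume(
    gt_pair: Tuple[Curve3D, Curve3D],
    model: SystemModel,
    grid_spec: GridSpec,
    seed: Union[int, np.random.SeedSequence],
) -> LabelVolume:
    """Automatic-segmentation-style binary volume around the true canal pair.

    Tubes around each ground-truth curve, with boundary voxel flips, optional
    short gaps (exercising gap concatenation downstream), optional spurious
    off-canal components (exercising anatomical filtering) and, with the
    failure probability, a canal omitted entirely.
    """
    rng = np.random.default_rng(seed)
    vol = grid_spec.empty_volume()
    origin = np.array(grid_spec.origin)
    spacing = grid_spec.spacing
    for curve in gt_pair:
        if rng.random() < model.failure_rate:
            continue
        dense = resample_uniform(curve.points, step=spacing / 2.0)
        shell = _rasterize_tube(vol.grid, grid_spec, dense, model.tube_radius_mm)
        if rng.random() < model.gap_rate and model.gap_length_mm > 0:
            # carve out all tube voxels whose nearest curve point falls in a
            # gap_length_mm arc window, so the axial gap has the stated length
            arc = np.concatenate(
                [[0.0], np.cumsum(np.linalg.norm(np.diff(dense, axis=0), axis=1))]
            )
            centre_arc = rng.uniform(0.15, 0.85) * arc[-1]
            in_window = np.abs(arc - centre_arc) <= model.gap_length_mm / 2.0
            window = dense[in_window]
            reach = model.tube_radius_mm + 2.0 * spacing
            lo = np.maximum(
                np.floor((window.min(axis=0) - reach - origin) / spacing), 0
            ).astype(int)
            hi = np.minimum(
                np.ceil((window.max(axis=0) + reach - origin) / spacing),
                np.array(grid_spec.shape) - 1,
            ).astype(int)
            ii, jj, kk = np.meshgrid(
                *[np.arange(lo[a], hi[a] + 1) for a in range(3)], indexing="ij"
            )
            idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
            centres = origin + idx * spacing
            tree = cKDTree(dense)
            d, nearest = tree.query(centres, k=1)
            cut = idx[(d <= reach) & in_window[nearest]]
            vol.grid[cut[:, 0], cut[:, 1], cut[:, 2]] = False
        if model.boundary_flip_prob > 0 and shell.shape[0]:
            flip = rng.random(shell.shape[0]) < model.boundary_flip_prob
            f = shell[flip]
            vol.grid[f[:, 0], f[:, 1], f[:, 2]] ^= True
    if rng.random() < model.spurious_rate and model.spurious_size_mm > 0:
        # short straight spur, kept well clear of both canals so it exercises
        # the anatomical filter rather than the gap concatenation
        both = np.vstack([c.points for c in gt_pair])
        hi_w = origin + (np.array(grid_spec.shape) - 2) * spacing
        clearance = 14.0
        for _ in range(20):
            start = np.array([
                rng.uniform(origin[0] + 2, hi_w[0] - 2),
                rng.uniform(origin[1] + 2, hi_w[1] - 2),
                rng.uniform(origin[2] + 2, hi_w[2] - 2),
            ])
            direction = rng.standard_normal(3)
            direction /= max(np.linalg.norm(direction), 1e-9)
            end = start + direction * model.spurious_size_mm
            spur = np.linspace(start, end, 32)
            inb = np.all((spur >= origin + spacing) & (spur <= hi_w), axis=1)
            if inb.sum() < 8:
                continue
            d, _ = cKDTree(both).query(spur[inb], k=1)
            if d.min() >= clearance:
                _rasterize_tube(vol.grid, grid_spec, spur[inb], model.tube_radius_mm * 0.8)
                break
    return vol


# ---------------------------------------------------------------------------
# Cohort generation


@dataclass
class Cohort:
    """A generated study cohort plus its full ground truth.

    ``system_curves`` is filled in "curve" mode (the system output modelled
    directly as a noisy curve); ``system_volumes`` in "volume" mode (the
    system output as a defective label volume, to be run through canal
    extraction).  Keys are (scan_id, side) for per-canal items.
    """

    records: List[ScanRecord]
    ground_truth: Dict[Tuple[str, str], Curve3D]
    annotations: Dict[Tuple[str, str, str], ControlPointAnnotation]  # (grader, scan, side)
    system_curves: Dict[Tuple[str, str], Optional[Curve3D]]
    system_volumes: Dict[str, LabelVolume]
    grid_specs: Dict[str, GridSpec]
    manifest: Dict

    @property
    def grader_ids(self) -> List[str]:
        return sorted({g for (g, _, _) in self.annotations})

    def expert_curves(self, step: float = 0.5) -> Dict[str, Dict[Tuple[str, str], Curve3D]]:
        """Densified spline curves per grader, keyed by (scan_id, side)."""
        out: Dict[str, Dict[Tuple[str, str], Curve3D]] = {}
        for (g, scan, side), ann in self.annotations.items():
            out.setdefault(g, {})[(scan, side)] = spline_densify(ann, step=step)
        return out


def default_annotator_models(n: int = 4) -> List[AnnotatorModel]:
    """Four experts with mildly different habits (systematic offset scale)."""
    scales = [1.25, 1.1, 0.95, 0.85]
    base = AnnotatorModel()
    return [base.scaled(scales[i % len(scales)]) for i in range(n)]


def generate_cohort(
    n_scans: int,
    devices: Optional[Sequence[Tuple[str, float]]] = None,
    annotator_models: Optional[Sequence[AnnotatorModel]] = None,
    system_model: Union[SystemModel, AnnotatorModel, None] = None,
    seed: int = 0,
    base_spec: Optional[PhantomSpec] = None,
    system_mode: str = "curve",
    device_system_scale: Optional[Dict[str, float]] = None,
    unclear_rate: float = 0.15,
    flag_rates: Optional[Dict[str, float]] = None,
) -> Cohort:
    """Generate a full synthetic study cohort.

    Per scan: one ground-truth canal pair (with per-scan anatomy variation),
    four expert annotations per canal, and one system output — either a
    noisy curve per canal ("curve" mode, ``system_model`` an
    :class:`AnnotatorModel`) or one defective label volume per scan
    ("volume" mode, ``system_model`` a :class:`SystemModel`).  Device labels
    follow the given proportions; Unclear canals get 1.5x annotator noise.
    Everything regenerates bit-identically from the same seed.
    """
    if devices is None:
        devices = [(d, 1.0 / len(DEVICES)) for d in DEVICES]
    props = np.array([p for _, p in devices], dtype=float)
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("device proportions must sum to 1")
    if system_mode not in ("curve", "volume"):
        raise ValueError("system_mode must be 'curve' or 'volume'")
    if annotator_models is None:
        annotator_models = default_annotator_models()
    if system_model is None:
        system_model = AnnotatorModel() if system_mode == "curve" else SystemModel()
    if system_mode == "curve" and not isinstance(system_model, AnnotatorModel):
        raise TypeError("curve mode needs an AnnotatorModel for the system")
    if system_mode == "volume" and not isinstance(system_model, SystemModel):
        raise TypeError("volume mode needs a SystemModel for the system")
    base_spec = base_spec or PhantomSpec()
    flag_rates = dict(flag_rates or {
        "movement_artefact": 0.08, "metal_artefact": 0.15, "bisagittal_osteotomy": 0.02,
        "difficult_bone_structure": 0.10, "difficult_pathology": 0.05,
    })
    device_system_scale = dict(device_system_scale or {})

    # device assignment: largest-remainder rounding of the proportions
    counts = np.floor(props * n_scans).astype(int)
    rem = n_scans - counts.sum()
    order = np.argsort(-(props * n_scans - counts))
    for i in range(rem):
        counts[order[i % len(counts)]] += 1
    device_of: List[str] = []
    for (name, _), c in zip(devices, counts):
        device_of.extend([name] * int(c))

    root = np.random.SeedSequence(seed)
    scan_seeds = root.spawn(n_scans)
    records: List[ScanRecord] = []
    ground_truth: Dict[Tuple[str, str], Curve3D] = {}
    annotations: Dict[Tuple[str, str, str], ControlPointAnnotation] = {}
    system_curves: Dict[Tuple[str, str], Optional[Curve3D]] = {}
    system_volumes: Dict[str, LabelVolume] = {}
    grid_specs: Dict[str, GridSpec] = {}
    n_experts = len(annotator_models)

    for i in range(n_scans):
        scan_id = f"scan{i:04d}"
        device = device_of[i]
        ss = scan_seeds[i]
        # sub-seeds: geometry, metadata, per-expert x sides, system
        subs = ss.spawn(4)
        geo_rng = np.random.default_rng(subs[0])
        meta_rng = np.random.default_rng(subs[1])
        spec = replace(
            base_spec,
            arch_width_mm=base_spec.arch_width_mm * geo_rng.uniform(0.95, 1.05),
            arch_depth_mm=base_spec.arch_depth_mm * geo_rng.uniform(0.95, 1.05),
            canal_dip_mm=base_spec.canal_dip_mm * geo_rng.uniform(0.9, 1.1),
        )
        left, right = generate_ground_truth(spec, subs[0].spawn(1)[0])
        ground_truth[(scan_id, "left")] = left
        ground_truth[(scan_id, "right")] = right
        grid_specs[scan_id] = spec.grid_spec()
        clarity = {
            s: ("Unclear" if meta_rng.random() < unclear_rate else "Clear")
            for s in ("left", "right")
        }
        flags = {f: bool(meta_rng.random() < r) for f, r in flag_rates.items()}
        records.append(
            ScanRecord(scan_id=scan_id, device=device, site="synthetic",
                       clarity=clarity, flags=flags)
        )
        ann_seeds = subs[2].spawn(n_experts * 2)
        for e, model in enumerate(annotator_models):
            gid = f"expert{e + 1}"
            for k, (side, gt) in enumerate((("left", left), ("right", right))):
                m = model.scaled(1.5) if clarity[side] == "Unclear" else model
                annotations[(gid, scan_id, side)] = simulate_annotation(
                    gt, m, ann_seeds[e * 2 + k], grader_id=gid, scan_id=scan_id,
                    clarity=clarity[side],
                )
        sys_scale = device_system_scale.get(device, 1.0)
        if system_mode == "curve":
            sys_seeds = subs[3].spawn(2)
            model = system_model.scaled(sys_scale)
            for k, (side, gt) in enumerate((("left", left), ("right", right))):
                ann = simulate_annotation(gt, model, sys_seeds[k], grader_id="system",
                                          scan_id=scan_id, clarity=clarity[side])
                system_curves[(scan_id, side)] = spline_densify(ann, step=0.5)
        else:
            model = replace(
                system_model,
                boundary_flip_prob=min(1.0, system_model.boundary_flip_prob * sys_scale),
                gap_rate=min(1.0, system_model.gap_rate * sys_scale),
            )
            system_volumes[scan_id] = simulate_system_volume(
                (left, right), model, grid_specs[scan_id], subs[3]
            )

    manifest = {
        "seed": int(seed),
        "n_scans": int(n_scans),
        "n_experts": n_experts,
        "system_mode": system_mode,
        "devices": [[d, float(p)] for d, p in devices],
        "device_system_scale": device_system_scale,
        "unclear_rate": unclear_rate,
        "flag_rates": flag_rates,
        "base_spec": {k: getattr(base_spec, k) for k in base_spec.__dataclass_fields__},
        "annotator_models": [
            {k: getattr(m, k) for k in m.__dataclass_fields__} for m in annotator_models
        ],
        "system_model": {k: getattr(system_model, k) for k in system_model.__dataclass_fields__},
    }
    return Cohort(records, ground_truth, annotations, system_curves,
                  system_volumes, grid_specs, manifest)
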