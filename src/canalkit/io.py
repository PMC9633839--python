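"""Volume, curve and cohort I/O plus resampling.

Volumes are NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd) via SimpleITK; the
in-memory grid is indexed [i, j, k] along world x, y, z (SimpleITK's own
index order), with spacing/origin round-tripped exactly.  Curves are stored
as JSON in world millimetres, never voxel indices, so they are independent
of any particular grid.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import SimpleITK as sitk

from .consensus import GridSpec
from .synthetic import Cohort
from .types import (
    HETEROGENEITY_FLAGS,
    ControlPointAnnotation,
    Curve3D,
    LabelVolume,
    ScanRecord,
)

VOLUME_SUFFIXES = (".nii", ".nii.gz", ".mha", ".mhd")


def _check_suffix(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(s) for s in VOLUME_SUFFIXES):
        raise ValueError(f"unsupported volume format: {path.name} (use NIfTI or MetaImage)")


def read_volume(
    path: Union[str, Path],
    resample_to: Optional[float] = None,
    anisotropy_tol: float = 1e-3,
) -> LabelVolume:
    """Read a binary label volume.

    Anisotropic files are an error unless ``resample_to`` gives a target
    isotropic spacing, in which case the volume is resampled on read.
    """
    path = Path(path)
    _check_suffix(path)
    img = sitk.ReadImage(str(path))
    spacing = np.array(img.GetSpacing(), dtype=float)  # (x, y, z)
    origin = np.array(img.GetOrigin(), dtype=float)
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    grid = np.transpose(arr, (2, 1, 0)) != 0
    vol = LabelVolume(grid, spacing, origin)
    if not np.allclose(spacing, spacing[0], rtol=anisotropy_tol):
        if resample_to is None:
            raise ValueError(
                f"anisotropic spacing {spacing} in {path.name}; pass resample_to "
                "(e.g. 0.4) to resample on read"
            )
        vol = resample_isotropic(vol, target=resample_to)
    elif resample_to is not None and not np.allclose(spacing, resample_to, rtol=1e-6):
        vol = resample_isotropic(vol, target=resample_to)
    return vol


def write_volume(volume: LabelVolume, path: Union[str, Path]) -> Path:
    """Write a binary volume as NIfTI or MetaImage, preserving spacing/origin."""
    path = Path(path)
    _check_suffix(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.transpose(volume.grid.astype(np.uint8), (2, 1, 0))
    img = sitk.GetImageFromArray(arr)
    img.SetSpacing(tuple(volume.spacing))
    img.SetOrigin(tuple(volume.origin))
    sitk.WriteImage(img, str(path))
    return path


def resample_isotropic(volume: LabelVolume, target: float = 0.4) -> LabelVolume:
    """Resample a label volume to isotropic spacing by linear interpolation.

    The binary field is interpolated linearly and re-thresholded at 0.5; the
    world extent is preserved to within one voxel.  A volume already at the
    target spacing is returned unchanged (voxelwise identity).
    """
    if target <= 0:
        raise ValueError("target spacing must be positive")
    if np.allclose(volume.spacing, target, rtol=1e-6):
        return volume.copy()
    img = sitk.GetImageFromArray(
        np.transpose(volume.grid.astype(np.float32), (2, 1, 0))
    )
    img.SetSpacing(tuple(volume.spacing))
    img.SetOrigin(tuple(volume.origin))
    old_size = np.array(volume.shape)
    extent = (old_size - 1) * volume.spacing
    # stay inside the original world extent so no sample needs padding
    new_size = np.maximum(np.floor(extent / target + 1e-9).astype(int) + 1, 1)
    res = sitk.Resample(
        img,
        [int(s) for s in new_size],
        sitk.Transform(),
        sitk.sitkLinear,
        img.GetOrigin(),
        (target, target, target),
        img.GetDirection(),
        0.0,
        sitk.sitkFloat32,
    )
    grid = np.transpose(sitk.GetArrayFromImage(res), (2, 1, 0)) >= 0.5
    return LabelVolume(grid, np.full(3, float(target)), volume.origin.copy())


# ---------------------------------------------------------------------------
# Curve / annotation JSON


def curve_to_dict(curve: Curve3D, scan_id: str = "", grader_id: str = "",
                  clarity: str = "Clear") -> Dict:
    return {
        "scan_id": scan_id,
        "grader_id": grader_id,
        "side": curve.label,
        "clarity": clarity,
        "points": [[float(v) for v in p] for p in curve.points],
    }


def write_curve(curve: Curve3D, path: Union[str, Path], **meta) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(curve_to_dict(curve, **meta), indent=1))
    return path


def read_curve(path: Union[str, Path]) -> Tuple[Curve3D, Dict]:
    d = json.loads(Path(path).read_text())
    curve = Curve3D(np.array(d["points"], dtype=float), label=d.get("side"))
    return curve, d


def write_annotation(ann: ControlPointAnnotation, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "scan_id": ann.scan_id,
        "grader_id": ann.grader_id,
        "side": ann.side,
        "clarity": ann.clarity,
        "points": [[float(v) for v in p] for p in ann.control_points],
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_annotation(path: Union[str, Path]) -> ControlPointAnnotation:
    d = json.loads(Path(path).read_text())
    return ControlPointAnnotation(
        np.array(d["points"], dtype=float),
        grader_id=d.get("grader_id", ""),
        scan_id=d.get("scan_id", ""),
        side=d.get("side", "left"),
        clarity=d.get("clarity", "Clear"),
    )


def points_to_csv(points: np.ndarray, path: Union[str, Path]) -> Path:
    """CSV alternative: one point per row with an x,y,z header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(points, columns=["x_mm", "y_mm", "z_mm"]).to_csv(path, index=False)
    return path


def points_from_csv(path: Union[str, Path]) -> np.ndarray:
    return pd.read_csv(path)[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Scan records


def records_to_frame(records: Sequence[ScanRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"scan_id": r.scan_id, "device": r.device, "site": r.site,
               "clarity_left": r.clarity.get("left", "Clear"),
               "clarity_right": r.clarity.get("right", "Clear")}
        for f in HETEROGENEITY_FLAGS:
            row[f] = bool(r.flags.get(f, False))
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(df: pd.DataFrame) -> List[ScanRecord]:
    out = []
    for _, row in df.iterrows():
        out.append(
            ScanRecord(
                scan_id=str(row["scan_id"]),
                device=str(row["device"]),
                site=str(row.get("site", "")),
                clarity={"left": row["clarity_left"], "right": row["clarity_right"]},
                flags={f: bool(row[f]) for f in HETEROGENEITY_FLAGS if f in row},
            )
        )
    return out


def write_records(records: Sequence[ScanRecord], path: Union[str, Path]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records_to_frame(records).to_csv(path, index=False)
    return path


def read_records(path: Union[str, Path]) -> List[ScanRecord]:
    return frame_to_records(pd.read_csv(path))


# ---------------------------------------------------------------------------
# Cohort directory tree


def write_cohort(cohort: Cohort, out_dir: Union[str, Path],
                 volume_format: str = ".nii.gz") -> Path:
    """Write a cohort as a directory tree.

    manifest.json, records.csv, ground_truth/ and annotations/ as curve
    JSON, and the system output under system/ as curve JSON or volumes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "manifest.json").write_text(json.dumps(cohort.manifest, indent=1, sort_keys=True))
    write_records(cohort.records, out / "records.csv")
    for (scan, side), curve in sorted(cohort.ground_truth.items()):
        write_curve(curve, out / "ground_truth" / f"{scan}_{side}.json",
                    scan_id=scan, grader_id="truth")
    for (g, scan, side), ann in sorted(cohort.annotations.items()):
        write_annotation(ann, out / "annotations" / f"{g}_{scan}_{side}.json")
    for (scan, side), curve in sorted(cohort.system_curves.items()):
        if curve is not None:
            write_curve(curve, out / "system" / "curves" / f"{scan}_{side}.json",
                        scan_id=scan, grader_id="system")
    for scan, vol in sorted(cohort.system_volumes.items()):
        write_volume(vol, out / "system" / "volumes" / f"{scan}{volume_format}")
    gspec = {
        scan: {"shape": list(gs.shape), "spacing": gs.spacing, "origin": list(gs.origin)}
        for scan, gs in cohort.grid_specs.items()
    }
    (out / "grid_specs.json").write_text(json.dumps(gspec, indent=1, sort_keys=True))
    return out


def read_cohort(in_dir: Union[str, Path]) -> Cohort:
    """Load a cohort directory written by :func:`write_cohort`."""
    root = Path(in_dir)
    manifest = json.loads((root / "manifest.json").read_text())
    records = read_records(root / "records.csv")
    ground_truth = {}
    for p in sorted((root / "ground_truth").glob("*.json")):
        curve, d = read_curve(p)
        ground_truth[(d["scan_id"], d["side"])] = curve
    annotations = {}
    for p in sorted((root / "annotations").glob("*.json")):
        ann = read_annotation(p)
        annotations[(ann.grader_id, ann.scan_id, ann.side)] = ann
    system_curves = {}
    cdir = root / "system" / "curves"
    if cdir.is_dir():
        for p in sorted(cdir.glob("*.json")):
            curve, d = read_curve(p)
            system_curves[(d["scan_id"], d["side"])] = curve
    system_volumes = {}
    vdir = root / "system" / "volumes"
    if vdir.is_dir():
        for p in sorted(vdir.iterdir()):
            if p.name.lower().endswith(VOLUME_SUFFIXES):
                scan = p.name.split(".")[0]
                system_volumes[scan] = read_volume(p)
    grid_specs = {}
    gpath = root / "grid_specs.json"
    if gpath.exists():
        for scan, d in json.loads(gpath.read_text()).items():
            grid_specs[scan] = GridSpec(tuple(d["shape"]), float(d["spacing"]),
                                        tuple(d["origin"]))
    return Cohort(records, ground_truth, annotations, system_curves,
                  system_volumes, grid_specs, manifest)
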