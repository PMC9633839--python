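"""End-to-end orchestration: extract → harmonize → metrics → consensus →
variability → stratified reports.

``run_pipeline`` takes a cohort (in memory or on disk), produces tidy CSV
tables and a JSON run log in a fresh output directory, and never mutates its
inputs.  Per-canal failures (e.g. a system volume from which no canal could
be extracted) are logged and counted, and the run continues.  Reruns with
the same inputs and configuration are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd

from . import io as ckio
from .consensus import DEFAULT_DIAMETER_MM, build_consensus
from .curve_metrics import (
    harmonize_endpoints,
    positional_profile,
    spline_densify,
    symmetric_mean_curve_distance,
)
from .extraction import ExtractionConfig, extract_canals
from .synthetic import Cohort
from .types import Curve3D
from .variability import (
    ALPHA,
    pairwise_matrix,
    stratified_comparison,
    variability_table,
)

FLOAT_FMT = "%.6g"


@dataclass
class PipelineConfig:
    """Everything a pipeline run depends on; serialized next to its outputs."""

    out_dir: str = "results"
    cohort_dir: Optional[str] = None  # load cohort from disk when given
    seed: int = 0
    alpha: float = ALPHA
    densify_step_mm: float = 0.5
    margin_mm: float = 2.0
    harmonize: str = "all"  # all | experts | off
    rasterize_diameter_mm: float = DEFAULT_DIAMETER_MM
    voxel_spacing_mm: float = 0.4
    stratify_by: Tuple[str, ...] = ("device",)
    run_consensus: bool = True
    profile_points: int = 200
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)

    def to_dict(self) -> Dict:
        d = asdict(self)
        d["stratify_by"] = list(self.stratify_by)
        return d


@dataclass
class PipelineResult:
    out_dir: Path
    table: pd.DataFrame
    strata: Dict[str, pd.DataFrame]
    pairwise_mcd: pd.DataFrame
    pairwise_margin: pd.DataFrame
    consensus: Optional[pd.DataFrame]
    profiles: Optional[pd.DataFrame]
    log: Dict


def _system_curves(cohort: Cohort, cfg: PipelineConfig, log: Dict) -> Dict:
    """System curve per canal: stored curves, or extraction from volumes."""
    out: Dict[Tuple[str, str], Optional[Curve3D]] = {}
    if cohort.system_curves:
        out.update(cohort.system_curves)
    for scan, vol in cohort.system_volumes.items():
        pair = extract_canals(vol, cfg.extraction)
        for side in ("left", "right"):
            out[(scan, side)] = pair.curves.get(side)
        log["extraction_status"][scan] = pair.status
    return out


def run_pipeline(
    config: PipelineConfig,
    cohort: Optional[Cohort] = None,
) -> PipelineResult:
    """Run the complete variability study and write its report bundle."""
    cfg = config
    if cohort is None:
        if cfg.cohort_dir is None:
            raise ValueError("need a cohort (in memory or via cohort_dir)")
        cohort = ckio.read_cohort(cfg.cohort_dir)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: Dict = {"extraction_status": {}, "failures": []}

    expert_curves = cohort.expert_curves(step=cfg.densify_step_mm)
    experts = sorted(expert_curves)
    system_curves = _system_curves(cohort, cfg, log)

    canals = sorted(set.intersection(*[set(expert_curves[e]) for e in experts]))
    # endpoint harmonization per canal
    if cfg.harmonize != "off":
        for key in canals:
            curves = [expert_curves[e][key] for e in experts]
            include_system = cfg.harmonize == "all" and system_curves.get(key) is not None
            if include_system:
                curves.append(system_curves[key])
            fixed = harmonize_endpoints(curves)
            for e, c in zip(experts, fixed):
                expert_curves[e][key] = c
            if include_system:
                system_curves[key] = fixed[-1]

    n_missing = sum(1 for key in canals if system_curves.get(key) is None)
    for key in canals:
        if system_curves.get(key) is None:
            log["failures"].append({"scan_id": key[0], "side": key[1],
                                    "stage": "system_extraction"})
    log["n_canals"] = len(canals)
    log["n_system_missing"] = n_missing
    log["n_system_ok"] = len(canals) - n_missing

    table = variability_table(expert_curves, system_curves)
    table.to_csv(out / "variability.csv", index=False, float_format=FLOAT_FMT)

    all_curves = dict(expert_curves)
    all_curves["system"] = {k: v for k, v in system_curves.items() if v is not None}
    pm = pairwise_matrix(all_curves, metric="mcd")
    pg = pairwise_matrix(all_curves, metric="margin", margin_mm=cfg.margin_mm)
    pm.formatted().to_csv(out / "pairwise_mcd.csv", index_label="ground_truth")
    pg.formatted().to_csv(out / "pairwise_margin.csv", index_label="ground_truth")

    strata: Dict[str, pd.DataFrame] = {}
    for by in cfg.stratify_by:
        key = _strata_key(by)
        df = stratified_comparison(table, cohort.records, by=key, alpha=cfg.alpha)
        df.insert(0, "stratified_by", by)
        df.to_csv(out / f"strata_{by}.csv", index=False, float_format=FLOAT_FMT)
        strata[by] = df

    consensus_df = profiles_df = None
    if cfg.run_consensus:
        consensus_df, profiles_df = _consensus_report(
            cohort, expert_curves, system_curves, canals, cfg, log
        )
        consensus_df.to_csv(out / "consensus.csv", index=False, float_format=FLOAT_FMT)
        profiles_df.to_csv(out / "profiles.csv", index=False, float_format=FLOAT_FMT)

    resolved = cfg.to_dict()
    resolved["quantile_rule"] = "linear interpolation"
    resolved["rasterize_diameter_mm"] = cfg.rasterize_diameter_mm
    (out / "resolved_config.json").write_text(json.dumps(resolved, indent=1, sort_keys=True))
    (out / "run_log.json").write_text(json.dumps(log, indent=1, sort_keys=True))
    return PipelineResult(out, table, strata, pm.formatted(), pg.formatted(),
                          consensus_df, profiles_df, log)


def _strata_key(by: str) -> str:
    aliases = {"clarity": "clarity", "device": "device"}
    return aliases.get(by, by)


def _local_grid(curves, spacing: float, diameter: float):
    """Canal-local grid tightly enclosing the grader curves plus the tube."""
    from .consensus import GridSpec

    pts = np.vstack([c.points for c in curves])
    margin = diameter / 2.0 + 1.0
    lo = pts.min(axis=0) - margin
    hi = pts.max(axis=0) + margin
    shape = tuple(int(np.ceil((hi[a] - lo[a]) / spacing)) + 1 for a in range(3))
    return GridSpec(shape=shape, spacing=spacing, origin=tuple(lo))


def _consensus_report(cohort, expert_curves, system_curves, canals, cfg, log):
    """Per-assessor SMCD to the majority-vote reference, plus positional profiles."""
    experts = sorted(expert_curves)
    rows = []
    prof_acc: Dict[Tuple[str, str], List[np.ndarray]] = {}
    n_ref_missing = 0
    for key in canals:
        scan, side = key
        curves = [expert_curves[e][key] for e in experts]
        gs = _local_grid(curves, cfg.voxel_spacing_mm, cfg.rasterize_diameter_mm)
        mask, ref = build_consensus(curves, gs, diameter=cfg.rasterize_diameter_mm)
        ref_curve = ref.get(side) or next(
            (c for c in ref.values() if c is not None), None
        )
        if ref_curve is None:
            n_ref_missing += 1
            log["failures"].append({"scan_id": scan, "side": side,
                                    "stage": "consensus_reference"})
            continue
        assessors = list(experts)
        if system_curves.get(key) is not None:
            assessors.append("system")
        for a in assessors:
            curve = system_curves[key] if a == "system" else expert_curves[a][key]
            rows.append({
                "scan_id": scan, "side": side, "assessor": a,
                "smcd_mm": symmetric_mean_curve_distance(curve, ref_curve),
            })
            prof = positional_profile(curve, ref_curve, n=cfg.profile_points)
            prof_acc.setdefault((a, side), []).append(prof.distance)
    log["n_reference_missing"] = n_ref_missing
    prof_rows = []
    for (a, side), stack in sorted(prof_acc.items()):
        mean_d = np.mean(np.stack(stack), axis=0)
        pos = np.linspace(0.0, 1.0, cfg.profile_points)
        for p, d in zip(pos, mean_d):
            prof_rows.append({"assessor": a, "side": side, "position": p,
                              "mean_distance_mm": d})
    return pd.DataFrame(rows), pd.DataFrame(prof_rows)
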