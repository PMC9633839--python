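"""Pairwise comparison machinery and paired statistics.

The study design: four experts annotate every canal and an automatic system
segments it.  Per canal, the *highest interobserver variability* (IV) is the
SMCD of the expert pair with the highest mean curve distance, and the
*highest system variability* (DV) is the SMCD between the system and the
expert with the highest MCD to it.  IV and DV are compared per canal with a
two-tailed Wilcoxon signed-rank test at alpha = 0.001, overall and within
strata (device, clarity, condition flags).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .curve_metrics import (
    mean_curve_distance,
    symmetric_mean_curve_distance,
    within_margin_proportion,
)
from .types import Curve3D, ScanRecord

ALPHA = 0.001
#: exact enumeration is used up to this sample size
EXACT_N_MAX = 25


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W+ (sum of positive ranks)
    p_value: float
    n_used: int  # pairs after zero-difference removal
    n_zero: int
    method: str  # "exact" | "approx" | "degenerate"
    alpha: float = ALPHA

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-tailed exact p over all 2^n equally likely sign assignments.

    Computed by dynamic programming on the distribution of W+ (ranks are
    midranks, so everything is doubled to stay integer); identical to full
    enumeration but O(n * total_rank) instead of O(2^n).
    """
    r2 = np.round(ranks * 2).astype(int)
    total = int(r2.sum())
    # dist[w] = number of sign assignments with doubled W+ == w
    dist = np.zeros(total + 1, dtype=float)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    n_total = dist.sum()
    w2 = int(round(w_plus * 2))
    p_le = dist[: w2 + 1].sum() / n_total
    p_ge = dist[w2:].sum() / n_total
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(
    a: Sequence[float],
    b: Optional[Sequence[float]] = None,
    alpha: float = ALPHA,
) -> WilcoxonResult:
    """Two-tailed Wilcoxon signed-rank test on paired samples.

    Differences ``a - b`` (or ``a`` directly when ``b`` is None) are ranked
    by absolute value after dropping zero differences.  Exact enumeration of
    the sign-assignment distribution is used for n <= 25 (valid with tied
    ranks); larger samples use the normal approximation with tie correction.
    """
    a = np.asarray(a, dtype=float)
    d = a if b is None else a - np.asarray(b, dtype=float)
    if b is not None and len(a) != len(d):
        raise ValueError("paired samples must have equal length")
    nz = d[d != 0.0]
    n_zero = int(len(d) - len(nz))
    if len(nz) == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return WilcoxonResult(0.0, 1.0, 0, n_zero, "degenerate", alpha)
    if len(nz) < 5:
        raise ValueError(
            f"need >= 5 nonzero differences for the signed-rank test, got {len(nz)}"
        )
    ranks = stats.rankdata(np.abs(nz))  # midranks for ties
    w_plus = float(ranks[nz > 0].sum())
    if len(nz) <= EXACT_N_MAX:
        p = _exact_signed_rank_p(ranks, w_plus)
        method = "exact"
    else:
        res = stats.wilcoxon(
            nz, zero_method="wilcox", alternative="two-sided", method="approx",
            correction=False,
        )
        p = float(res.pvalue)
        method = "approx"
    return WilcoxonResult(w_plus, p, len(nz), n_zero, method, alpha)


# ---------------------------------------------------------------------------
# Summaries


def summarize(values: Sequence[float]) -> Dict[str, float]:
    """median, IQR (linear-interpolation quantiles), mean, SD (n-1) and n."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty sample")
    q1, q3 = np.quantile(v, [0.25, 0.75])  # linear interpolation
    return {
        "median": float(np.median(v)),
        "iqr": float(q3 - q1),
        "mean": float(np.mean(v)),
        "sd": float(np.std(v, ddof=1)) if v.size > 1 else 0.0,
        "n": int(v.size),
    }


def format_median_iqr(s: Dict[str, float], nd: int = 2) -> str:
    return f"{s['median']:.{nd}f} [{s['iqr']:.{nd}f}]"


def format_mean_sd(s: Dict[str, float], nd: int = 2) -> str:
    return f"{s['mean']:.{nd}f} ({s['sd']:.{nd}f})"


# ---------------------------------------------------------------------------
# Pairwise comparison matrices


@dataclass
class PairwiseMatrices:
    """Directed assessor-vs-assessor summaries.

    Rows are the assessor used as ground truth, columns the estimator; the
    MCD is asymmetric so the matrices are asymmetric by construction.
    """

    metric: str  # "mcd" | "margin"
    central: pd.DataFrame  # median (mcd) or mean (margin)
    spread: pd.DataFrame  # IQR (mcd) or SD (margin)
    n: pd.DataFrame  # canals contributing to each cell

    def formatted(self, nd: int = 2) -> pd.DataFrame:
        out = self.central.copy().astype(object)
        for r in out.index:
            for c in out.columns:
                if self.metric == "mcd":
                    out.loc[r, c] = f"{self.central.loc[r, c]:.{nd}f} [{self.spread.loc[r, c]:.{nd}f}]"
                else:
                    out.loc[r, c] = f"{self.central.loc[r, c]:.{nd}f} ({self.spread.loc[r, c]:.{nd}f})"
        return out


CurvesByCanal = Dict[object, Curve3D]  # canal key -> curve


def pairwise_matrix(
    curves: Dict[str, CurvesByCanal],
    metric: str = "mcd",
    margin_mm: float = 2.0,
) -> PairwiseMatrices:
    """Pairwise directed comparison of assessors over their common canals.

    ``curves`` maps assessor name -> {canal key -> Curve3D}.  For each
    ordered pair (ground truth row, estimator column) the per-canal metric is
    summarized as median/IQR (MCD, mm) or mean/SD (2 mm within-margin
    proportion).  Diagonal cells are exactly 0 (MCD) or 1 (margin).  Canals
    missing a curve for either assessor are excluded from that cell, with the
    contributing count reported.
    """
    if metric not in ("mcd", "margin"):
        raise ValueError("metric must be 'mcd' or 'margin'")
    names = list(curves)
    if len(names) < 2:
        raise ValueError("need at least 2 assessors")
    central = pd.DataFrame(index=names, columns=names, dtype=float)
    spread = pd.DataFrame(index=names, columns=names, dtype=float)
    counts = pd.DataFrame(index=names, columns=names, dtype=int)
    for gt in names:
        for est in names:
            if gt == est:
                central.loc[gt, est] = 0.0 if metric == "mcd" else 1.0
                spread.loc[gt, est] = 0.0
                counts.loc[gt, est] = len(curves[gt])
                continue
            common = [k for k in curves[gt] if k in curves[est]]
            vals = []
            for k in common:
                if metric == "mcd":
                    vals.append(mean_curve_distance(curves[gt][k], curves[est][k]))
                else:
                    vals.append(
                        within_margin_proportion(curves[gt][k], curves[est][k], margin_mm)
                    )
            counts.loc[gt, est] = len(vals)
            if not vals:
                central.loc[gt, est] = np.nan
                spread.loc[gt, est] = np.nan
                continue
            s = summarize(vals)
            if metric == "mcd":
                central.loc[gt, est] = s["median"]
                spread.loc[gt, est] = s["iqr"]
            else:
                central.loc[gt, est] = s["mean"]
                spread.loc[gt, est] = s["sd"]
    return PairwiseMatrices(metric, central, spread, counts)


# ---------------------------------------------------------------------------
# Highest-variability selection


def highest_interobserver(
    expert_curves: Dict[str, Curve3D],
) -> Tuple[Tuple[str, str], float]:
    """Expert pair with the highest mean curve distance for one canal.

    The MCD is asymmetric while the pair is unordered, so "highest MCD" is
    resolved as maximizing the larger of the two directed MCDs.  The
    returned value is that pair's SMCD.  Ties go to the lexicographically
    first pair for determinism.
    """
    names = list(expert_curves)
    if len(names) < 2:
        raise ValueError("need at least 2 experts")
    best_pair = None
    best_crit = -np.inf
    for a, b in combinations(names, 2):
        ab = mean_curve_distance(expert_curves[a], expert_curves[b])
        ba = mean_curve_distance(expert_curves[b], expert_curves[a])
        crit = max(ab, ba)
        if crit > best_crit + 1e-15:
            best_crit = crit
            best_pair = (a, b)
    smcd = symmetric_mean_curve_distance(
        expert_curves[best_pair[0]], expert_curves[best_pair[1]]
    )
    return best_pair, smcd


def highest_system_variability(
    expert_curves: Dict[str, Curve3D],
    system_curve: Optional[Curve3D],
) -> Tuple[str, float]:
    """Expert with the highest MCD to the system curve, and that SMCD.

    The expert annotation is treated as the ground truth curve and the
    automatic segmentation as the estimator.  A missing system curve (failed
    extraction) raises so the caller can count the exclusion explicitly.
    """
    if system_curve is None:
        raise ValueError("system curve absent (extraction failed)")
    if len(expert_curves) < 1:
        raise ValueError("need at least 1 expert")
    names = list(expert_curves)
    crit = [mean_curve_distance(expert_curves[e], system_curve) for e in names]
    best = names[int(np.argmax(crit))]
    return best, symmetric_mean_curve_distance(expert_curves[best], system_curve)


# ---------------------------------------------------------------------------
# Variability table and stratified comparison


def variability_table(
    expert_curves: Dict[str, Dict[object, Curve3D]],
    system_curves: Dict[object, Optional[Curve3D]],
) -> pd.DataFrame:
    """One IV and one DV row per canal: the study's paired comparison table.

    Canal keys are (scan_id, side).  Canals whose system curve is absent get
    only the IV row plus a ``system_missing`` marker so failures are counted,
    never silently dropped.
    """
    experts = list(expert_curves)
    canals = sorted(
        set.intersection(*[set(expert_curves[e]) for e in experts]),
        key=str,
    )
    rows = []
    for key in canals:
        scan_id, side = key
        per_expert = {e: expert_curves[e][key] for e in experts}
        pair, iv = highest_interobserver(per_expert)
        rows.append(
            {"scan_id": scan_id, "side": side, "kind": "IV", "value_mm": iv,
             "pair": f"{pair[0]}|{pair[1]}", "system_missing": False}
        )
        sys_curve = system_curves.get(key)
        if sys_curve is None:
            rows.append(
                {"scan_id": scan_id, "side": side, "kind": "DV", "value_mm": np.nan,
                 "pair": "", "system_missing": True}
            )
        else:
            expert, dv = highest_system_variability(per_expert, sys_curve)
            rows.append(
                {"scan_id": scan_id, "side": side, "kind": "DV", "value_mm": dv,
                 "pair": f"{expert}|system", "system_missing": False}
            )
    return pd.DataFrame(rows)


def _records_frame(records: Union[pd.DataFrame, Sequence[ScanRecord]]) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    rows = []
    for r in records:
        for side in ("left", "right"):
            row = {"scan_id": r.scan_id, "side": side, "device": r.device,
                   "site": r.site, "clarity": r.clarity.get(side, "Clear")}
            row.update(r.flags)
            rows.append(row)
    return pd.DataFrame(rows)


def iv_dv_pairs(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot the tidy table to one row per canal with IV and DV columns."""
    wide = table.pivot_table(
        index=["scan_id", "side"], columns="kind", values="value_mm", aggfunc="first"
    ).reset_index()
    return wide.dropna(subset=["IV", "DV"])


def stratified_comparison(
    table: pd.DataFrame,
    records: Union[pd.DataFrame, Sequence[ScanRecord]],
    by: Optional[str] = None,
    alpha: float = ALPHA,
    min_pairs: int = 5,
) -> pd.DataFrame:
    """IV vs DV summaries and paired Wilcoxon test, overall and per stratum.

    ``by`` is a record column ("device", "clarity" or a condition flag).
    Strata with fewer than ``min_pairs`` complete IV/DV pairs are reported
    without a test and flagged.  The overall row is always included.
    """
    rec = _records_frame(records)
    wide = iv_dv_pairs(table).merge(rec, on=["scan_id", "side"], how="left", validate="one_to_one")
    groups: List[Tuple[str, pd.DataFrame]] = [("overall", wide)]
    if by is not None:
        if by not in wide.columns:
            raise KeyError(f"no such stratification column: {by!r}")
        for name, g in wide.groupby(by, sort=True):
            if len(g) == 0:
                continue
            groups.append((str(name), g))
    rows = []
    for name, g in groups:
        iv_s = summarize(g["IV"]) if len(g) else None
        dv_s = summarize(g["DV"]) if len(g) else None
        row = {"stratum": name, "n_pairs": len(g)}
        for tag, s in (("iv", iv_s), ("dv", dv_s)):
            for stat in ("median", "iqr", "mean", "sd"):
                row[f"{tag}_{stat}"] = s[stat] if s else np.nan
        if len(g) >= min_pairs:
            try:
                res = wilcoxon_signed_rank(g["IV"].to_numpy(), g["DV"].to_numpy(), alpha=alpha)
                row.update(p_value=res.p_value, significant=res.significant,
                           tested=True, test_note=res.method)
            except ValueError as exc:  # e.g. too many zero differences
                row.update(p_value=np.nan, significant=False, tested=False,
                           test_note=str(exc))
        else:
            row.update(p_value=np.nan, significant=False, tested=False,
                       test_note=f"fewer than {min_pairs} pairs")
        rows.append(row)
    return pd.DataFrame(rows)
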