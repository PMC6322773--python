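"""End-to-end virtual weight-estimation study on a cohort table.

The cohort is a pandas DataFrame with columns
``id, country, year, region, sex, age_months, weight_kg, height_cm, mac_cm``
and optionally pre-computed survey z-scores ``waz, haz, whz, baz``.  The
pipeline derives anthropometric indicators, applies every requested tape
calibration, summarises accuracy overall and by subgroup, runs paired
method comparisons against a reference method, and applies the
acceptability rule (p10 >= 70% and p20 >= 95%).

Subgroup bins follow the conventional study layout: age in completed months
{6-12, 13-24, 25-36, 37-48, >48}; weight {<=10 kg, (10, 15] kg, >15 kg};
BMI-for-age five habitus grades; weight-for-height wasting grades; sex;
region.  Records that cannot be estimated by a method are excluded from that
method's summaries only, with counts reported, and comparisons are pairwise
complete-case.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from . import accuracy as acc
from .accuracy import AccuracySummary, PairedComparison
from .estimators import estimate_many
from .growth import GrowthReference, classify_many

__all__ = [
    "DEFAULT_DIMENSIONS",
    "AnalysisReport",
    "derive_indicators",
    "apply_estimators",
    "assign_bins",
    "run_subgroups",
    "compare_all",
    "evaluate_acceptability",
]

#: indicator -> (z column, axis column, measurement column)
_INDICATOR_COLUMNS = {
    "weight-for-age": ("waz", "age_months", "weight_kg"),
    "height-for-age": ("haz", "age_months", "height_cm"),
    "weight-for-height": ("whz", "height_cm", "weight_kg"),
    "bmi-for-age": ("baz", "age_months", "bmi"),
}

AGE_BIN_LABELS = ("6-12 months", "13-24 months", "25-36 months", "37-48 months", ">48 months")
WEIGHT_BIN_LABELS = ("<=10kg", "10.1-15kg", ">15kg")

DEFAULT_DIMENSIONS = ("sex", "age", "weight", "bmi_for_age_z", "weight_for_height_z", "region")


def derive_indicators(records: pd.DataFrame, reference: GrowthReference,
                      *, passthrough: bool = True):
    """Populate BMI and the four z-score columns.

    With ``passthrough`` (default) a z column already present and non-null is
    kept — matching survey practice where the distributed dataset carries its
    own z-scores — and only missing values are computed.  Records outside the
    reference grid get NaN z-scores and are counted, never dropped.

    Returns ``(records, flagged)`` where ``flagged`` maps indicator -> count
    of records that could not be scored.
    """
    out = records.copy()
    out["bmi"] = out["weight_kg"] / (out["height_cm"] / 100.0) ** 2
    flagged: dict = {}
    for indicator, (col, axis_col, value_col) in _INDICATOR_COLUMNS.items():
        have = out[col].notna() if (passthrough and col in out.columns) else pd.Series(False, index=out.index)
        z = np.full(len(out), np.nan)
        if have.any():
            z[have.to_numpy()] = out.loc[have, col].to_numpy(dtype=float)
        todo = ~have.to_numpy()
        for sex in ("male", "female"):
            m = todo & (out["sex"] == sex).to_numpy()
            if not np.any(m):
                continue
            table = reference.table(indicator, sex)
            lo, hi = table.axis_range
            axis = out.loc[m, axis_col].to_numpy(dtype=float)
            inside = (axis >= lo) & (axis <= hi)
            idx = np.flatnonzero(m)
            if np.any(inside):
                z[idx[inside]] = table.zscore(
                    axis[inside], out.loc[m, value_col].to_numpy(dtype=float)[inside]
                )
        out[col] = z
        flagged[indicator] = int(np.sum(~np.isfinite(z)))
    return out, flagged


def apply_estimators(records: pd.DataFrame, calibrations: dict):
    """Attach per-method estimate columns ``est_<method>`` / ``inrange_<method>``.

    Returns ``(records, out_of_range)`` with per-method exclusion counts.
    """
    out = records.copy()
    lengths = out["height_cm"].to_numpy(dtype=float)
    mac = out["mac_cm"].to_numpy(dtype=float)
    excluded: dict = {}
    for name, cal in calibrations.items():
        weights, ok, _, _ = estimate_many(cal, lengths, mac_cm=mac)
        out[f"est_{name}"] = weights
        out[f"inrange_{name}"] = ok
        excluded[name] = int(np.sum(~ok))
    return out, excluded


def assign_bins(records: pd.DataFrame, dimension: str) -> pd.Series:
    """Label every record on one stratification dimension.

    Unassignable records (missing z-score, unknown category) get "" and are
    reported as exclusions by :func:`run_subgroups`.
    """
    if dimension == "sex":
        return records["sex"].astype(str)
    if dimension == "region":
        r = records.get("region")
        if r is None:
            return pd.Series("unassigned", index=records.index)
        return r.fillna("unassigned").replace("", "unassigned").astype(str)
    if dimension == "age":
        age = records["age_months"].to_numpy(dtype=float)
        conds = [age <= 12, age <= 24, age <= 36, age <= 48]
        out = np.select(conds, AGE_BIN_LABELS[:4], default=AGE_BIN_LABELS[4])
        return pd.Series(out, index=records.index)
    if dimension == "weight":
        w = records["weight_kg"].to_numpy(dtype=float)
        out = np.select([w <= 10.0, w <= 15.0], WEIGHT_BIN_LABELS[:2], default=WEIGHT_BIN_LABELS[2])
        return pd.Series(out, index=records.index)
    if dimension == "bmi_for_age_z":
        return pd.Series(classify_many(records["baz"].to_numpy(dtype=float), "bmi_for_age_5bin"),
                         index=records.index)
    if dimension == "weight_for_height_z":
        return pd.Series(classify_many(records["whz"].to_numpy(dtype=float), "wfh_3bin"),
                         index=records.index)
    raise KeyError(f"unknown subgroup dimension {dimension!r}")


def _bin_order(records, dimension) -> list:
    if dimension == "sex":
        return ["male", "female"]
    if dimension == "age":
        return list(AGE_BIN_LABELS)
    if dimension == "weight":
        return list(WEIGHT_BIN_LABELS)
    if dimension == "bmi_for_age_z":
        from .growth import SCHEMES
        return list(SCHEMES["bmi_for_age_5bin"])
    if dimension == "weight_for_height_z":
        from .growth import SCHEMES
        return list(SCHEMES["wfh_3bin"])
    if dimension == "region":
        seen = assign_bins(records, "region")
        return sorted(seen.unique())
    raise KeyError(dimension)


@dataclass
class AnalysisReport:
    """Overall and stratified accuracy summaries plus paired comparisons."""

    overall: dict                     # method -> AccuracySummary (or None if n < 2)
    cells: pd.DataFrame               # one row per (dimension, bin, method)
    acceptability: dict               # method -> bool (overall)
    exclusions: dict                  # method -> out-of-range count
    comparisons: list = field(default_factory=list)

    def comparisons_frame(self) -> pd.DataFrame:
        from dataclasses import asdict
        return pd.DataFrame([asdict(c) for c in self.comparisons])


def _pe_for(records, method):
    est = records[f"est_{method}"].to_numpy(dtype=float)
    ok = records[f"inrange_{method}"].to_numpy(dtype=bool) & np.isfinite(est)
    actual = records["weight_kg"].to_numpy(dtype=float)
    pe = np.full(len(records), np.nan)
    pe[ok] = acc.percentage_error(est[ok], actual[ok])
    return pe, ok


def _summary_or_none(pe) -> Optional[AccuracySummary]:
    return acc.summarize(pe) if pe.size >= 2 else None


def _summary_row(dimension, bin_label, method, s: Optional[AccuracySummary], n: int) -> dict:
    row = {"dimension": dimension, "bin": bin_label, "method": method, "n": n}
    if s is None:
        row.update({k: np.nan for k in
                    ("mpe", "sd", "loa_low", "loa_high", "rmspe", "rmspe_companion", "p10", "p20")})
        row["acceptable"] = False
    else:
        row.update(s.as_dict())
        row["n"] = s.n
        row["acceptable"] = evaluate_acceptability(s)
    return row


def run_subgroups(records: pd.DataFrame, methods: Iterable[str],
                  dimensions: Iterable[str] = DEFAULT_DIMENSIONS) -> AnalysisReport:
    """Accuracy summaries per method, overall and per (dimension, bin).

    Empty cells are carried with n = 0 and NaN statistics.  Each method's
    out-of-range records are excluded from that method's cells only.
    """
    methods = list(methods)
    pe_cols = {m: _pe_for(records, m) for m in methods}

    overall = {}
    acceptability = {}
    exclusions = {}
    rows = []
    for m in methods:
        pe, ok = pe_cols[m]
        s = _summary_or_none(pe[ok])
        overall[m] = s
        acceptability[m] = bool(s and evaluate_acceptability(s))
        exclusions[m] = int(np.sum(~ok))
        rows.append(_summary_row("overall", "all", m, s, int(np.sum(ok))))

    for dim in dimensions:
        labels = assign_bins(records, dim).to_numpy()
        for bin_label in _bin_order(records, dim):
            in_bin = labels == bin_label
            for m in methods:
                pe, ok = pe_cols[m]
                pick = in_bin & ok
                s = _summary_or_none(pe[pick])
                rows.append(_summary_row(dim, bin_label, m, s, int(np.sum(pick))))

    return AnalysisReport(
        overall=overall,
        cells=pd.DataFrame(rows),
        acceptability=acceptability,
        exclusions=exclusions,
    )


def compare_all(records: pd.DataFrame, methods: Iterable[str], reference_method: str,
                dimensions: Iterable[str] = (), *,
                alpha: float = 0.001, clinical_margin: float = 10.0,
                thresholds: tuple = (10.0, 20.0)) -> list:
    """Paired comparisons of each method against ``reference_method``.

    For p10/p20: McNemar + matched odds ratio on within-threshold hits.
    For MPE: paired t-test on matched percentage errors.  Records are
    included pairwise — only where both methods produced an estimate.
    """
    methods = [m for m in methods if m != reference_method]
    pe_ref, ok_ref = _pe_for(records, reference_method)
    comparisons: list = []

    scopes = [("overall", "all", np.ones(len(records), dtype=bool))]
    for dim in dimensions:
        labels = assign_bins(records, dim).to_numpy()
        for bin_label in _bin_order(records, dim):
            scopes.append((dim, bin_label, labels == bin_label))

    for m in methods:
        pe_m, ok_m = _pe_for(records, m)
        both = ok_ref & ok_m
        for dim, bin_label, in_scope in scopes:
            pick = both & in_scope
            n = int(np.sum(pick))
            a = pe_ref[pick]
            b = pe_m[pick]
            for thr, metric in zip(thresholds, ("p10", "p20")):
                if n == 0:
                    continue
                comparisons.append(acc.compare_within_threshold(
                    np.abs(a) <= thr, np.abs(b) <= thr,
                    metric=metric, method_a=reference_method, method_b=m,
                    dimension=dim, bin=bin_label,
                    alpha=alpha, clinical_margin=clinical_margin,
                ))
            if n >= 2:
                t = acc.paired_t(a, b)
                mpe_a, mpe_b = float(np.mean(a)), float(np.mean(b))
                comparisons.append(PairedComparison(
                    metric="mpe", method_a=reference_method, method_b=m,
                    dimension=dim, bin=bin_label, n=n,
                    statistic=t.t, p_value=t.p_value,
                    value_a=mpe_a, value_b=mpe_b,
                    significant=(not t.degenerate or t.p_value == 0.0) and t.p_value < alpha,
                    clinically_important=abs(mpe_a - mpe_b) > clinical_margin,
                    degenerate=t.degenerate,
                ))
    return comparisons


def evaluate_acceptability(summary: AccuracySummary, *,
                           p10_threshold: float = 70.0,
                           p20_threshold: float = 95.0) -> bool:
    """Acceptable iff p10 >= 70% and p20 >= 95% (inclusive; thresholds configurable)."""
    return summary.p10 >= p10_threshold and summary.p20 >= p20_threshold
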