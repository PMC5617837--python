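"""Cardiac MRI systolic wall-thickening statistics.

Regional contractility is measured as systolic wall thickening,
SWT = (ESWT - EDWT)/EDWT x 100, from end-diastolic and end-systolic wall
thickness on cine CMR. SWT is averaged over the designated mid-apical
segments of each region (anteroseptal + anterior for the ischemic area,
inferolateral + inferior for the remote area); a segment is classified
dysfunctional when SWT is 30% or lower. Group-level (mean, SD, n)
summaries are pooled across groups by total-sum-of-squares combination and
pairwise p-values are adjusted by the sequential Holm-Bonferroni method.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .stats import holm_bonferroni  # noqa: F401  (re-exported spec surface)

__all__ = [
    "ISCHEMIC_SEGMENTS",
    "REMOTE_SEGMENTS",
    "GroupSummary",
    "PooledSummary",
    "compute_swt",
    "regional_swt",
    "classify_dysfunctional",
    "pool_group_summaries",
    "summarize_records",
    "build_table",
    "holm_bonferroni",
]

ISCHEMIC_SEGMENTS = ("anteroseptal", "anterior")
REMOTE_SEGMENTS = ("inferolateral", "inferior")

#: SWT at or below this percentage marks a dysfunctional segment.
DYSFUNCTION_THRESHOLD = 30.0


@dataclass(frozen=True)
class GroupSummary:
    """Mean (SD) systolic wall thickening of one group x region x phase."""

    group: str
    region: str
    phase: str
    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.sd > 0 and self.n < 2:
            raise ValueError("a nonzero SD requires n >= 2")


@dataclass(frozen=True)
class PooledSummary:
    region: str
    phase: str
    mean: float
    sd: float
    n: int


def compute_swt(edwt, eswt):
    """Systolic wall thickening percent: (ESWT - EDWT)/EDWT x 100.

    Ratio-based, hence invariant to the thickness unit. Accepts scalars or
    arrays; EDWT must be strictly positive.
    """
    edwt = np.asarray(edwt, dtype=float)
    eswt = np.asarray(eswt, dtype=float)
    if np.any(edwt <= 0):
        raise ValueError("end-diastolic wall thickness must be positive")
    out = (eswt - edwt) / edwt * 100.0
    return float(out) if out.ndim == 0 else out


def regional_swt(segment_values: Sequence[float]) -> float:
    """Regional SWT: arithmetic mean over the region's designated segments."""
    vals = np.asarray(segment_values, dtype=float)
    if vals.size == 0:
        raise ValueError("no segments")
    return float(vals.mean())


def classify_dysfunctional(swt):
    """True when SWT is 30% or lower (boundary inclusive)."""
    swt = np.asarray(swt, dtype=float)
    if np.any(~np.isfinite(swt)):
        raise ValueError("SWT must be finite")
    out = swt <= DYSFUNCTION_THRESHOLD
    return bool(out) if out.ndim == 0 else out


def pool_group_summaries(summaries: Sequence[GroupSummary]) -> PooledSummary:
    """Combine group (mean, SD, n) cells into one pooled mean and SD.

    The pooled mean is the n-weighted mean; the pooled SD comes from the
    total sum of squares SS = sum (n_i - 1) s_i^2 + sum n_i (m_i - m)^2
    with sd = sqrt(SS / (N - 1)), i.e. exactly the SD of the concatenated
    raw samples when each group matches its summary moments.
    """
    if not summaries:
        raise ValueError("no summaries to pool")
    regions = {s.region for s in summaries}
    phases = {s.phase for s in summaries}
    if len(regions) != 1 or len(phases) != 1:
        raise ValueError("summaries must share region and phase")
    n = np.array([s.n for s in summaries], dtype=float)
    m = np.array([s.mean for s in summaries], dtype=float)
    s = np.array([s.sd for s in summaries], dtype=float)
    total_n = int(n.sum())
    pooled_mean = float((n * m).sum() / n.sum())
    if total_n < 2:
        raise ValueError("pooled SD requires at least two animals in total")
    ss = float(((n - 1) * s**2).sum() + (n * (m - pooled_mean) ** 2).sum())
    pooled_sd = float(np.sqrt(ss / (total_n - 1)))
    return PooledSummary(
        region=regions.pop(), phase=phases.pop(), mean=pooled_mean, sd=pooled_sd, n=total_n
    )


def summarize_records(records: pd.DataFrame) -> pd.DataFrame:
    """Group x region x phase summaries from per-animal, per-segment records.

    ``records`` columns: animal, group, region, phase, segment, edwt_mm,
    eswt_mm. Per animal, segment SWT values are averaged within the region
    (regional SWT); per group, mean / SD (ddof=1) / n over animals.
    """
    required = {"animal", "group", "region", "phase", "segment", "edwt_mm", "eswt_mm"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"CMR record table missing columns: {sorted(missing)}")
    rec = records.copy()
    rec["swt"] = compute_swt(rec["edwt_mm"].to_numpy(), rec["eswt_mm"].to_numpy())
    per_animal = (
        rec.groupby(["group", "region", "phase", "animal"], sort=True)["swt"]
        .mean()
        .reset_index()
    )
    out = (
        per_animal.groupby(["group", "region", "phase"], sort=True)["swt"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0, n="size")
        .reset_index()
    )
    out["dysfunctional"] = classify_dysfunctional(out["mean"].to_numpy())
    return out


def build_table(summaries: pd.DataFrame) -> pd.DataFrame:
    """Wide, publication-style table: one row per group x region, one column
    per phase holding "mean (sd)", plus pooled rows per region computed by
    :func:`pool_group_summaries`."""
    required = {"group", "region", "phase", "mean", "sd", "n"}
    missing = required - set(summaries.columns)
    if missing:
        raise ValueError(f"summary table missing columns: {sorted(missing)}")
    phases = list(pd.unique(summaries["phase"]))
    rows = []
    for (group, region), sub in summaries.groupby(["group", "region"], sort=True):
        row = {"group": group, "region": region}
        for ph in phases:
            cell = sub[sub["phase"] == ph]
            if len(cell):
                row[ph] = f"{cell['mean'].iloc[0]:.1f} ({cell['sd'].iloc[0]:.1f})"
        rows.append(row)
    for region, sub in summaries.groupby("region", sort=True):
        row = {"group": "Pooled", "region": region}
        for ph in phases:
            cells = sub[sub["phase"] == ph]
            if len(cells):
                pooled = pool_group_summaries(
                    [
                        GroupSummary(str(r.group), str(region), str(ph), r.mean, r.sd, int(r.n))
                        for r in cells.itertuples()
                    ]
                )
                row[ph] = f"{pooled.mean:.1f} ({pooled.sd:.1f})"
        rows.append(row)
    return pd.DataFrame(rows)
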