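"""Targeted quantification from PRM fragment-ion chromatograms.

Parallel reaction monitoring (PRM) quantifies predefined peptides from the
extracted ion chromatograms (XICs) of their fragment ions. Only b- and
y-series fragments are accepted for quantitation. Transition peak areas are
integrated by the trapezoid rule, summed into peptide (and optionally
protein) values, and normalized by the run's total base-peak area — the
integral of the per-scan maximum intensity across all traces — which acts
as a loading control. Technical replicates are averaged per animal.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Chromatogram",
    "TransitionArea",
    "integrate_peak",
    "find_integration_window",
    "rollup_peptide",
    "rollup_protein",
    "total_base_peak_area",
    "normalize_run",
    "average_replicates",
    "quantify_run",
]

_ION_RE = re.compile(r"^[by]\d+$")


@dataclass(frozen=True)
class Chromatogram:
    """One transition's XIC: intensity versus retention time (seconds)."""

    peptide: str
    transition: str
    ion: str
    times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", y)
        if t.size == 0:
            raise ValueError("empty time grid")
        if t.size != y.size:
            raise ValueError("time grid and trace lengths differ")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if not np.all(np.isfinite(y)):
            raise ValueError("non-finite intensities")

    @property
    def is_quantifier(self) -> bool:
        """True for b/y-series fragment ions, the only ones used for quantitation."""
        return bool(_ION_RE.match(self.ion))


@dataclass(frozen=True)
class TransitionArea:
    peptide: str
    transition: str
    ion: str
    window: tuple[float, float]
    area: float
    normalized_area: float | None = None

    def __post_init__(self):
        if self.area < 0:
            raise ValueError("area must be non-negative")


def integrate_peak(chrom: Chromatogram, start: float, end: float) -> float:
    """Trapezoidal area of the trace restricted to the window [start, end]."""
    if start >= end:
        raise ValueError("window start must precede end")
    t = chrom.times
    if start < t[0] - 1e-9 or end > t[-1] + 1e-9:
        raise ValueError("integration window outside the chromatogram span")
    if np.any(chrom.intensities < 0):
        raise ValueError("negative intensities cannot be integrated")
    mask = (t >= start) & (t <= end)
    if mask.sum() < 2:
        raise ValueError("integration window contains fewer than two samples")
    return float(np.trapezoid(chrom.intensities[mask], t[mask]))


def find_integration_window(
    chrom: Chromatogram, threshold_frac: float = 0.05, smooth_points: int = 5
) -> tuple[float, float]:
    """Automatic peak boundaries: the contiguous region around the apex where
    the moving-average-smoothed trace stays above ``threshold_frac`` of its
    maximum."""
    if not 0 < threshold_frac < 1:
        raise ValueError("threshold_frac must lie in (0, 1)")
    y = chrom.intensities
    k = max(1, int(smooth_points))
    kernel = np.ones(k) / k
    smooth = np.convolve(y, kernel, mode="same")
    peak = smooth.max()
    if peak <= 0:
        raise ValueError("flat trace: no peak to integrate")
    above = smooth >= threshold_frac * peak
    apex = int(np.argmax(smooth))
    lo = apex
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = apex
    while hi < y.size - 1 and above[hi + 1]:
        hi += 1
    return float(chrom.times[lo]), float(chrom.times[hi])


def rollup_peptide(areas: Iterable[TransitionArea]) -> float:
    """Peptide-level area: sum of its b/y transition areas."""
    areas = list(areas)
    if not areas:
        raise ValueError("no transitions to roll up")
    peptides = {a.peptide for a in areas}
    if len(peptides) != 1:
        raise ValueError(f"transitions from multiple peptides: {sorted(peptides)}")
    bad = [a.transition for a in areas if not _ION_RE.match(a.ion)]
    if bad:
        raise ValueError(f"non-b/y transitions are not quantifiers: {bad}")
    return float(sum(a.area for a in areas))


def rollup_protein(peptide_areas: Mapping[str, float], how: str = "sum") -> float:
    """Protein-level value from its monitored peptides (default: sum)."""
    if not peptide_areas:
        raise ValueError("no peptides to roll up")
    vals = np.asarray(list(peptide_areas.values()), dtype=float)
    if how == "sum":
        return float(vals.sum())
    if how == "mean":
        return float(vals.mean())
    raise ValueError(f"unknown rollup mode {how!r}")


def total_base_peak_area(chroms: Sequence[Chromatogram]) -> float:
    """Integral of the per-scan maximum intensity across all traces of a run.

    All chromatograms of the run must share one time grid.
    """
    if not chroms:
        raise ValueError("empty run")
    grid = chroms[0].times
    for c in chroms[1:]:
        if c.times.size != grid.size or not np.allclose(c.times, grid):
            raise ValueError("all chromatograms of a run must share the time grid")
    base = np.max(np.vstack([c.intensities for c in chroms]), axis=0)
    return float(np.trapezoid(base, grid))


def normalize_run(areas, total_base_peak: float):
    """Divide areas by the run's total base-peak area.

    Accepts a mapping, sequence or scalar of areas; TransitionArea objects
    get their ``normalized_area`` field filled in.
    """
    if not np.isfinite(total_base_peak) or total_base_peak <= 0:
        raise ValueError("total base-peak area must be positive")
    if isinstance(areas, TransitionArea):
        return replace(areas, normalized_area=areas.area / total_base_peak)
    if isinstance(areas, Mapping):
        return {k: v / total_base_peak for k, v in areas.items()}
    if np.isscalar(areas):
        return float(areas) / total_base_peak
    return [
        replace(a, normalized_area=a.area / total_base_peak)
        if isinstance(a, TransitionArea)
        else a / total_base_peak
        for a in areas
    ]


def average_replicates(values: Sequence[float]) -> float:
    """Per-animal value from 1-2 technical replicates (arithmetic mean)."""
    if len(values) == 0:
        raise ValueError("no replicates")
    if len(values) > 2:
        raise ValueError("at most two technical replicates expected")
    return float(np.mean(values))


def quantify_run(
    chroms: Sequence[Chromatogram],
    windows: Mapping[str, tuple[float, float]] | None = None,
    protein_of: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Integrate a full PRM run into normalized peptide (and protein) areas.

    Non-b/y transitions are rejected. ``windows`` maps transition id to an
    explicit integration window; transitions without one get automatic
    boundaries from :func:`find_integration_window`.
    """
    if not chroms:
        raise ValueError("empty run")
    tbpa = total_base_peak_area(chroms)
    per_peptide: dict[str, list[TransitionArea]] = {}
    for c in chroms:
        if not c.is_quantifier:
            raise ValueError(
                f"transition {c.transition!r} has non-b/y ion {c.ion!r}; "
                "only b/y fragments are used for quantitation"
            )
        win = windows.get(c.transition) if windows else None
        if win is None:
            win = find_integration_window(c)
        area = integrate_peak(c, *win)
        per_peptide.setdefault(c.peptide, []).append(
            TransitionArea(c.peptide, c.transition, c.ion, win, area)
        )
    rows = []
    for peptide, areas in sorted(per_peptide.items()):
        total = rollup_peptide(areas)
        rows.append(
            {
                "peptide": peptide,
                "protein": protein_of.get(peptide, peptide) if protein_of else peptide,
                "n_transitions": len(areas),
                "area": total,
                "normalized_area": total / tbpa,
            }
        )
    return pd.DataFrame(rows)
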