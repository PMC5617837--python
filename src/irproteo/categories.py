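"""Category-coordination analysis (Zc), FDR control and time-course clusters.

Coordinated behavior of functionally related proteins is detected by the
standardized category average

    Zc = (sum of member Zq) / sqrt(n),

which is ~N(0, 1) when the n quantified members are unchanged and grows as
sqrt(n) * delta when all members share a moderate standardized shift delta
— making coordinated subtle changes detectable even when no single protein
is significant on its own. Two-sided normal p-values are controlled by
Benjamini-Hochberg within each condition, and the per-region time profiles
of significant categories are classified into the cluster taxonomy
(a: early sustained up, b: early down recovering, c: late up peaking at
day 7, d: progressive down, e: transient early excursion).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .stats import bh_adjust

__all__ = [
    "CategoryAnnotation",
    "CLUSTER_LABELS",
    "compute_zc",
    "category_fdr",
    "classify_profile",
    "classify_profiles",
    "category_ecdf",
    "ecdf",
    "SbtModel",
    "SbtResults",
]

CLUSTER_LABELS = ("a", "b", "c", "d", "e", "unclassified")

#: Half-width of the band within which a category is considered to have
#: returned to its baseline level; also the slack allowed on the
#: monotonicity check of cluster d. Covers ~98.8% of the unit-variance
#: sampling noise of a truly recovered category.
RETURN_BAND = 2.5


@dataclass(frozen=True)
class CategoryAnnotation:
    """One functional category: id, free-text description, member proteins."""

    category_id: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "members", tuple(dict.fromkeys(self.members)))
        if not self.members:
            raise ValueError(f"category {self.category_id!r} has no members")


def _as_annotations(annotations) -> list[CategoryAnnotation]:
    if isinstance(annotations, Mapping):
        return [CategoryAnnotation(k, "", tuple(v)) for k, v in annotations.items()]
    return list(annotations)


def compute_zc(
    scores: pd.DataFrame,
    annotations: Iterable[CategoryAnnotation] | Mapping[str, Sequence[str]],
    min_size: int = 5,
) -> pd.DataFrame:
    """Per category x condition Zc with two-sided normal p-values.

    Member lists are de-duplicated, restricted to quantified proteins, and
    category-condition cells with fewer than ``min_size`` quantified members
    are dropped. ``scores`` is a protein-score table with columns
    ``protein, region, timepoint, Zq``.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    annotations = _as_annotations(annotations)
    members = pd.DataFrame(
        [(a.category_id, p) for a in annotations for p in a.members],
        columns=["category", "protein"],
    )
    merged = members.merge(scores[["protein", "region", "timepoint", "Zq"]], on="protein")
    if merged.empty:
        warnings.warn("no annotated protein is quantified: empty category table")
        return pd.DataFrame(columns=["category", "region", "timepoint", "n", "Zc", "p"])
    out = (
        merged.groupby(["category", "region", "timepoint"], sort=True)["Zq"]
        .agg(n="size", zq_sum="sum")
        .reset_index()
    )
    out = out[out["n"] >= min_size].reset_index(drop=True)
    out["Zc"] = out.pop("zq_sum") / np.sqrt(out["n"])
    out["p"] = 2.0 * norm.sf(np.abs(out["Zc"]))
    return out


def category_fdr(scores: pd.DataFrame, scope: str = "condition") -> pd.DataFrame:
    """Benjamini-Hochberg adjusted q-values for category scores.

    ``scope="condition"`` adjusts within each region x timepoint (the
    default, matching per-timepoint significance calls); ``scope="global"``
    adjusts over the whole table at once.
    """
    out = scores.copy()
    if scope == "global":
        out["fdr"] = bh_adjust(out["p"].to_numpy())
    elif scope == "condition":
        out["fdr"] = (
            out.groupby(["region", "timepoint"], sort=False)["p"]
            .transform(lambda p: bh_adjust(p.to_numpy()))
        )
    else:
        raise ValueError(f"unknown FDR scope {scope!r}")
    return out


def classify_profile(
    zc: Sequence[float],
    significant: Sequence[bool],
    return_band: float = RETURN_BAND,
) -> str:
    """Cluster label for one ordered 4-point Zc time profile.

    Rules, tried in the fixed priority a > b > c > d > e (a label requires
    significance at >= 1 time point):

    - ``a``: significant positive at the first time point and still
      significantly positive at the last (early, sustained upregulation).
    - ``b``: significant negative at the first time point, back within
      ``return_band`` of zero at the last (early down, recovering).
    - ``c``: significant positive maximum at the last time point with no
      significance at the first two (late upregulation peaking at day 7).
    - ``d``: significant negative at the last time point, non-increasing
      within ``return_band`` slack, not significant at the first
      (progressive downregulation reaching its minimum at day 7).
    - ``e``: significant excursion of either sign at one of the first two
      time points, back within ``return_band`` at the last (transient).
    """
    zc = np.asarray(zc, dtype=float)
    sig = np.asarray(significant, dtype=bool)
    if zc.shape != (4,) or sig.shape != (4,):
        raise ValueError("a profile is exactly 4 ordered Zc values with a significance mask")
    if not sig.any():
        return "unclassified"
    sig_pos = sig & (zc > 0)
    sig_neg = sig & (zc < 0)
    returned = abs(zc[3]) < return_band
    if sig_pos[0] and sig_pos[3]:
        return "a"
    if sig_neg[0] and returned:
        return "b"
    if sig_pos[3] and zc.argmax() == 3 and not sig[0] and not sig[1]:
        return "c"
    if sig_neg[3] and not sig[0] and np.all(np.diff(zc) <= return_band):
        return "d"
    if (sig[0] or sig[1]) and returned:
        return "e"
    return "unclassified"


def classify_profiles(
    scored: pd.DataFrame,
    timepoints: Sequence[str],
    alpha: float = 0.05,
    return_band: float = RETURN_BAND,
) -> pd.DataFrame:
    """Cluster labels for every category x region with a complete time profile.

    ``scored`` must carry ``fdr`` (see :func:`category_fdr`); significance
    is fdr < ``alpha`` per time point. Category-region pairs missing any of
    the ordered ``timepoints`` are skipped with a warning.
    """
    timepoints = list(timepoints)
    if len(timepoints) != 4:
        raise ValueError("the cluster taxonomy is defined over 4 ordered time points")
    rows, skipped = [], 0
    for (category, region), sub in scored.groupby(["category", "region"], sort=True):
        sub = sub.set_index("timepoint")
        if not all(tp in sub.index for tp in timepoints):
            skipped += 1
            continue
        zc = sub.loc[timepoints, "Zc"].to_numpy(dtype=float)
        sig = sub.loc[timepoints, "fdr"].to_numpy(dtype=float) < alpha
        row = {"category": category, "region": region}
        for tp, z, s in zip(timepoints, zc, sig):
            row[f"Zc_{tp}"] = z
            row[f"sig_{tp}"] = bool(s)
        row["cluster"] = classify_profile(zc, sig, return_band=return_band)
        rows.append(row)
    if skipped:
        warnings.warn(f"{skipped} category-region profiles lacked a complete time course")
    return pd.DataFrame(rows)


def ecdf(values) -> tuple[np.ndarray, np.ndarray]:
    """Right-continuous empirical CDF: sorted values and F at each of them."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("empty input")
    return v, np.arange(1, v.size + 1) / v.size


@dataclass(frozen=True)
class EcdfPair:
    """Category ECDF with its all-protein background for comparison."""

    category_x: np.ndarray
    category_f: np.ndarray
    background_x: np.ndarray
    background_f: np.ndarray

    def evaluate(self, x, which: str = "category") -> np.ndarray:
        xs, fs = (
            (self.category_x, self.category_f)
            if which == "category"
            else (self.background_x, self.background_f)
        )
        idx = np.searchsorted(xs, np.asarray(x, dtype=float), side="right")
        out = np.concatenate([[0.0], fs])[idx]
        return float(out) if out.ndim == 0 else out


def category_ecdf(category_values, background_values) -> EcdfPair:
    """Empirical CDFs of a category's Zq values and of the background Zq."""
    cx, cf = ecdf(category_values)
    bx, bf = ecdf(background_values)
    return EcdfPair(cx, cf, bx, bf)


# ---------------------------------------------------------------------------
# model / results


class SbtModel:
    """Category-coordination model over a fitted protein-score table.

    Parameters
    ----------
    scores
        Protein scores (``protein, region, timepoint, Zq``) — typically
        ``WsppResults.protein_scores``.
    annotations
        Iterable of :class:`CategoryAnnotation` or a mapping
        category id -> member proteins.
    min_size
        Minimum quantified members per category-condition cell.
    """

    def __init__(self, scores, annotations, min_size: int = 5):
        if hasattr(scores, "protein_scores"):  # accept a WsppResults directly
            scores = scores.protein_scores
        self.scores = scores
        self.annotations = _as_annotations(annotations)
        self.min_size = int(min_size)

    def fit(
        self,
        alpha: float = 0.05,
        fdr_scope: str = "condition",
        timepoints: Sequence[str] | None = None,
        return_band: float = RETURN_BAND,
    ) -> "SbtResults":
        if not 0 < alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        scored = category_fdr(
            compute_zc(self.scores, self.annotations, min_size=self.min_size),
            scope=fdr_scope,
        )
        if timepoints is None:
            timepoints = list(pd.unique(self.scores["timepoint"]))
        profiles = (
            classify_profiles(scored, timepoints, alpha=alpha, return_band=return_band)
            if len(scored) and len(timepoints) == 4
            else pd.DataFrame(columns=["category", "region", "cluster"])
        )
        return SbtResults(
            model=self, alpha=alpha, category_scores=scored, profiles=profiles
        )


@dataclass
class SbtResults:
    """Fitted category analysis: Zc scores with FDR and cluster profiles."""

    model: SbtModel
    alpha: float
    category_scores: pd.DataFrame = field(repr=False)
    profiles: pd.DataFrame = field(repr=False)

    @property
    def significant(self) -> pd.DataFrame:
        return self.category_scores[self.category_scores["fdr"] < self.alpha]

    def ecdf(self, category_id: str, region: str, timepoint: str) -> EcdfPair:
        """Member-Zq ECDF of one category cell against the all-protein background."""
        members = next(
            (a.members for a in self.model.annotations if a.category_id == category_id),
            None,
        )
        if members is None:
            raise KeyError(f"unknown category {category_id!r}")
        scores = self.model.scores
        cell = scores[(scores["region"] == region) & (scores["timepoint"] == timepoint)]
        return category_ecdf(
            cell.loc[cell["protein"].isin(members), "Zq"].to_numpy(),
            cell["Zq"].to_numpy(),
        )

    def summary(self) -> str:
        sig = self.significant
        lines = [
            "Category coordination analysis (standardized category averages)",
            "=" * 64,
            f"categories scored: {self.category_scores['category'].nunique()}"
            f"    cells: {len(self.category_scores)}"
            f"    significant (FDR < {self.alpha:g}): {len(sig)}",
        ]
        if len(self.profiles):
            counts = self.profiles["cluster"].value_counts()
            lines.append(
                "cluster counts: "
                + ", ".join(f"{k}: {counts.get(k, 0)}" for k in CLUSTER_LABELS)
            )
            top = sig.reindex(sig["Zc"].abs().sort_values(ascending=False).index).head(10)
            if len(top):
                lines.append("-" * 64)
                lines.append(f"{'category':<20}{'region':<10}{'timepoint':<12}{'n':>5}{'Zc':>9}{'fdr':>10}")
                for r in top.itertuples():
                    lines.append(
                        f"{r.category:<20}{r.region:<10}{r.timepoint:<12}{r.n:>5d}{r.Zc:>9.2f}{r.fdr:>10.2e}"
                    )
        return "\n".join(lines)
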