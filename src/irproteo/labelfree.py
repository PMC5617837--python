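"""Label-free iBAQ quantification and between-group testing.

iBAQ (intensity-based absolute quantification) divides a protein's summed
peptide intensity by the number of tryptic peptides the protein can
theoretically yield within the observable length window, giving a value
roughly proportional to molar amount. Abundances are then expressed as a
percentage of the identified proteome within each animal, so that group
comparisons act on composition-normalized values. Groups are compared with
the two-sided Mann-Whitney test and Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import re
from typing import Mapping

import numpy as np
import pandas as pd

from .stats import TestResult, bh_adjust, mann_whitney

__all__ = [
    "tryptic_peptides",
    "count_theoretical_peptides",
    "compute_ibaq",
    "compare_groups",
    "test_group_differences",
    "bh_adjust",
]

_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
# trypsin: cleave C-terminal to K or R, except when followed by P
_TRYPSIN = re.compile(r"(?<=[KR])(?!P)")


def tryptic_peptides(sequence: str, min_len: int = 7, max_len: int = 30) -> list[str]:
    """Fully tryptic peptides (zero missed cleavages) within a length window.

    Cleaves after K or R unless the next residue is P. Repeated peptides are
    kept, so the result counts occurrences rather than distinct sequences.
    """
    if not sequence:
        raise ValueError("empty sequence")
    bad = set(sequence) - _AA
    if bad:
        raise ValueError(f"invalid residue letters: {sorted(bad)}")
    return [p for p in _TRYPSIN.split(sequence) if min_len <= len(p) <= max_len]


def count_theoretical_peptides(sequence: str, min_len: int = 7, max_len: int = 30) -> int:
    """Number of theoretically observable tryptic peptides (iBAQ denominator)."""
    return len(tryptic_peptides(sequence, min_len, max_len))


def compute_ibaq(
    intensities: pd.DataFrame, n_theoretical: Mapping[str, int]
) -> pd.DataFrame:
    """Per-animal iBAQ values and proteome percentages.

    Parameters
    ----------
    intensities
        Long table with columns ``animal``, ``protein``, ``intensity``
        (an optional ``peptide`` column is ignored; intensities are summed
        over a protein's peptides within each animal).
    n_theoretical
        Mapping protein id -> count of theoretical tryptic peptides.

    Proteins with a zero theoretical-peptide count are flagged
    ``quantifiable = False``; their iBAQ is undefined (NaN) and they are
    excluded from the proteome-percentage denominator. Percentages sum to
    100 within each animal over quantifiable proteins.
    """
    required = {"animal", "protein", "intensity"}
    missing = required - set(intensities.columns)
    if missing:
        raise ValueError(f"intensity table missing columns: {sorted(missing)}")
    if (intensities["intensity"] < 0).any():
        raise ValueError("negative intensities")

    summed = (
        intensities.groupby(["animal", "protein"], sort=True)["intensity"]
        .sum()
        .reset_index()
    )
    unknown = set(summed["protein"]) - set(n_theoretical)
    if unknown:
        raise ValueError(f"proteins without theoretical peptide counts: {sorted(unknown)[:5]}")
    summed["n_theoretical"] = summed["protein"].map(n_theoretical).astype(int)
    if (summed["n_theoretical"] < 0).any():
        raise ValueError("n_theoretical must be >= 0")
    summed["quantifiable"] = summed["n_theoretical"] >= 1
    summed["ibaq"] = np.where(
        summed["quantifiable"], summed["intensity"] / summed["n_theoretical"].clip(lower=1), np.nan
    )

    totals = summed[summed["quantifiable"]].groupby("animal")["ibaq"].sum()
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"zero total iBAQ intensity for animals {bad}: cannot normalize")
    summed["proteome_pct"] = 100.0 * summed["ibaq"] / summed["animal"].map(totals)
    return summed


def compare_groups(values_a, values_b, exact_threshold: int = 12) -> TestResult:
    """Two-sided Mann-Whitney comparison of two groups of animals.

    Exact by full enumeration of group labelings when nA + nB is at most
    ``exact_threshold``, otherwise the tie-corrected normal approximation.
    """
    return mann_whitney(values_a, values_b, exact_threshold=exact_threshold)


def test_group_differences(
    ibaq: pd.DataFrame,
    design: Mapping[str, str],
    group_a: str,
    group_b: str,
    value: str = "proteome_pct",
    exact_threshold: int = 12,
) -> pd.DataFrame:
    """Per-protein Mann-Whitney tests between two animal groups, with BH q-values.

    ``design`` maps animal id -> group label. Proteins are tested when both
    groups contribute at least one animal with a finite value.
    """
    df = ibaq.copy()
    df["group"] = df["animal"].map(design)
    rows = []
    for protein, sub in df.groupby("protein", sort=True):
        a = sub.loc[sub["group"] == group_a, value].dropna().to_numpy()
        b = sub.loc[sub["group"] == group_b, value].dropna().to_numpy()
        if a.size == 0 or b.size == 0:
            continue
        res = compare_groups(a, b, exact_threshold=exact_threshold)
        rows.append((protein, res.u, res.p))
    out = pd.DataFrame(rows, columns=["protein", "u", "p"])
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
    else:
        out["q"] = pd.Series(dtype=float)
    return out
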