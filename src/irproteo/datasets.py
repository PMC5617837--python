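"""Bundled example data.

Group-level systolic wall-thickening summaries (mean %, SD, n = 5 animals
per group) from the porcine 40-min ischemia/reperfusion study design this
package emulates: five groups followed by cine CMR from baseline up to
their sacrifice time point, with ischemic and remote regions scored
separately. These printed group cells are inputs; pooled statistics are
recomputed from them with :func:`irproteo.cmr.pool_group_summaries`.
"""

from __future__ import annotations

import pandas as pd

from .cmr import GroupSummary

__all__ = ["wall_thickening_group_summaries", "wall_thickening_table"]

PHASES = ("baseline", "R-120min", "R-24h", "R-Day4", "R-Day7")

# (group, region, phase, mean %, sd %); n = 5 animals everywhere
_CELLS = [
    ("group1", "ischemic", "baseline", 75.7, 16.7),
    ("group1", "remote", "baseline", 61.8, 20.1),
    ("group2", "ischemic", "baseline", 38.4, 10.2),
    ("group2", "ischemic", "R-120min", -21.4, 15.1),
    ("group2", "remote", "baseline", 18.3, 7.0),
    ("group2", "remote", "R-120min", -12.3, 9.3),
    ("group3", "ischemic", "baseline", 47.5, 11.6),
    ("group3", "ischemic", "R-120min", -15.8, 12.4),
    ("group3", "ischemic", "R-24h", -4.3, 9.7),
    ("group3", "remote", "baseline", 30.6, 14.0),
    ("group3", "remote", "R-120min", 6.7, 16.1),
    ("group3", "remote", "R-24h", 9.7, 13.9),
    ("group4", "ischemic", "baseline", 45.4, 17.7),
    ("group4", "ischemic", "R-120min", -14.6, 9.7),
    ("group4", "ischemic", "R-24h", -3.7, 7.9),
    ("group4", "ischemic", "R-Day4", 12.9, 16.9),
    ("group4", "remote", "baseline", 35.3, 16.3),
    ("group4", "remote", "R-120min", -5.5, 9.4),
    ("group4", "remote", "R-24h", 7.9, 21.5),
    ("group4", "remote", "R-Day4", 39.7, 21.7),
    ("group5", "ischemic", "baseline", 80.6, 16.2),
    ("group5", "ischemic", "R-120min", -10.2, 18.6),
    ("group5", "ischemic", "R-24h", 3.6, 15.3),
    ("group5", "ischemic", "R-Day4", 21.6, 7.8),
    ("group5", "ischemic", "R-Day7", 17.6, 15.5),
    ("group5", "remote", "baseline", 65.6, 14.9),
    ("group5", "remote", "R-120min", 14.1, 11.3),
    ("group5", "remote", "R-24h", 18.6, 21.3),
    ("group5", "remote", "R-Day4", 40.0, 12.7),
    ("group5", "remote", "R-Day7", 35.4, 19.7),
]


def wall_thickening_group_summaries(
    region: str | None = None, phase: str | None = None
) -> list[GroupSummary]:
    """The bundled group summaries, optionally filtered by region and phase."""
    out = [
        GroupSummary(group=g, region=r, phase=p, mean=m, sd=s, n=5)
        for g, r, p, m, s in _CELLS
        if (region is None or r == region) and (phase is None or p == phase)
    ]
    if not out:
        raise ValueError(f"no bundled cells for region={region!r}, phase={phase!r}")
    return out


def wall_thickening_table() -> pd.DataFrame:
    """The bundled summaries as a tidy DataFrame (group, region, phase, mean, sd, n)."""
    return pd.DataFrame(
        [(g, r, p, m, s, 5) for g, r, p, m, s in _CELLS],
        columns=["group", "region", "phase", "mean", "sd", "n"],
    )
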