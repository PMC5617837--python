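"""Readers and writers for the package's interchange formats.

TSV with a header line is the interchange format for tabular data (UTF-8,
"." decimal separator, ``NA`` for missing, 12 significant digits so that
write-then-read is an identity on the canonical form). Category
annotations use the GMT convention (one set per line: id, description,
members, tab-separated) and chromatograms a plain JSON layout.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .categories import CategoryAnnotation
from .prm import Chromatogram
from .quant import SCAN_COLUMNS, validate_scan_table

__all__ = [
    "read_table",
    "write_table",
    "read_scan_table",
    "write_scan_table",
    "read_gmt",
    "write_gmt",
    "read_chromatograms",
    "write_chromatograms",
]

_FLOAT_FORMAT = "%.12g"


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT, na_rep="NA")
    return path


def read_table(
    path,
    required: Sequence[str] = (),
    numeric: Sequence[str] = (),
) -> pd.DataFrame:
    """TSV reader with schema validation naming the offending column/row."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=True)
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{path.name}: missing required columns {sorted(missing)}")
    for col in numeric:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            row = int(bad[0]) + 2 if len(bad) else "?"  # +2: header + 1-based
            raise ValueError(f"{path.name}: non-numeric value in column {col!r} at line {row}") from exc
    return df


def write_scan_table(scans: pd.DataFrame, path) -> Path:
    return write_table(validate_scan_table(scans)[list(SCAN_COLUMNS)], path)


def read_scan_table(path) -> pd.DataFrame:
    df = read_table(path, required=SCAN_COLUMNS, numeric=["log2_ratio", "intensity"])
    return validate_scan_table(df)


def write_gmt(annotations: Iterable[CategoryAnnotation], path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8") as fh:
        for a in annotations:
            desc = a.description or "-"
            fh.write("\t".join([a.category_id, desc, *a.members]) + "\n")
    return path


def read_gmt(path) -> list[CategoryAnnotation]:
    path = Path(path)
    out = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path.name}:{lineno}: GMT lines need id, description and >= 1 member"
                )
            out.append(CategoryAnnotation(parts[0], parts[1], tuple(parts[2:])))
    return out


def write_chromatograms(chroms: Sequence[Chromatogram], path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = [
        {
            "peptide": c.peptide,
            "transition": c.transition,
            "ion": c.ion,
            "times": np.round(c.times, 9).tolist(),
            "intensities": np.round(c.intensities, 9).tolist(),
        }
        for c in chroms
    ]
    path.write_text(json.dumps({"chromatograms": payload}), encoding="utf-8")
    return path


def read_chromatograms(path) -> list[Chromatogram]:
    path = Path(path)
    payload = json.loads(path.read_text(encoding="utf-8"))
    if "chromatograms" not in payload:
        raise ValueError(f"{path.name}: missing 'chromatograms' key")
    return [
        Chromatogram(
            peptide=c["peptide"],
            transition=c["transition"],
            ion=c["ion"],
            times=np.asarray(c["times"], dtype=float),
            intensities=np.asarray(c["intensities"], dtype=float),
        )
        for c in payload["chromatograms"]
    ]
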