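"""Orchestration of the two analysis pipelines.

The screening pipeline runs scan-level quantification through Zq
standardization, category Zc scoring with FDR control, and time-course
cluster classification, writing every stage as TSV next to a JSON run
report. The validation pipeline runs whichever of the label-free (iBAQ),
targeted (PRM) and CMR wall-thickening stages are configured. Outputs are
a pure function of (configuration, seed).
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .categories import SbtModel, RETURN_BAND
from .cmr import build_table, summarize_records
from .io import (
    read_chromatograms,
    read_gmt,
    read_scan_table,
    read_table,
    write_table,
)
from .labelfree import compute_ibaq, count_theoretical_peptides, test_group_differences
from .prm import quantify_run
from .quant import WsppModel

__all__ = ["PipelineConfig", "RunReport", "run_screening", "run_validation"]

log = logging.getLogger("irproteo")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[%(name)s] %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


@dataclass
class PipelineConfig:
    """Paths and parameters driving a pipeline run."""

    out_dir: str = "irproteo_out"
    seed: int = 0
    # screening
    scans: str | None = None
    annotations: str | None = None
    min_category_size: int = 5
    fdr_threshold: float = 0.05
    fdr_scope: str = "condition"
    n_bins: int = 5
    return_band: float = RETURN_BAND
    # validation
    labelfree_intensities: str | None = None
    labelfree_fasta: str | None = None
    labelfree_design: str | None = None
    labelfree_groups: tuple[str, str] | None = None
    prm_chromatograms: str | None = None
    cmr_records: str | None = None

    def __post_init__(self):
        if not 0 < self.fdr_threshold < 1:
            raise ValueError("fdr_threshold must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        if "labelfree_groups" in raw and raw["labelfree_groups"] is not None:
            raw["labelfree_groups"] = tuple(raw["labelfree_groups"])
        return cls(**raw)


@dataclass
class RunReport:
    """Machine-readable record of a pipeline run."""

    pipeline: str
    seed: int
    parameters: dict
    row_counts: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    version: str = __version__
    elapsed_s: float = 0.0

    def write(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2, default=str), encoding="utf-8")
        missing = [p for p in self.outputs if not Path(p).exists()]
        if missing:  # manifest contract: every declared output exists
            raise RuntimeError(f"declared outputs missing on disk: {missing}")
        return path


def _require(value, name: str):
    if value is None:
        raise ValueError(f"pipeline configuration lacks required input {name!r}")
    return value


def run_screening(config: PipelineConfig) -> RunReport:
    """Scan table -> Zq -> Zc -> clusters, with TSV outputs and a JSON report."""
    t0 = time.perf_counter()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = RunReport(
        pipeline="screening",
        seed=config.seed,
        parameters={
            "min_category_size": config.min_category_size,
            "fdr_threshold": config.fdr_threshold,
            "fdr_scope": config.fdr_scope,
            "n_bins": config.n_bins,
            "return_band": config.return_band,
        },
    )

    scans = read_scan_table(_require(config.scans, "scans"))
    report.row_counts["scans"] = len(scans)
    log.info("quantifying %d scan rows", len(scans))
    results = WsppModel(scans, n_bins=config.n_bins).fit()
    zq_path = write_table(results.protein_scores, out_dir / "zq.tsv")
    report.row_counts["protein_scores"] = len(results.protein_scores)

    comp_path = out_dir / "variance_components.json"
    comp_path.write_text(
        json.dumps(
            {
                f"{r}|{t}": {"sigma_P2": c.sigma_P2, "sigma_Q2": c.sigma_Q2}
                for (r, t), c in results.components.items()
            }
            | {
                "scan_variance": {
                    "edges": results.scan_model.edges.tolist(),
                    "variances": results.scan_model.variances.tolist(),
                }
            },
            indent=2,
        ),
        encoding="utf-8",
    )

    annotations = read_gmt(_require(config.annotations, "annotations"))
    sbt = SbtModel(results, annotations, min_size=config.min_category_size).fit(
        alpha=config.fdr_threshold,
        fdr_scope=config.fdr_scope,
        timepoints=sorted(scans["timepoint"].unique(), key=_timepoint_key),
        return_band=config.return_band,
    )
    cat_path = write_table(sbt.category_scores, out_dir / "category_scores.tsv")
    prof_path = write_table(sbt.profiles, out_dir / "category_profiles.tsv")
    report.row_counts["category_scores"] = len(sbt.category_scores)
    report.row_counts["category_profiles"] = len(sbt.profiles)
    if sbt.category_scores.empty:
        log.warning("no category overlapped the quantified proteins")

    ecdf_rows = []
    for r in sbt.significant.itertuples():
        pair = sbt.ecdf(r.category, r.region, r.timepoint)
        ecdf_rows.append(
            pd.DataFrame(
                {
                    "category": r.category,
                    "region": r.region,
                    "timepoint": r.timepoint,
                    "zq": pair.category_x,
                    "ecdf": pair.category_f,
                }
            )
        )
    ecdf_df = (
        pd.concat(ecdf_rows, ignore_index=True)
        if ecdf_rows
        else pd.DataFrame(columns=["category", "region", "timepoint", "zq", "ecdf"])
    )
    ecdf_path = write_table(ecdf_df, out_dir / "category_ecdf.tsv")
    report.row_counts["category_ecdf"] = len(ecdf_df)

    report.outputs = [str(p) for p in (zq_path, comp_path, cat_path, prof_path, ecdf_path)]
    report.elapsed_s = round(time.perf_counter() - t0, 3)
    report.write(out_dir / "screening_report.json")
    log.info("screening finished in %.1fs", report.elapsed_s)
    return report


_TP_ORDER = {"R-120min": 0, "R-24h": 1, "R-Day4": 2, "R-Day7": 3}


def _timepoint_key(tp: str):
    return (_TP_ORDER.get(tp, 99), tp)


def run_validation(config: PipelineConfig) -> RunReport:
    """Run the configured subset of label-free, PRM and CMR stages."""
    t0 = time.perf_counter()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = RunReport(pipeline="validation", seed=config.seed, parameters={})
    ran_any = False

    if config.labelfree_intensities is not None:
        ran_any = True
        intensities = read_table(
            config.labelfree_intensities,
            required=("animal", "protein", "intensity"),
            numeric=("intensity",),
        )
        fasta = _require(config.labelfree_fasta, "labelfree_fasta")
        n_theo = {
            pid: count_theoretical_peptides(seq) for pid, seq in _read_fasta(fasta).items()
        }
        ibaq = compute_ibaq(intensities, n_theo)
        report.outputs.append(str(write_table(ibaq, out_dir / "ibaq.tsv")))
        report.row_counts["ibaq"] = len(ibaq)
        if config.labelfree_design and config.labelfree_groups:
            design_df = read_table(config.labelfree_design, required=("animal", "group"))
            design = dict(zip(design_df["animal"], design_df["group"]))
            tests = test_group_differences(ibaq, design, *config.labelfree_groups)
            report.outputs.append(str(write_table(tests, out_dir / "ibaq_tests.tsv")))
            report.row_counts["ibaq_tests"] = len(tests)

    if config.prm_chromatograms is not None:
        ran_any = True
        chroms = read_chromatograms(config.prm_chromatograms)
        areas = quantify_run(chroms)
        report.outputs.append(str(write_table(areas, out_dir / "prm_areas.tsv")))
        report.row_counts["prm_areas"] = len(areas)

    if config.cmr_records is not None:
        ran_any = True
        records = read_table(
            config.cmr_records,
            required=("animal", "group", "region", "phase", "segment", "edwt_mm", "eswt_mm"),
            numeric=("edwt_mm", "eswt_mm"),
        )
        summaries = summarize_records(records)
        report.outputs.append(str(write_table(summaries, out_dir / "cmr_summaries.tsv")))
        table = build_table(summaries)
        report.outputs.append(str(write_table(table, out_dir / "cmr_table.tsv")))
        report.row_counts["cmr_summaries"] = len(summaries)

    if not ran_any:
        raise ValueError("no validation stage configured")
    report.elapsed_s = round(time.perf_counter() - t0, 3)
    report.write(out_dir / "validation_report.json")
    log.info("validation finished in %.1fs", report.elapsed_s)
    return report


def _read_fasta(path) -> dict[str, str]:
    sequences: dict[str, list[str]] = {}
    current = None
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                current = line[1:].split()[0]
                sequences[current] = []
            elif current is None:
                raise ValueError(f"{path}: sequence data before first FASTA header")
            else:
                sequences[current].append(line)
    return {k: "".join(v) for k, v in sequences.items()}
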