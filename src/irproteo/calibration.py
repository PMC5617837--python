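"""Monte-Carlo calibration experiments for the screening pipeline.

These experiments run the full scan-table -> Zq -> Zc -> FDR pipeline on
seeded complete-null synthetic datasets and measure its operating
characteristics; the headline quantity is the empirical false-discovery
proportion at the q < 0.05 threshold, which Benjamini-Hochberg should keep
at or below 0.05 when no category carries a coordinated effect.
"""

from __future__ import annotations

import numpy as np

from .categories import category_fdr, compute_zc
from .quant import WsppModel
from .simulate import SimulationConfig, category_annotations, generate_scan_table

__all__ = ["child_seeds", "null_fdp_experiment"]


def child_seeds(seed: int, n: int) -> np.ndarray:
    """n reproducible independent sub-seeds (each < 2^31) from one seed."""
    return np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32) & 0x7FFFFFFF


def null_fdp_experiment(
    n_datasets: int = 500,
    n_proteins: int = 2000,
    n_categories: int = 200,
    category_size: int = 10,
    alpha: float = 0.05,
    min_size: int = 5,
    seed: int = 0,
    config: SimulationConfig | None = None,
) -> dict:
    """Empirical false-discovery proportion of the category pipeline under
    the complete null.

    Each dataset draws ``n_proteins`` unchanged proteins with the default
    three-level noise and ``n_categories`` disjoint categories of
    ``category_size`` members carrying no coordinated effect, runs
    quantification, Zq standardization, Zc scoring and per-condition
    Benjamini-Hochberg adjustment. Every rejection is false, so each
    dataset x condition contributes V / max(R, 1) and the estimate is the
    mean over all such units.
    """
    base = config or SimulationConfig(
        n_proteins=n_proteins,
        n_null_categories=n_categories,
        null_category_size=category_size,
    )
    fdps, total_rejections = [], 0
    for ds_seed in child_seeds(seed, n_datasets):
        cfg = base.with_seed(int(ds_seed))
        scores = WsppModel(generate_scan_table(cfg)).fit().protein_scores
        scored = category_fdr(
            compute_zc(scores, category_annotations(cfg), min_size=min_size)
        )
        for _, sub in scored.groupby(["region", "timepoint"], sort=False):
            r = int((sub["fdr"] < alpha).sum())
            total_rejections += r
            fdps.append(r / max(r, 1))
    return {
        "fdp": float(np.mean(fdps)),
        "n_datasets": n_datasets,
        "n_units": len(fdps),
        "total_rejections": total_rejections,
        "alpha": alpha,
    }
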