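import numpy as np
import pandas as pd
import pytest

from irproteo.quant import ScanVarianceModel
from irproteo.simulate import CategoryEffect, DistSpec, SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def unit_variance_model():
    """Constant scan variance 1 => unit scan weights."""
    return ScanVarianceModel(edges=np.empty(0), variances=np.array([1.0]))


@pytest.fixture
def small_null_config():
    """A light complete-null design (one region) for fast pipeline tests."""
    return SimulationConfig(
        n_proteins=500,
        peptides_per_protein=DistSpec("geometric", 2.0),
        scans_per_peptide=DistSpec("geometric", 1.5),
        regions=("ischemic",),
        seed=11,
    )


def make_scan_table(rows):
    """Scan table from (scan_id, peptide, protein, region, timepoint, x, intensity) tuples."""
    return pd.DataFrame(
        rows,
        columns=[
            "scan_id",
            "peptide",
            "protein",
            "region",
            "timepoint",
            "log2_ratio",
            "intensity",
        ],
    )


@pytest.fixture
def tiny_scan_table():
    return make_scan_table(
        [
            ("s1", "pepA1", "A", "ischemic", "R-24h", 1.0, 1e6),
            ("s2", "pepA1", "A", "ischemic", "R-24h", 3.0, 1e6),
            ("s3", "pepA2", "A", "ischemic", "R-24h", -1.0, 1e7),
            ("s4", "pepB1", "B", "ischemic", "R-24h", 0.5, 1e6),
        ]
    )
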