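"""Hierarchical weighted quantification: hand oracles, recovery, calibration."""

import numpy as np
import pandas as pd
import pytest

from irproteo.quant import (
    ScanVarianceModel,
    WsppModel,
    aggregate_peptides,
    aggregate_proteins,
    estimate_variance_components,
    fit_scan_variance,
    standardize,
    validate_scan_table,
)
from irproteo.simulate import DistSpec, SimulationConfig, generate_scan_table

from conftest import make_scan_table


def brute_force_means(scans, variance_model, sigma_P2):
    """Independent oracle: naive per-group loops over the raw table."""
    x_p, v_p, x_q, v_q = {}, {}, {}, {}
    for (pep, r, t), sub in scans.groupby(["peptide", "region", "timepoint"]):
        w = 1.0 / np.maximum(variance_model(sub["intensity"].to_numpy()), 1e-12)
        x = sub["log2_ratio"].to_numpy()
        x_p[(pep, r, t)] = np.sum(w * x) / np.sum(w)
        v_p[(pep, r, t)] = 1.0 / np.sum(w)
    for (prot, r, t), sub in scans.groupby(["protein", "region", "timepoint"]):
        peps = sub["peptide"].unique()
        W = np.array([1.0 / (v_p[(p, r, t)] + sigma_P2) for p in peps])
        xs = np.array([x_p[(p, r, t)] for p in peps])
        x_q[(prot, r, t)] = np.sum(W * xs) / np.sum(W)
        v_q[(prot, r, t)] = 1.0 / np.sum(W)
    return x_p, v_p, x_q, v_q


class TestScanVariance:
    def test_homoscedastic_recovery(self, rng):
        """Pooled within-peptide variance recovers sigma_S^2 = 0.04 at 10k scans."""
        n_pep = 2500
        rows = []
        for i in range(n_pep):
            for s in range(4):
                rows.append(
                    (f"s{i}_{s}", f"pep{i}", f"prot{i // 3}", "ischemic", "R-24h",
                     rng.normal(0, 0.2), 1e6)
                )
        model = fit_scan_variance(make_scan_table(rows), n_bins=1)
        assert model.variances[0] == pytest.approx(0.04, abs=0.005)

    def test_zero_noise_gives_zero_variance(self):
        rows = [(f"s{i}{j}", f"pep{i}", "prot0", "ischemic", "R-24h", 0.5, 1e6)
                for i in range(5) for j in range(3)]
        model = fit_scan_variance(make_scan_table(rows), n_bins=1)
        assert model.variances[0] == 0.0

    def test_two_bin_recovery(self, rng):
        """Bin variances (0.09, 0.01) split by intensity half are recovered
        and kept non-increasing."""
        rows = []
        for i in range(3000):
            low = i % 2 == 0
            sd, inten = (0.3, 1e5) if low else (0.1, 1e7)
            for s in range(2):
                rows.append(
                    (f"s{i}_{s}", f"pep{i}", f"prot{i}", "ischemic", "R-24h",
                     rng.normal(0, sd), inten)
                )
        model = fit_scan_variance(make_scan_table(rows), n_bins=2)
        assert model.variances[0] == pytest.approx(0.09, abs=0.01)
        assert model.variances[1] == pytest.approx(0.01, abs=0.005)
        assert model(np.array([1e5, 1e7]))[0] >= model(np.array([1e5, 1e7]))[1]

    def test_unidentifiable_without_replicate_scans(self):
        rows = [(f"s{i}", f"pep{i}", "prot0", "ischemic", "R-24h", 0.1, 1e6) for i in range(5)]
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_scan_variance(make_scan_table(rows))


class TestAggregation:
    def test_single_scan_identity(self, unit_variance_model):
        table = make_scan_table([("s1", "p1", "A", "ischemic", "R-24h", 1.7, 1e6)])
        pep = aggregate_peptides(table, unit_variance_model)
        assert pep["x_p"].iloc[0] == pytest.approx(1.7)
        assert pep["v_p"].iloc[0] == pytest.approx(1.0)  # = sigma_S^2

    def test_equal_weight_mean(self, unit_variance_model):
        table = make_scan_table(
            [("s1", "p1", "A", "ischemic", "R-24h", 1.0, 1e6),
             ("s2", "p1", "A", "ischemic", "R-24h", 3.0, 1e6)]
        )
        assert aggregate_peptides(table, unit_variance_model)["x_p"].iloc[0] == pytest.approx(2.0)

    def test_weighted_mean_hand_example(self):
        # weights (1, 3) on x = (0, 4): weighted mean 3
        model = ScanVarianceModel(edges=np.array([1e6]), variances=np.array([1.0, 1.0 / 3.0]))
        table = make_scan_table(
            [("s1", "p1", "A", "ischemic", "R-24h", 0.0, 1e5),
             ("s2", "p1", "A", "ischemic", "R-24h", 4.0, 1e7)]
        )
        pep = aggregate_peptides(table, model)
        assert pep["x_p"].iloc[0] == pytest.approx(3.0)
        assert pep["v_p"].iloc[0] == pytest.approx(0.25)

    def test_single_peptide_protein_retained(self, unit_variance_model, tiny_scan_table):
        pep = aggregate_peptides(tiny_scan_table, unit_variance_model)
        prot = aggregate_proteins(pep, sigma_P2=0.5)
        b = prot[prot["protein"] == "B"].iloc[0]
        assert b["x_q"] == pytest.approx(0.5)
        assert b["v_q"] == pytest.approx(1.0 + 0.5)  # v_p + sigma_P^2
        assert b["n_peptides"] == 1

    def test_symmetric_peptides_average_to_zero(self, unit_variance_model):
        table = make_scan_table(
            [("s1", "p1", "A", "ischemic", "R-24h", -1.0, 1e6),
             ("s2", "p2", "A", "ischemic", "R-24h", 1.0, 1e6)]
        )
        pep = aggregate_peptides(table, unit_variance_model)
        assert aggregate_proteins(pep, 0.1)["x_q"].iloc[0] == pytest.approx(0.0)

    def test_oracle_equivalence_on_random_table(self, rng, unit_variance_model):
        """x_p and x_q equal brute-force weighted means on a random table."""
        rows = []
        sid = 0
        for prot in range(40):
            for pep in range(rng.integers(1, 6)):
                for s in range(rng.integers(1, 4)):
                    rows.append(
                        (f"s{sid}", f"p{prot}_{pep}", f"prot{prot}", "ischemic",
                         rng.choice(["R-24h", "R-Day7"]), rng.normal(), 10 ** rng.uniform(5, 8))
                    )
                    sid += 1
        table = make_scan_table(rows)
        model = ScanVarianceModel(edges=np.array([1e6, 1e7]), variances=np.array([0.3, 0.1, 0.05]))
        sigma_P2 = 0.2
        pep = aggregate_peptides(table, model)
        prot = aggregate_proteins(pep, sigma_P2)
        bx_p, bv_p, bx_q, bv_q = brute_force_means(table, model, sigma_P2)
        for row in pep.itertuples():
            key = (row.peptide, row.region, row.timepoint)
            assert row.x_p == pytest.approx(bx_p[key], abs=1e-10)
            assert row.v_p == pytest.approx(bv_p[key], abs=1e-12)
        for row in prot.itertuples():
            key = (row.protein, row.region, row.timepoint)
            assert row.x_q == pytest.approx(bx_q[key], abs=1e-10)
            assert row.v_q == pytest.approx(bv_q[key], abs=1e-12)

    def test_adding_data_never_increases_variance(self, unit_variance_model):
        base = [("s1", "p1", "A", "ischemic", "R-24h", 1.0, 1e6)]
        more_scans = base + [("s2", "p1", "A", "ischemic", "R-24h", 0.0, 1e6)]
        v1 = aggregate_peptides(make_scan_table(base), unit_variance_model)["v_p"].iloc[0]
        v2 = aggregate_peptides(make_scan_table(more_scans), unit_variance_model)["v_p"].iloc[0]
        assert v2 <= v1
        more_peps = base + [("s2", "p2", "A", "ischemic", "R-24h", 0.0, 1e6)]
        q1 = aggregate_proteins(
            aggregate_peptides(make_scan_table(base), unit_variance_model), 0.2
        )["v_q"].iloc[0]
        q2 = aggregate_proteins(
            aggregate_peptides(make_scan_table(more_peps), unit_variance_model), 0.2
        )["v_q"].iloc[0]
        assert q2 <= q1


class TestVarianceComponents:
    def test_recovery_of_generator_truth(self):
        cfg = SimulationConfig(n_proteins=2000, sigma_P=0.3, sigma_Q=0.5, seed=21)
        comps = estimate_variance_components(generate_scan_table(cfg))
        assert 0.25 <= np.sqrt(comps.sigma_P2) <= 0.35
        assert 0.45 <= np.sqrt(comps.sigma_Q2) <= 0.55

    def test_zero_noise_gives_zero_components(self):
        cfg = SimulationConfig(n_proteins=100, sigma_S=0.0, sigma_P=0.0, sigma_Q=0.0, seed=2)
        comps = estimate_variance_components(generate_scan_table(cfg))
        assert comps.sigma_P2 <= 1e-6
        assert comps.sigma_Q2 <= 1e-6

    def test_doubling_generator_variances_doubles_components(self):
        base = SimulationConfig(n_proteins=1500, sigma_S=0.2, sigma_P=0.3, sigma_Q=0.4,
                                regions=("ischemic",), seed=5)
        doubled = SimulationConfig(
            n_proteins=1500, sigma_S=0.2 * np.sqrt(2), sigma_P=0.3 * np.sqrt(2),
            sigma_Q=0.4 * np.sqrt(2), regions=("ischemic",), seed=5,
        )
        c1 = estimate_variance_components(generate_scan_table(base))
        c2 = estimate_variance_components(generate_scan_table(doubled))
        assert c2.sigma_P2 / c1.sigma_P2 == pytest.approx(2.0, rel=0.15)
        assert c2.sigma_Q2 / c1.sigma_Q2 == pytest.approx(2.0, rel=0.15)


class TestStandardize:
    def test_protein_at_grand_mean_has_zero_zq(self):
        prot = pd.DataFrame(
            {"protein": ["A", "B", "C"], "region": "ischemic", "timepoint": "R-24h",
             "x_q": [1.0, 1.0, 1.0], "v_q": [0.1, 0.2, 0.3]}
        )
        out = standardize(prot, sigma_Q2=0.5)
        assert np.allclose(out["Zq"], 0.0)

    def test_large_shift_small_variance_limit(self):
        """One protein shifted by +1 log2 with tiny v_q and sigma_Q = 0 gets
        Zq ~ 1/sqrt(v_q)."""
        n = 1000
        prot = pd.DataFrame(
            {"protein": [f"p{i}" for i in range(n)], "region": "ischemic",
             "timepoint": "R-24h", "x_q": [1.0] + [0.0] * (n - 1), "v_q": 1e-8}
        )
        out = standardize(prot, sigma_Q2=0.0)
        assert out["Zq"].iloc[0] == pytest.approx(1.0 / np.sqrt(1e-8), rel=0.01)

    def test_degenerate_variance_rejected(self):
        prot = pd.DataFrame(
            {"protein": ["A"], "region": ["r"], "timepoint": ["t"], "x_q": [0.0], "v_q": [-1.0]}
        )
        with pytest.raises(ValueError):
            standardize(prot, sigma_Q2=0.0)


class TestWsppModel:
    def test_null_zq_is_standard_normal(self):
        """Complete-null pipeline: Zq has mean ~0, SD ~1, and ~5% beyond 1.96."""
        cfg = SimulationConfig(n_proteins=2000, regions=("ischemic",),
                               timepoints=("R-24h",), seed=17)
        scores = WsppModel(generate_scan_table(cfg)).fit().protein_scores
        zq = scores["Zq"].to_numpy()
        assert abs(zq.mean()) < 0.05
        assert 0.95 <= zq.std(ddof=1) <= 1.05
        assert 0.035 <= np.mean(np.abs(zq) > 1.96) <= 0.065

    def test_row_permutation_invariance(self, rng):
        cfg = SimulationConfig(n_proteins=60, seed=13)
        table = generate_scan_table(cfg)
        shuffled = table.sample(frac=1.0, random_state=7).reset_index(drop=True)
        a = WsppModel(table).fit().protein_scores.reset_index(drop=True)
        b = WsppModel(shuffled).fit().protein_scores.reset_index(drop=True)
        pd.testing.assert_frame_equal(a[["protein", "region", "timepoint"]],
                                      b[["protein", "region", "timepoint"]])
        assert np.allclose(a["Zq"], b["Zq"], atol=1e-12)
        assert np.allclose(a["x_q"], b["x_q"], atol=1e-12)

    def test_schema_validation(self, tiny_scan_table):
        with pytest.raises(ValueError, match="missing columns"):
            WsppModel(tiny_scan_table.drop(columns=["intensity"]))
        bad = tiny_scan_table.copy()
        bad.loc[0, "log2_ratio"] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            validate_scan_table(bad)
        shared = tiny_scan_table.copy()
        shared.loc[3, "peptide"] = "pepA1"  # pepA1 now maps to A and B
        with pytest.raises(ValueError, match="multiple proteins"):
            validate_scan_table(shared)

    def test_summary_mentions_components(self):
        cfg = SimulationConfig(n_proteins=80, regions=("ischemic",), seed=3)
        text = WsppModel(generate_scan_table(cfg)).fit().summary()
        assert "sigma_P" in text and "sigma_Q" in text
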