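"""Synthetic-data generators: determinism, degenerate limits, moment contracts."""

import numpy as np
import pandas as pd
import pytest

from irproteo.cmr import GroupSummary
from irproteo.prm import integrate_peak
from irproteo.quant import WsppModel
from irproteo.simulate import (
    ARCHETYPES,
    CategoryEffect,
    DistSpec,
    SimulationConfig,
    category_annotations,
    generate_chromatograms,
    generate_cmr_records,
    generate_labelfree_intensities,
    generate_proteome,
    generate_scan_table,
)


class TestScanTable:
    def test_noise_free_null_is_identically_zero(self):
        cfg = SimulationConfig(n_proteins=50, sigma_S=0.0, sigma_P=0.0, sigma_Q=0.0, seed=1)
        table = generate_scan_table(cfg)
        assert np.all(table["log2_ratio"] == 0.0)

    def test_same_seed_gives_identical_tables(self):
        cfg = SimulationConfig(n_proteins=100, seed=42)
        t1, t2 = generate_scan_table(cfg), generate_scan_table(cfg)
        pd.testing.assert_frame_equal(t1, t2)
        assert t1.to_csv() == t2.to_csv()

    def test_different_seed_differs(self):
        cfg = SimulationConfig(n_proteins=100, seed=42)
        t1 = generate_scan_table(cfg)
        t2 = generate_scan_table(cfg.with_seed(43))
        assert t1.to_csv() != t2.to_csv()

    def test_design_structure(self):
        cfg = SimulationConfig(n_proteins=80, seed=5)
        table = generate_scan_table(cfg)
        # one row per scan per condition, full 2x4 design
        n_scans = table["scan_id"].nunique()
        assert len(table) == n_scans * 8
        assert set(table["region"]) == {"ischemic", "remote"}
        assert set(table["timepoint"]) == set(cfg.timepoints)
        # every peptide belongs to exactly one protein
        assert (table.groupby("peptide")["protein"].nunique() == 1).all()

    def test_counts_match_distribution_in_expectation(self):
        cfg = SimulationConfig(
            n_proteins=2000,
            peptides_per_protein=DistSpec("geometric", 3.0),
            scans_per_peptide=DistSpec("geometric", 2.0),
            regions=("ischemic",),
            seed=9,
        )
        table = generate_scan_table(cfg)
        sub = table[table["timepoint"] == "R-24h"]
        pep_per_prot = sub.groupby("protein")["peptide"].nunique()
        assert pep_per_prot.mean() == pytest.approx(3.0, rel=0.05)
        assert sub.groupby("peptide").size().mean() == pytest.approx(2.0, rel=0.05)

    def test_unknown_archetype_rejected(self):
        with pytest.raises(ValueError, match="archetype"):
            CategoryEffect("x", 10, "no_such_shape", 0.5)

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_proteins=0)
        with pytest.raises(ValueError):
            CategoryEffect("x", 0, "early_sustained_up", 0.5)

    def test_archetype_templates_cover_all_timepoints(self):
        assert set(ARCHETYPES) == {
            "early_sustained_up",
            "early_down_recover",
            "late_up_peak_d7",
            "late_down",
            "transient_early",
        }
        for arch in ARCHETYPES.values():
            assert len(arch.template) == 4


class TestCategories:
    def test_disjoint_membership(self):
        cfg = SimulationConfig(
            n_proteins=200,
            categories=(
                CategoryEffect("c1", 30, "early_sustained_up", 0.5),
                CategoryEffect("c2", 30, "late_down", 0.5),
            ),
            n_null_categories=4,
            seed=3,
        )
        ann = category_annotations(cfg)
        all_members = [p for a in ann for p in a.members]
        assert len(all_members) == len(set(all_members))

    def test_membership_deterministic_and_consistent_with_table(self):
        cfg = SimulationConfig(
            n_proteins=100,
            categories=(CategoryEffect("c1", 20, "early_sustained_up", 0.5),),
            seed=8,
        )
        a1, a2 = category_annotations(cfg), category_annotations(cfg)
        assert [x.members for x in a1] == [x.members for x in a2]
        table = generate_scan_table(cfg)
        assert set(a1[0].members) <= set(table["protein"])

    def test_oversized_categories_rejected(self):
        cfg = SimulationConfig(
            n_proteins=10,
            categories=(CategoryEffect("c1", 20, "early_sustained_up", 0.5),),
            seed=1,
        )
        with pytest.raises(ValueError, match="disjoint"):
            generate_scan_table(cfg)

    def test_injected_effect_is_unbiased_in_x_q(self):
        """A coordinated shift of delta standard deviations is recovered by
        the fitted x_q without systematic bias (Monte-Carlo over seeds)."""
        cfg = SimulationConfig(
            n_proteins=300,
            categories=(CategoryEffect("hit", 40, "early_sustained_up", 0.8),),
            regions=("ischemic",),
            seed=0,
        )
        errors = []
        for seed in range(100):
            c = cfg.with_seed(seed)
            table = generate_scan_table(c)
            members = set(category_annotations(c)[0].members)
            res = WsppModel(table).fit()
            scores = res.protein_scores
            hit = scores[scores["protein"].isin(members)]
            # expected log2 shift: delta * true total SD per protein (the
            # fitted sigma_Q would itself be inflated by the injected effect)
            expected = 0.8 * np.sqrt(hit["v_q"].to_numpy() + c.sigma_Q**2)
            errors.extend(hit["x_q"].to_numpy() - expected)
        assert abs(np.mean(errors)) < 0.02


class TestLabelFree:
    def test_zero_sigma_reproduces_means_exactly(self):
        cfg = SimulationConfig(n_proteins=3, lf_sigma=0.0, n_animals_per_group=2, seed=4)
        proteome = generate_proteome(3, seed=4)
        table = generate_labelfree_intensities(cfg, proteome)
        per_pep = table.groupby(["group", "peptide"])["intensity"].nunique()
        assert (per_pep == 1).all()  # no animal-level scatter

    def test_deterministic(self):
        cfg = SimulationConfig(n_proteins=3, n_animals_per_group=2, seed=4)
        proteome = generate_proteome(3, seed=4)
        pd.testing.assert_frame_equal(
            generate_labelfree_intensities(cfg, proteome),
            generate_labelfree_intensities(cfg, proteome),
        )

    def test_missing_sequences_rejected(self):
        cfg = SimulationConfig(n_proteins=2, seed=1)
        with pytest.raises(ValueError, match="without sequences"):
            generate_labelfree_intensities(cfg, {"P00000": "AAAK" * 10}, {"P00001": 1.0})

    def test_fold_change_two_recovered_in_mean_ibaq_ratio(self):
        """A 2x fold change on one protein gives a mean between-group summed
        intensity ratio of ~2 across seeds."""
        proteome = generate_proteome(4, seed=7)
        ratios = []
        for seed in range(100):
            cfg = SimulationConfig(
                n_proteins=4, n_animals_per_group=3, lf_sigma=0.3, seed=seed
            )
            table = generate_labelfree_intensities(cfg, proteome, {"P00000": 1.0})
            sums = (
                table[table["protein"] == "P00000"]
                .groupby("group")["intensity"]
                .sum()
            )
            ratios.append(sums["R-Day7"] / sums["baseline"])
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.05)


class TestChromatograms:
    def test_zero_amplitude_zero_noise_is_flat(self):
        chroms = generate_chromatograms(["PEP"], 2, (30.0, 2.0, 0.0), 0.0, seed=1)
        assert all(np.all(c.intensities == 0.0) for c in chroms)

    def test_unit_gaussian_area_is_sqrt_two_pi(self):
        chroms = generate_chromatograms(
            ["PEP"], 1, (30.0, 1.0, 1.0), 0.0, seed=1, t_start=25.0, t_end=35.0, dt=0.01
        )
        area = integrate_peak(chroms[0], 25.0, 35.0)
        assert area == pytest.approx(np.sqrt(2 * np.pi), abs=1e-3)

    def test_summed_area_linearity(self):
        chroms = generate_chromatograms(["PEP"], 2, (30.0, 1.5, 2.0), 0.0, seed=1)
        areas = [integrate_peak(c, 20.0, 40.0) for c in chroms]
        both = np.trapezoid(
            chroms[0].intensities + chroms[1].intensities, chroms[0].times
        )
        mask = (chroms[0].times >= 20.0) & (chroms[0].times <= 40.0)
        both_window = np.trapezoid(
            (chroms[0].intensities + chroms[1].intensities)[mask], chroms[0].times[mask]
        )
        assert sum(areas) == pytest.approx(both_window, rel=1e-12)
        assert both >= both_window

    def test_b_and_y_labels(self):
        chroms = generate_chromatograms(["PEP"], 4, (30.0, 1.0, 1.0), 0.0, seed=1)
        assert {c.ion[0] for c in chroms} == {"b", "y"}

    def test_invalid_peak_rejected(self):
        with pytest.raises(ValueError, match="width"):
            generate_chromatograms(["PEP"], 1, (30.0, 0.0, 1.0), 0.0, seed=1)
        with pytest.raises(ValueError, match="time grid"):
            generate_chromatograms(["PEP"], 1, (30.0, 1.0, 1.0), 0.0, seed=1, t_start=10, t_end=5)


class TestCmrRecords:
    def test_moments_matched_exactly(self):
        target = GroupSummary("group1", "ischemic", "baseline", 57.5, 22.1, 5)
        rec = generate_cmr_records([target], seed=3)
        per_animal = (
            rec.groupby("animal")
            .apply(
                lambda df: ((df["eswt_mm"] - df["edwt_mm"]) / df["edwt_mm"] * 100).mean(),
                include_groups=False,
            )
            .to_numpy()
        )
        assert per_animal.mean() == pytest.approx(57.5, abs=1e-9)
        assert per_animal.std(ddof=1) == pytest.approx(22.1, abs=1e-9)

    def test_zero_sd_gives_identical_animals(self):
        rec = generate_cmr_records([GroupSummary("g", "remote", "baseline", 40.0, 0.0, 4)], seed=1)
        assert rec["eswt_mm"].nunique() == 1

    def test_deterministic(self):
        tgt = [GroupSummary("g", "ischemic", "baseline", 50.0, 10.0, 5)]
        pd.testing.assert_frame_equal(
            generate_cmr_records(tgt, seed=9), generate_cmr_records(tgt, seed=9)
        )

    def test_small_n_with_sd_rejected(self):
        with pytest.raises(ValueError):
            GroupSummary("g", "ischemic", "baseline", 50.0, 10.0, 1)
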