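"""Synthetic cohort generator: determinism, calibration, fixture round-trip."""

import dataclasses
import json

import numpy as np
import pandas as pd
import pytest

from ighvstrat.repertoire import BCellSubset, read_clonotype_table
from ighvstrat.simulate import SimConfig, simulate_cohort
from ighvstrat.usage import compute_usage


class TestDeterminism:
    def test_same_seed_identical_outputs(self):
        a = simulate_cohort(SimConfig(n_patients=12), seed=3)
        b = simulate_cohort(SimConfig(n_patients=12), seed=3)
        pd.testing.assert_frame_equal(a.clinical, b.clinical)
        pd.testing.assert_frame_equal(a.usage, b.usage)
        ra = a.repertoire("P0003", BCellSubset.USM)
        rb = b.repertoire("P0003", BCellSubset.USM)
        assert ra.clonotypes == rb.clonotypes

    def test_different_seed_differs(self):
        a = simulate_cohort(SimConfig(n_patients=12), seed=3)
        b = simulate_cohort(SimConfig(n_patients=12), seed=4)
        assert not a.usage.usage.equals(b.usage.usage)

    def test_invalid_config_rejected_before_sampling(self):
        with pytest.raises(ValueError):
            simulate_cohort(SimConfig(n_patients=1))
        with pytest.raises(ValueError):
            simulate_cohort(SimConfig(baseline_usage={"USM": 1.5}))
        with pytest.raises(ValueError):
            simulate_cohort(SimConfig(gene_panel={"IGHV4-34": -1.0}))


class TestUsageCalibration:
    def test_null_usage_near_baseline(self):
        """Zero effect, large samples: usage concentrates at baseline."""
        cfg = SimConfig(
            n_patients=60,
            effect_usage_on_activity=0.0,
            clonotypes_mean=4000.0,
            clonotypes_min=3000,
            dirichlet_concentration=5000.0,
        )
        cohort = simulate_cohort(cfg, seed=5)
        usm = cohort.usage[cohort.usage.subset == "USM"].usage
        se = np.sqrt(0.066 * 0.934 / (3000 * 60)) + 0.066 / np.sqrt(5001 * 60)
        assert usm.mean() == pytest.approx(0.066, abs=4 * se + 0.002)

    def test_degenerate_panel_usage_one(self):
        cfg = SimConfig(
            n_patients=3,
            gene_panel={"IGHV4-34": 1.0},
            baseline_usage={s.value: 0.999999 for s in BCellSubset},
            clonotypes_mean=60.0,
            dirichlet_concentration=1e6,
        )
        cohort = simulate_cohort(cfg, seed=0)
        rep = cohort.repertoire("P0000", "USM")
        assert compute_usage(rep, "IGHV4-34").usage == pytest.approx(1.0, abs=1e-3)

    def test_positive_effect_orders_usage_in_activity(self):
        """Patients at +activity draw higher USM usage than at -activity."""
        cfg = SimConfig(n_patients=200, effect_usage_on_activity=0.35)
        cohort = simulate_cohort(cfg, seed=9)
        merged = cohort.usage[cohort.usage.subset == "USM"].merge(cohort.latent)
        hi = merged[merged.activity > 1].usage.mean()
        lo = merged[merged.activity < -1].usage.mean()
        assert hi > lo

    def test_repertoire_focal_count_matches_usage_matrix(self):
        cohort = simulate_cohort(SimConfig(n_patients=5), seed=2)
        for subset in ("USM", "NAIVE"):
            rep = cohort.repertoire("P0001", subset)
            row = cohort.usage[
                (cohort.usage.patient_id == "P0001") & (cohort.usage.subset == subset)
            ].iloc[0]
            assert compute_usage(rep, "IGHV4-34").usage == pytest.approx(row.usage)
            assert len(rep) == row.n_clonotypes


class TestClinicalCouplings:
    def test_negative_activity_complement_link(self, sim_cohort):
        merged = sim_cohort.clinical.merge(sim_cohort.latent)
        assert np.corrcoef(merged.activity, merged.c4)[0, 1] < 0
        assert np.corrcoef(merged.activity, merged.c3)[0, 1] < 0
        assert np.corrcoef(merged.activity, merged.sledai_2k)[0, 1] > 0

    def test_null_config_decouples_usage_and_complement(self):
        """With all links zeroed, Spearman(usage, C4) centres on 0."""
        from ighvstrat.association import spearman

        rhos = []
        cfg = SimConfig(
            n_patients=50,
            effect_usage_on_activity=0.0,
            c3_activity_slope=0.0,
            c4_activity_slope=0.0,
        )
        for seed in range(200):
            cohort = simulate_cohort(cfg, seed=seed)
            usm = cohort.usage[cohort.usage.subset == "USM"]
            rho, _ = spearman(usm.usage.to_numpy(), cohort.clinical.c4.to_numpy())
            rhos.append(rho)
        assert np.mean(rhos) == pytest.approx(0.0, abs=3 * np.std(rhos) / np.sqrt(200))

    def test_flare_hazard_increases_with_group(self):
        cfg = SimConfig(n_patients=400, flare_hazard_ratio_high=3.0)
        cohort = simulate_cohort(cfg, seed=13)
        usm = cohort.usage[cohort.usage.subset == "USM"].set_index("patient_id").usage
        df = cohort.clinical.set_index("patient_id")
        high = usm >= cfg.flare_group_threshold
        assert df.loc[high[high].index, "flare_event"].mean() > df.loc[
            high[~high].index, "flare_event"
        ].mean()


class TestFixtureSet:
    def test_file_tree_and_roundtrip(self, tmp_path):
        cohort = simulate_cohort(SimConfig(n_patients=3, clonotypes_mean=60.0), seed=1)
        manifest = cohort.write_fixture_set(tmp_path)
        tsvs = sorted(tmp_path.glob("*_*.tsv"))
        assert len(tsvs) == 15
        assert (tmp_path / "clinical.csv").exists()
        assert (tmp_path / "truth.json").exists()
        assert manifest["n_patients"] == 3

        # round-trip: reading a written file reproduces the in-memory sample
        sample = cohort.repertoire("P0002", "SM")
        back = read_clonotype_table(tmp_path / "P0002_SM.tsv", dialect="airr")
        assert set((c.v_gene, c.cdr3_nt, c.count) for c in back.clonotypes) == set(
            (c.v_gene, c.cdr3_nt, c.count) for c in sample.clonotypes
        )

        truth = json.loads((tmp_path / "truth.json").read_text())
        assert len(truth["latent_activity"]) == 3
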