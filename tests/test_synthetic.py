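"""Synthetic cohort generator: determinism, calibration, copula marginals,
item-level consistency, injected-effect recovery."""

import io

import numpy as np
import pandas as pd
import pytest

from resiliometry import scoring
from resiliometry import synthetic as syn
from resiliometry.residuals import compute_resilience_residuals, regress_residuals
from resiliometry.synthetic import (GeneratorConfig, InjectedEffect,
                                    build_target_corr, check_calibration,
                                    generate_cohort, null_effect_config)


class TestDeterminism:
    def test_same_seed_same_bytes(self):
        a = generate_cohort(syn.default_config(200, seed=9))
        b = generate_cohort(syn.default_config(200, seed=9))
        buf_a, buf_b = io.StringIO(), io.StringIO()
        a.table.to_csv(buf_a, index=False)
        b.table.to_csv(buf_b, index=False)
        assert buf_a.getvalue() == buf_b.getvalue()
        assert a.metadata["config_hash"] == b.metadata["config_hash"]

    def test_different_seed_differs(self):
        a = generate_cohort(syn.default_config(200, seed=9))
        b = generate_cohort(syn.default_config(200, seed=10))
        assert not a.table["p_sdq_t2"].equals(b.table["p_sdq_t2"])


class TestCalibration:
    def test_identity_correlation_independence(self):
        names = list(syn.PRIMARY_NAMES)
        cfg = GeneratorConfig(
            n_children=10_000, seed=1,
            target_corr=pd.DataFrame(np.eye(len(names)), index=names, columns=names),
        )
        t = generate_cohort(cfg).table
        emp = t[names].corr().to_numpy()
        np.fill_diagonal(emp, 0)
        assert np.abs(emp).max() < 0.05

    def test_default_surface_at_10k(self, calibrated_cohort_10k):
        cohort, cfg = calibrated_cohort_10k
        rep = check_calibration(cohort, cfg, tolerance=0.05)
        assert rep.passed
        r = cohort.table["p_sdq_t2"].corr(cohort.table["t_sdq_t2"])
        assert r == pytest.approx(0.42, abs=0.03)

    def test_small_sample_fails_tight_tolerance(self):
        cfg = syn.default_config(50, seed=6)
        rep = check_calibration(generate_cohort(cfg), cfg, tolerance=0.01)
        assert not rep.passed

    def test_config_mismatch_error(self, calibrated_cohort_10k):
        cohort, _ = calibrated_cohort_10k
        with pytest.raises(ValueError, match="configuration"):
            check_calibration(cohort, syn.default_config(10_000, seed=999))

    def test_gender_point_biserial(self, calibrated_cohort_10k):
        t = calibrated_cohort_10k[0].table
        r = np.corrcoef(t["gender"], t["t_sdq_t2"])[0, 1]
        assert r == pytest.approx(-0.26, abs=0.04)
        assert t["gender"].mean() == pytest.approx(0.51, abs=0.02)

    def test_scale_scores_within_legal_ranges(self, calibrated_cohort_10k):
        t = calibrated_cohort_10k[0].table
        for v in syn.ANALYSIS_VARIABLES:
            if np.isfinite(v.lo):
                assert t[v.name].min() >= v.lo and t[v.name].max() <= v.hi

    def test_adversity_field_prevalences(self, calibrated_cohort_10k):
        t = calibrated_cohort_10k[0].table
        assert t["benefit_receipt"].mean() == pytest.approx(0.403, abs=0.02)
        assert t["single_parent"].mean() == pytest.approx(0.129, abs=0.015)
        assert (t["n_siblings"] >= 3).mean() == pytest.approx(0.089, abs=0.015)
        assert (t["mother_age_at_birth"] <= 20).mean() == pytest.approx(0.072, abs=0.012)
        assert (t["father_age_at_birth"] <= 20).mean() == pytest.approx(0.020, abs=0.008)
        assert (t["ghq_total"] >= 1).mean() == pytest.approx(0.391, abs=0.02)
        assert t["ghq_total"].mean() == pytest.approx(1.41, abs=0.1)
        assert t["lte_count"].mean() == pytest.approx(0.90, abs=0.06)

    def test_baseline_clinical_rates(self, calibrated_cohort_10k):
        t = calibrated_cohort_10k[0].table
        assert (t["p_sdq_t1"] > 14).mean() == pytest.approx(0.053, abs=0.012)
        assert (t["t_sdq_t1"] > 12).mean() == pytest.approx(0.059, abs=0.012)


class TestConfigValidation:
    def test_minimum_cohort_size(self):
        with pytest.raises(ValueError, match="30"):
            GeneratorConfig(n_children=10)

    def test_unknown_injected_resource(self):
        with pytest.raises(ValueError, match="unknown resource"):
            GeneratorConfig(injected_effects=(
                InjectedEffect("not_a_var", "p_sdq_t2", main_beta=0.2),))

    def test_asymmetric_matrix_rejected(self):
        names = list(syn.PRIMARY_NAMES)
        C = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
        C.iloc[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            GeneratorConfig(target_corr=C)

    def test_mild_psd_violation_repaired_with_warning(self):
        C = build_target_corr({("p_self_esteem", "p_self_efficacy"): 0.999,
                               ("p_self_esteem", "p_self_control"): 0.9,
                               ("p_self_efficacy", "p_self_control"): -0.2})
        cfg = GeneratorConfig(n_children=100, seed=0, target_corr=C,
                              psd_repair_limit=2.0)
        with pytest.warns(UserWarning, match="repaired"):
            generate_cohort(cfg)

    def test_gross_psd_violation_names_eigenvalue(self):
        C = build_target_corr({("p_self_esteem", "p_self_efficacy"): 0.999,
                               ("p_self_esteem", "p_self_control"): 0.9,
                               ("p_self_efficacy", "p_self_control"): -0.2})
        cfg = GeneratorConfig(n_children=100, seed=0, target_corr=C,
                              psd_repair_limit=1e-6)
        with pytest.raises(ValueError, match="eigenvalue"):
            generate_cohort(cfg)


class TestItemLevel:
    @pytest.fixture(scope="class")
    @staticmethod
    def item_cohort():
        return generate_cohort(syn.default_config(400, seed=15, item_level=True)).table

    def test_sum_scale_items_reproduce_totals(self, item_cohort):
        d = scoring.DEFAULT_SCALES["child_parent_rel"]
        cols = [f"p_child_parent_rel_item_{j}" for j in range(1, 16)]
        rescored = [scoring.score_sum_scale(row, d)
                    for row in item_cohort[cols].to_numpy()]
        assert (rescored == item_cohort["p_child_parent_rel"]).all()

    def test_sdq_items_reproduce_totals(self, item_cohort):
        cols = [f"t_sdq_t2_item_{j}" for j in range(1, 26)]
        rescored = [scoring.score_sdq(row, "teacher").total
                    for row in item_cohort[cols].to_numpy()]
        assert (rescored == item_cohort["t_sdq_t2"]).all()

    def test_ghq_items_reproduce_totals(self, item_cohort):
        cols = [f"ghq_item_{j}" for j in range(1, 13)]
        rescored = [scoring.score_ghq12(row)[0] for row in item_cohort[cols].to_numpy()]
        assert (rescored == item_cohort["ghq_total"]).all()

    def test_lte_items_reproduce_counts(self, item_cohort):
        cols = [f"lte_event_{j}" for j in range(1, 13)]
        rescored = [scoring.score_lteq(row) for row in item_cohort[cols].to_numpy()]
        assert (rescored == item_cohort["lte_count"]).all()

    def test_alpha_near_target(self, item_cohort):
        cols = [f"t_self_esteem_item_{j}" for j in range(1, 15)]
        alpha = scoring.cronbach_alpha(item_cohort[cols].to_numpy())
        assert alpha == pytest.approx(0.92, abs=0.08)


class TestInjectedEffects:
    def test_main_effect_recovered_by_residual_regression(self):
        cfg = null_effect_config(5000, seed=21, injected_effects=(
            InjectedEffect("p_self_control", "p_sdq_t2", main_beta=-0.30),))
        t = generate_cohort(cfg).table
        res = compute_resilience_residuals(t, "p_sdq_t2")
        model = regress_residuals(res, t, ("p_self_concept", "p_self_control",
                                           "p_child_parent_rel", "t_child_teacher_rel"))
        # residuals are reverse-coded, so the beneficial effect comes back positive
        assert model.final.betas["p_self_control"] == pytest.approx(0.30, abs=0.05)

    def test_injection_preserves_adversity_link(self):
        cfg = syn.default_config(10_000, seed=22, injected_effects=(
            InjectedEffect("p_self_control", "p_sdq_t2", main_beta=-0.30),))
        t = generate_cohort(cfg).table
        assert t["adversity_index"].corr(t["p_sdq_t2"]) == pytest.approx(0.26, abs=0.04)

    def test_oversized_effects_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            generate_cohort(syn.default_config(100, seed=0, injected_effects=(
                InjectedEffect("p_self_control", "p_sdq_t2", main_beta=0.9),
                InjectedEffect("p_child_parent_rel", "p_sdq_t2", main_beta=0.9),)))
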