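"""Tests for the mixed-model workflows: screen, moderation, Paternoster, MoCA."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from dataclasses import replace
from hypothesis import given, settings, strategies as st
from scipy import stats

from megsni import (
    CohortScenario,
    SniModel,
    default_cohort_scenario,
    fit_lmem,
    generate_cohort,
    moca_models,
    paternoster_z,
    prepare_apoe_factor,
    screen_biomarkers,
)
from megsni.cohort import test_moderation as run_moderation
from megsni.validate import null_scenario


class TestPaternoster:
    def test_equal_slopes_give_zero(self):
        z, p = paternoster_z(0.7, 0.1, 0.7, 2.0)
        assert z == 0.0
        assert p == pytest.approx(1.0)

    def test_pythagorean_denominator(self):
        # (3 - 0) / sqrt(16 + 9) = 3/5
        z, p = paternoster_z(3.0, 4.0, 0.0, 3.0)
        assert z == pytest.approx(0.6, abs=1e-15)
        assert p == pytest.approx(2 * stats.norm.sf(0.6), abs=1e-12)

    @given(
        st.floats(-5, 5), st.floats(0.01, 5), st.floats(-5, 5), st.floats(0.01, 5)
    )
    @settings(max_examples=50)
    def test_antisymmetry(self, b1, se1, b2, se2):
        z_ab, p_ab = paternoster_z(b1, se1, b2, se2)
        z_ba, p_ba = paternoster_z(b2, se2, b1, se1)
        assert z_ab == pytest.approx(-z_ba, abs=1e-12)
        assert p_ab == pytest.approx(p_ba, abs=1e-12)

    @pytest.mark.parametrize("se1,se2", [(0.0, 1.0), (1.0, -0.5)])
    def test_nonpositive_se_rejected(self, se1, se2):
        with pytest.raises(ValueError):
            paternoster_z(1.0, se1, 0.0, se2)


class TestFitLmem:
    def test_ols_limit_single_visit_no_random_intercept(self):
        """One visit/subject and zero subject SD: slopes match OLS to 3 decimals."""
        scen = CohortScenario(
            n_subjects=120,
            visit_weights=(1.0,),
            sni_model=SniModel(subject_sd=0.0, slope_offsets={}),
        )
        t = generate_cohort(scen, seed=7).table
        fit = fit_lmem(t, "sni", covariates=["age", "ptau217"])
        X = sm.add_constant(t[["age", "ptau217"]].astype(float))
        ols = sm.OLS(t["sni"].astype(float), X).fit()
        for name in ("age", "ptau217"):
            assert fit.slope(name)[0] == pytest.approx(ols.params[name], abs=1e-3)

    def test_single_level_factor_rejected(self, cohort_table):
        t = cohort_table.copy()
        t["hhv1"] = 1  # 100% seropositive: no contrast, no model
        with pytest.raises(ValueError, match="single observed level"):
            fit_lmem(t, "sni", covariates=["age"], factors=["hhv1"])

    def test_listwise_deletion_accounting(self, cohort_table):
        fit = fit_lmem(cohort_table, "sni", covariates=["age", "ttau"])
        complete = cohort_table[["sni", "age", "ttau", "subject_id"]].dropna()
        assert fit.n_obs == len(complete)
        assert fit.n_subjects == complete["subject_id"].nunique()

    def test_determinism(self, cohort_table):
        a = fit_lmem(cohort_table, "sni", covariates=["age", "ptau217"])
        b = fit_lmem(cohort_table, "sni", covariates=["age", "ptau217"])
        pd.testing.assert_frame_equal(a.terms, b.terms)

    def test_missing_column_rejected(self, cohort_table):
        with pytest.raises(KeyError):
            fit_lmem(cohort_table, "sni", covariates=["not_a_column"])

    def test_too_few_subjects_rejected(self, cohort_table):
        one = cohort_table[cohort_table["subject_id"] == "S0000"]
        with pytest.raises(ValueError, match="2 subjects"):
            fit_lmem(one, "sni", covariates=["age"])

    def test_ci_covers_estimate(self, cohort_table):
        fit = fit_lmem(cohort_table, "sni", covariates=["age", "ptau217"])
        lo, hi = fit.ci("ptau217")
        b, _ = fit.slope("ptau217")
        assert lo < b < hi


class TestScreen:
    def test_eight_predictors_reported(self, cohort_table):
        scr = screen_biomarkers(cohort_table)
        assert len(scr) == 8
        assert list(scr["predictor"]) == [
            "age", "abeta40", "abeta42", "abeta_ratio", "nfl", "ttau", "ptau181", "ptau217",
        ]

    def test_planted_effect_detected_positive(self, cohort_table):
        """Only pTau217 drives SNI in the generator; the screen must flag it."""
        scr = screen_biomarkers(cohort_table).set_index("predictor")
        assert scr.loc["ptau217", "association"] == "positive"
        assert scr.loc["ptau217", "p"] < 1e-6

    def test_noise_free_p_collapses(self):
        scen = CohortScenario(
            n_subjects=60, sni_model=SniModel(subject_sd=0.0, residual_sd=0.0, slope_offsets={})
        )
        t = generate_cohort(scen, seed=3).table
        scr = screen_biomarkers(t).set_index("predictor")
        assert scr.loc["ptau217", "p"] < 1e-30

    def test_per_biomarker_mode(self, cohort_table):
        scr = screen_biomarkers(cohort_table, joint=False)
        assert len(scr) == 8
        assert scr.set_index("predictor").loc["ptau217", "association"] == "positive"

    def test_all_missing_biomarker_skipped(self, cohort_table):
        t = cohort_table.copy()
        t["nfl"] = np.nan
        with pytest.warns(UserWarning, match="nfl"):
            scr = screen_biomarkers(t)
        assert len(scr) == 7

    def test_holm_adjustment_monotone(self, cohort_table):
        scr = screen_biomarkers(cohort_table, holm=True)
        assert (scr["p_adjusted"] >= scr["p"] - 1e-15).all()


class TestModeration:
    def test_protective_allele_direction(self, cohort_table):
        """Carriers' slope is negative, non-carriers' positive: absent > present."""
        res = run_moderation(cohort_table, "drb1_1301")
        assert res.significant
        assert res.direction == "absent > present"
        assert res.slope_absent[0] > 0
        assert res.slope_present[0] < 0
        assert res.paternoster_z > 0

    def test_z_exactly_matches_stored_slopes(self, cohort_table):
        res = run_moderation(cohort_table, "drb1_1301", always_stratify=True)
        (b1, se1), (b2, se2) = res.slope_absent, res.slope_present
        z_expected = (b1 - b2) / np.sqrt(se1**2 + se2**2)
        assert res.paternoster_z == pytest.approx(z_expected, abs=1e-15)

    def test_label_swap_negates_z(self, cohort_table):
        res = run_moderation(cohort_table, "drb1_1301", always_stratify=True)
        t = cohort_table.copy()
        t["drb1_1301"] = 1 - t["drb1_1301"]
        swapped = run_moderation(t, "drb1_1301", always_stratify=True)
        assert swapped.paternoster_z == pytest.approx(-res.paternoster_z, rel=1e-9)
        assert swapped.paternoster_p == pytest.approx(res.paternoster_p, rel=1e-9)
        assert abs(swapped.interaction_p - res.interaction_p) < 1e-9

    def test_constant_factor_rejected(self, cohort_table):
        t = cohort_table.copy()
        t["hhv1"] = 1
        with pytest.raises(ValueError):
            run_moderation(t, "hhv1")

    def test_gating_suppresses_stratified_fits(self):
        """No moderation in truth and interaction p > alpha: slopes not compared."""
        scen = replace(
            null_scenario(n_subjects=80),
            sni_model=SniModel(ptau217_slope=0.0015, slope_offsets={}),
        )
        t = generate_cohort(scen, seed=4).table
        res = run_moderation(t, "drb1_1301")
        assert not res.significant
        assert res.slope_absent is None
        assert res.paternoster_z is None

    def test_virus_moderation_present_greater(self):
        """A positive serostatus slope offset reports present > absent."""
        scen = replace(
            default_cohort_scenario(), sni_model=SniModel(slope_offsets={"hervk": 0.002})
        )
        t = generate_cohort(scen, seed=2).table
        res = run_moderation(t, "hervk")
        assert res.significant
        assert res.direction == "present > absent"

    def test_apoe_contrast_preparation(self, cohort_table):
        sub = prepare_apoe_factor(cohort_table)
        assert set(sub["apoe_group"].unique()) <= {"ApoE2", "ApoE4"}
        assert set(sub["apoe4"].unique()) <= {0, 1}
        assert len(sub) < len(cohort_table)  # e3e3 / e2e4 / missing rows dropped


class TestMoca:
    def test_age_effect_negative(self, cohort_table):
        res = moca_models(cohort_table)
        b, _ = res.age_model.slope("age")
        assert b < 0
        assert res.age_model.p("age") < 0.001

    def test_ptau_sni_interaction_negative(self, cohort_table):
        res = moca_models(cohort_table)
        fit = res.interaction_model
        assert fit.slope("ptau217:sni")[0] < 0
        assert fit.p("ptau217:sni") < 0.01

    def test_protection_only_in_noncarriers(self, cohort_table):
        """The MoCA interaction survives only in allele-absent strata."""
        res = moca_models(cohort_table)
        for allele in ("drb1_1301", "drb1_1302"):
            assert res.interaction_p(allele, 0) < 0.05
            assert res.interaction_p(allele, 1) > 0.05

    def test_biomarker_models_cover_all_biomarkers(self, cohort_table):
        res = moca_models(cohort_table)
        assert len(res.biomarker_models) == 7
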