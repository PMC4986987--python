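"""Counterfactual recoding and burden measures: no-op at the reference,
monotone attribution, truth recovery on synthetic surveys, profiles and
equity tables."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from lifeburden import burden, exposures, riskengine, synthetic
from lifeburden.burden import (
    burden_estimate,
    equity_table,
    healthy_reference,
    healthy_reference_coded,
    profile_life_expectancy,
)
from lifeburden.exposures import ExposureVector

ALL = ("smoking", "alcohol", "activity", "diet")


def vector(**overrides):
    base = dict(smoking_class="non", time_since_quit=0.0,
                alcohol_class="light_non", mets_per_day=4.0, diet_score=9.0,
                deprivation="low", education="post_sec",
                immigration="born_or_gt_45", heart_disease=False,
                stroke=False, cancer=False, diabetes=False, bmi_ge_35=False)
    base.update(overrides)
    return ExposureVector(**base)


class TestHealthyReference:
    def test_non_smoker_unchanged(self):
        v = vector()
        assert healthy_reference(v, ("smoking",)) == v

    def test_inactive_recoded_to_three_mets(self):
        v = vector(mets_per_day=1.0)
        assert healthy_reference(v, ("activity",)).mets_per_day == 3.0

    def test_active_respondent_untouched(self):
        v = vector(mets_per_day=5.5)
        assert healthy_reference(v, ("activity",)).mets_per_day == 5.5

    def test_former_smoker_recode_zeroes_quit_clock(self):
        v = vector(smoking_class="former_heavy", time_since_quit=8.0)
        out = healthy_reference(v, ("smoking",))
        assert out.smoking_class == "non"
        assert out.time_since_quit == 0.0

    def test_heavy_drinker_to_light_non(self):
        v = vector(alcohol_class="heavy")
        assert healthy_reference(v, ("alcohol",)).alcohol_class == "light_non"
        v = vector(alcohol_class="moderate")
        assert healthy_reference(v, ("alcohol",)).alcohol_class == "moderate"

    def test_full_deletion_on_healthy_is_identity(self):
        v = vector()
        assert healthy_reference(v, ALL) == v

    def test_other_covariates_never_touched(self):
        v = vector(smoking_class="heavy", diabetes=True, deprivation="high",
                   bmi_ge_35=True)
        out = healthy_reference(v, ALL)
        assert out.diabetes and out.bmi_ge_35 and out.deprivation == "high"

    def test_empty_behaviour_set_rejected(self):
        with pytest.raises(ValueError):
            healthy_reference(vector(), ())

    def test_coded_recode_matches_vector_recode(self, coded_survey):
        sub = coded_survey.sample(100, random_state=3).reset_index(drop=True)
        rec = healthy_reference_coded(sub, ALL)
        assert (rec["smoke_heavy"] == 0).all()
        assert (rec["years_since_quit"] == 0).all()
        assert (rec["mets_per_day"] >= 3.0).all()
        assert (rec["diet_score"] >= 8.0).all()
        assert (rec["alc_heavy"] == 0).all()
        # untouched columns identical
        for col in ("age", "weight", "diabetes", "dep_high", "edu_lt_hs"):
            np.testing.assert_array_equal(rec[col], sub[col])


class TestBurdenEstimate:
    def test_survey_at_reference_zero_burden(self, calibrated_algorithms,
                                             coded_survey):
        ref = healthy_reference_coded(coded_survey, ALL)
        est = burden_estimate(calibrated_algorithms, ref, ALL)
        assert est.attributable_deaths == pytest.approx(0.0, abs=1e-9)
        assert est.le_lost == pytest.approx(0.0, abs=1e-9)

    def test_identities_hold(self, calibrated_algorithms, coded_survey):
        est = burden_estimate(calibrated_algorithms, coded_survey, ALL)
        assert est.attributable_deaths == pytest.approx(
            est.baseline_deaths - est.reference_deaths, abs=1e-9)
        assert est.attributable_fraction == pytest.approx(
            est.attributable_deaths / est.baseline_deaths, abs=1e-12)
        assert est.le_lost == pytest.approx(
            est.reference_le - est.baseline_le, abs=1e-12)

    def test_single_burden_below_combined(self, calibrated_algorithms,
                                          coded_survey):
        """With all unhealthy effects adverse in the fitted models, each
        single-behaviour burden is no larger than the four-behaviour one."""
        combined = burden_estimate(calibrated_algorithms, coded_survey, ALL)
        for b in ALL:
            single = burden_estimate(calibrated_algorithms, coded_survey, (b,))
            assert single.attributable_deaths <= \
                combined.attributable_deaths + 1e-6
            assert single.le_lost <= combined.le_lost + 0.05

    def test_counterfactual_risk_never_higher_under_truth(self, coded_survey,
                                                          study_config):
        """With the generator's true coefficients (all unhealthy directions
        adverse), deletion lowers every respondent's risk."""
        truth = truth_algorithms(study_config)
        base = riskengine.apply_to_survey(truth, coded_survey)
        ref = riskengine.apply_to_survey(
            truth, healthy_reference_coded(coded_survey, ALL))
        assert (ref["risk_1y"] <= base["risk_1y"] + 1e-15).all()

    def test_deleting_absent_behaviour_exactly_zero(self, calibrated_algorithms):
        cfg = synthetic.CohortConfig(n=800, seed=41)
        cfg.male.smoking = {"heavy": 0, "light": 0, "former_heavy": 0,
                            "former_light": 0, "non": 1.0}
        cfg.female.smoking = dict(cfg.male.smoking)
        survey = synthetic.generate_cohort(cfg)
        coded, _ = exposures.code_survey(survey)
        est = burden_estimate(calibrated_algorithms, coded, ("smoking",))
        assert est.attributable_deaths == 0.0
        assert est.le_lost == 0.0

    def test_attributable_fraction_recovers_truth(self, coded_survey,
                                                  study_config, algorithms):
        """The fitted estimate lies close to the generator's exact
        counterfactual value (tight agreement at full scale is asserted in
        the acceptance suite via the bootstrap CI)."""
        est = burden_estimate(algorithms, coded_survey, ALL)
        truth = exact_truth_fraction(study_config, coded_survey)
        assert est.attributable_fraction == pytest.approx(truth, abs=0.08)


def truth_algorithms(cfg):
    """Risk algorithms carrying the generator's exact parameters."""
    from lifeburden.exposures import MODEL_TERMS
    algs = {}
    for sex in ("male", "female"):
        h20, b = cfg.sex_config(sex).gompertz
        H = h20 / b * (np.exp(b * (riskengine.AGE_GRID - 20.0)) - 1.0)
        algs[sex] = riskengine.RiskAlgorithm(
            sex=sex, terms=MODEL_TERMS,
            coefficients=np.array([cfg.true_log_hazard_ratios[t]
                                   for t in MODEL_TERMS]),
            s0=np.exp(-H))
    return algs


def exact_truth_fraction(cfg, coded, behaviours=ALL):
    base = riskengine.apply_to_survey(truth_algorithms(cfg), coded)
    ref = riskengine.apply_to_survey(
        truth_algorithms(cfg), healthy_reference_coded(coded, behaviours))
    w = coded["weight"].to_numpy()
    b = np.sum(w * base["risk_1y"])
    r = np.sum(w * ref["risk_1y"])
    return 1.0 - r / b


class TestExternalAttributionHazards:
    def test_own_hazards_reproduce_standard_result(self, calibrated_algorithms,
                                                   coded_survey):
        """Supplying the algorithm's own coefficients as the attribution
        hazards must reproduce the single-model estimate."""
        hazards = {
            s: dict(zip(alg.coefficient_names(), alg.coefficients))
            for s, alg in calibrated_algorithms.items()
        }
        std = burden_estimate(calibrated_algorithms, coded_survey, ("smoking",))
        ext = burden_estimate(calibrated_algorithms, coded_survey, ("smoking",),
                              attribution_hazards=hazards)
        assert ext.attributable_deaths == pytest.approx(
            std.attributable_deaths, rel=1e-9)
        assert ext.le_lost == pytest.approx(std.le_lost, abs=1e-9)

    def test_null_hazards_give_zero_burden(self, calibrated_algorithms,
                                           coded_survey):
        hazards = {
            s: {t: 0.0 for t in
                ("smoke_heavy", "smoke_light", "smoke_former_heavy",
                 "smoke_former_light", "years_since_quit")}
            for s in calibrated_algorithms
        }
        est = burden_estimate(calibrated_algorithms, coded_survey, ("smoking",),
                              attribution_hazards=hazards)
        assert est.attributable_deaths == pytest.approx(0.0, abs=1e-9)

    def test_unknown_term_rejected(self, calibrated_algorithms, coded_survey):
        with pytest.raises(KeyError):
            burden_estimate(calibrated_algorithms, coded_survey, ("smoking",),
                            attribution_hazards={"male": {"bogus": 0.1}})


class TestProfiles:
    def test_healthy_beats_unhealthy(self, calibrated_algorithms, coded_survey):
        healthy = profile_life_expectancy(calibrated_algorithms, coded_survey,
                                          "healthy")
        unhealthy = profile_life_expectancy(calibrated_algorithms,
                                            coded_survey, "unhealthy")
        assert healthy > unhealthy + 3.0

    def test_whole_population_equals_baseline(self, calibrated_algorithms,
                                              coded_survey):
        est = burden_estimate(calibrated_algorithms, coded_survey, ALL)
        le = profile_life_expectancy(calibrated_algorithms, coded_survey, None)
        assert le == pytest.approx(est.baseline_le, abs=1e-9)

    def test_fixed_vector_reference_equals_baseline_survival(self, algorithms):
        """The fixed-vector life expectancy at the all-reference covariate
        vector equals the life table built on the baseline survival."""
        from lifeburden import lifetable
        alg = algorithms["male"]
        ref_vec = vector(mets_per_day=0.0, diet_score=0.0,
                         deprivation="low")
        le = profile_life_expectancy(algorithms, ref_vec, sex="male")
        ages = np.arange(20.0, 100.0)
        log_s0 = np.log(alg.s0)
        risks = 1.0 - np.exp(np.interp(ages + 1, riskengine.AGE_GRID, log_s0)
                             - np.interp(ages, riskengine.AGE_GRID, log_s0))
        direct = lifetable.survey_life_table(risks, ages, np.ones_like(ages))
        assert le == pytest.approx(lifetable.life_expectancy(direct), abs=1e-9)

    def test_empty_profile_errors(self, calibrated_algorithms, coded_survey):
        sub = coded_survey[coded_survey["smoking_class"] == "non"]
        with pytest.raises(ValueError):
            profile_life_expectancy(
                calibrated_algorithms, sub,
                {"smoking": ("heavy",), "alcohol": ("heavy",),
                 "mets_max": 0.0, "diet_max": 0.0})


class TestEquity:
    def test_single_group_equals_overall(self, calibrated_algorithms,
                                         coded_survey):
        df = coded_survey.copy()
        df["everyone"] = "all"
        table = equity_table(calibrated_algorithms, df, "everyone", ALL)
        est = burden_estimate(calibrated_algorithms, coded_survey, ALL)
        assert len(table) == 1
        assert table["attributable_fraction"].iloc[0] == pytest.approx(
            est.attributable_fraction, abs=1e-12)
        assert table["le_lost"].iloc[0] == pytest.approx(est.le_lost, abs=1e-9)

    def test_row_identity(self, calibrated_algorithms, coded_survey):
        table = equity_table(calibrated_algorithms, coded_survey,
                             "education", ("smoking",))
        np.testing.assert_allclose(
            table["le_lost"], table["deleted_le"] - table["baseline_le"],
            atol=1e-9)

    def test_smoking_concentrated_in_low_education(self):
        """When smoking is concentrated in the low-education stratum, that
        stratum shows the largest smoking-attributable loss."""
        cfg = synthetic.CohortConfig(n=25_000, seed=47,
                                     behaviour_ses_corr=0.7)
        survey = synthetic.generate_cohort(cfg)
        coded, _ = exposures.code_survey(survey)
        algs = truth_algorithms(cfg)
        table = equity_table(algs, coded, "education", ("smoking",),
                             sex="male").set_index("group")
        assert table.loc["lt_hs", "le_lost"] == table["le_lost"].max()

    def test_small_group_flagged(self, calibrated_algorithms, coded_survey):
        df = coded_survey.copy()
        df["grp"] = np.where(np.arange(len(df)) < 20, "tiny", "rest")
        table = equity_table(calibrated_algorithms, df, "grp", ALL,
                             min_group_size=50).set_index("group")
        assert table.loc["tiny", "flagged_small"]
        assert not table.loc["rest", "flagged_small"]

    def test_unknown_grouping_errors(self, calibrated_algorithms, coded_survey):
        with pytest.raises(KeyError):
            equity_table(calibrated_algorithms, coded_survey, "zodiac", ALL)
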