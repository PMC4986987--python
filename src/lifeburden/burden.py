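"""Counterfactual healthy-reference recoding and mortality-burden measures.

The burden of a set of unhealthy behaviours is the difference between the
survey's **baseline** mortality (risks predicted from reported exposures)
and its **healthy-reference** mortality (risks predicted after recoding the
behaviours to recommended levels: non-smoker with the time-since-quit term
zeroed; at least 3 METs/day of leisure activity; diet score at least 8;
heavy drinkers moved to light/non).  Recoding is a no-op for respondents
already at the reference, and touches nothing but the listed behaviours —
sociodemographics, diseases and BMI stay fixed, so mediated pathways remain
in the baseline.

Outputs: attributable deaths on a 1-y horizon (sum of weighted calibrated
annual risks), the attributable fraction, and life expectancy lost from
cause-deleted period life tables; plus per-profile life expectancy and
per-group equity tables.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import lifetable, riskengine
from .exposures import BEHAVIOURS, ExposureVector

#: healthy reference levels for the modifiable behaviours
REFERENCE_METS = 3.0
REFERENCE_DIET = 8.0

#: profile definitions (applied to a coded survey frame)
HEALTHY_PROFILE = dict(smoking=("non",), alcohol=("moderate", "light_non"),
                       mets_min=3.0, diet_min=8.0)
UNHEALTHY_PROFILE = dict(smoking=("heavy",), alcohol=("heavy",),
                         mets_max=1.5, diet_max=2.0)


@dataclass
class BurdenEstimate:
    """Baseline vs counterfactual summary for one behaviour set."""

    behaviours: tuple[str, ...]
    sex: str | None
    baseline_le: float
    reference_le: float
    le_lost: float
    baseline_deaths: float
    reference_deaths: float
    attributable_deaths: float
    attributable_fraction: float
    calibrated: bool = True
    n: int = 0
    ci: dict | None = None


def _check_behaviours(behaviours: Sequence[str]) -> tuple[str, ...]:
    bad = [b for b in behaviours if b not in BEHAVIOURS]
    if bad:
        raise ValueError(f"unknown behaviours {bad}; choose from {BEHAVIOURS}")
    if not behaviours:
        raise ValueError("behaviours must be a non-empty subset")
    return tuple(behaviours)


# -- counterfactual recoding -------------------------------------------------


def healthy_reference(vec: ExposureVector,
                      behaviours: Sequence[str]) -> ExposureVector:
    """Recode one exposure vector to the healthy reference for the listed
    behaviours; everything else is untouched."""
    behaviours = _check_behaviours(behaviours)
    changes = {}
    if "smoking" in behaviours:
        changes["smoking_class"] = "non"
        changes["time_since_quit"] = 0.0
    if "activity" in behaviours:
        changes["mets_per_day"] = max(vec.mets_per_day, REFERENCE_METS)
    if "diet" in behaviours:
        changes["diet_score"] = max(vec.diet_score, REFERENCE_DIET)
    if "alcohol" in behaviours and vec.alcohol_class == "heavy":
        changes["alcohol_class"] = "light_non"
    return replace(vec, **changes)


def healthy_reference_coded(coded: pd.DataFrame,
                            behaviours: Sequence[str]) -> pd.DataFrame:
    """Vectorized healthy-reference recode of a coded survey frame."""
    behaviours = _check_behaviours(behaviours)
    out = coded.copy()
    if "smoking" in behaviours:
        for col in ("smoke_heavy", "smoke_light", "smoke_former_heavy",
                    "smoke_former_light", "years_since_quit"):
            out[col] = 0.0
        if "smoking_class" in out:
            out["smoking_class"] = "non"
    if "activity" in behaviours:
        out["mets_per_day"] = np.maximum(
            out["mets_per_day"].to_numpy(dtype=float), REFERENCE_METS)
    if "diet" in behaviours:
        out["diet_score"] = np.maximum(
            out["diet_score"].to_numpy(dtype=float), REFERENCE_DIET)
    if "alcohol" in behaviours:
        heavy = out["alc_heavy"].to_numpy(dtype=float) > 0
        out.loc[heavy, "alc_heavy"] = 0.0
        if "alcohol_class" in out:
            out.loc[heavy, "alcohol_class"] = "light_non"
    return out


# -- burden ------------------------------------------------------------------


def _risks_life_expectancies(risks: pd.DataFrame) -> dict[str, float]:
    """Per-sex life expectancy from a (sex, age, weight, risk_1y) frame."""
    les = {}
    scored = risks.loc[risks["risk_1y"].notna()]
    for sex, sub in scored.groupby("sex", observed=True):
        table = lifetable.survey_life_table(
            sub["risk_1y"], sub["age"], sub["weight"])
        les[sex] = lifetable.life_expectancy(table)
    return les


def _sex_life_expectancies(
    algorithms: Mapping[str, riskengine.RiskAlgorithm],
    coded: pd.DataFrame,
) -> dict[str, float]:
    return _risks_life_expectancies(
        riskengine.apply_to_survey(algorithms, coded))


def _combine_le(les: dict[str, float], coded: pd.DataFrame) -> float:
    """Weight-averaged combined-sex life expectancy (non-canonical summary;
    sex-specific values are the primary outputs)."""
    tw = {sex: coded.loc[coded["sex"] == sex, "weight"].sum() for sex in les}
    total = sum(tw.values())
    return sum(les[s] * tw[s] for s in les) / total


def _attribution_algorithms(
    algorithms: Mapping[str, riskengine.RiskAlgorithm],
    attribution_hazards: Mapping[str, Mapping[str, float]],
) -> dict[str, riskengine.RiskAlgorithm]:
    """Per-sex copies whose selected coefficients carry external log-HRs;
    used only to form the counterfactual linear-predictor shift."""
    from dataclasses import replace as dc_replace
    out = {}
    for s, alg in algorithms.items():
        beta = alg.coefficients.copy()
        names = alg.coefficient_names()
        for term, value in attribution_hazards.get(s, {}).items():
            if term not in names:
                raise KeyError(f"unknown attribution term {term!r}")
            beta[names.index(term)] = value
        out[s] = dc_replace(alg, coefficients=beta, coef_covariance=None)
    return out


def _reference_risks(
    algorithms: Mapping[str, riskengine.RiskAlgorithm],
    coded: pd.DataFrame,
    ref_coded: pd.DataFrame,
    attribution_hazards: Mapping[str, Mapping[str, float]] | None,
) -> pd.DataFrame:
    """Counterfactual 1-y risks: direct re-prediction, or — when external
    attribution hazards are supplied — the survival-scale shift
    risk_ref = factor * [1 - (1 - risk_base_raw)^exp(LP_ref - LP_base)]
    so baseline risk stays the algorithm's own while the reduction follows
    the external hazards."""
    if attribution_hazards is None:
        return riskengine.apply_to_survey(algorithms, ref_coded)
    attr_algs = _attribution_algorithms(algorithms, attribution_hazards)
    out = coded.loc[:, ["id", "sex", "age", "weight"]].copy()
    risk1 = np.full(len(coded), np.nan)
    for s, alg in algorithms.items():
        m = (coded["sex"] == s).to_numpy()
        if not m.any():
            continue
        sub = coded.loc[m]
        sub_ref = ref_coded.loc[m]
        age = sub["age"].to_numpy(dtype=float)
        lp = alg.linear_predictor(sub)
        # uncalibrated baseline risk, then the external-hazard shift
        factor = alg.calibration_factor(age)
        base_cal = alg.predict_risk_lp(lp, age, 1.0, truncate_horizon=True)
        raw_base = np.clip(base_cal / factor, 0.0, 1.0)
        delta = (attr_algs[s].linear_predictor(sub_ref)
                 - attr_algs[s].linear_predictor(sub))
        raw_ref = 1.0 - (1.0 - raw_base) ** np.exp(delta)
        risk1[m] = np.clip(factor * raw_ref, 0.0, 1.0)
    out["risk_1y"] = risk1
    out["risk_5y"] = np.nan
    return out


def burden_estimate(
    algorithms: Mapping[str, riskengine.RiskAlgorithm],
    coded: pd.DataFrame,
    behaviours: Sequence[str],
    sex: str | None = None,
    attribution_hazards: Mapping[str, Mapping[str, float]] | None = None,
) -> BurdenEstimate:
    """Baseline vs healthy-reference burden for a coded (unlinked) survey.

    Attributable deaths use the 1-y calibrated risks (annual death
    framing); life expectancy comes from sex-specific abridged life tables,
    combined across sexes by survey weight when ``sex`` is None.

    ``attribution_hazards`` optionally maps sex -> {term: log-HR} to
    decouple attribution from the fitted model: the counterfactual risk
    reduction then follows the supplied (e.g. causally specified) hazards
    while baseline risk still comes from the algorithm.  The reduction is
    applied on the survival scale:
    risk_ref = 1 - (1 - risk_base)^exp(LP_ref - LP_base).
    """
    behaviours = _check_behaviours(behaviours)
    if sex is not None:
        coded = coded.loc[coded["sex"] == sex]
        algorithms = {sex: algorithms[sex]}
    if len(coded) == 0:
        raise ValueError("empty survey")
    ref_coded = healthy_reference_coded(coded, behaviours)

    base = riskengine.apply_to_survey(algorithms, coded)
    ref = _reference_risks(algorithms, coded, ref_coded, attribution_hazards)
    w = base["weight"].to_numpy(dtype=float)
    base_deaths = float(np.sum(w * base["risk_1y"].to_numpy(dtype=float)))
    ref_deaths = float(np.sum(w * ref["risk_1y"].to_numpy(dtype=float)))

    base_les = _risks_life_expectancies(base)
    ref_les = _risks_life_expectancies(ref)
    if sex is not None:
        base_le = base_les[sex]
        ref_le = ref_les[sex]
    else:
        base_le = _combine_le(base_les, coded)
        ref_le = _combine_le(ref_les, ref_coded)

    attributable = base_deaths - ref_deaths
    return BurdenEstimate(
        behaviours=behaviours,
        sex=sex,
        baseline_le=base_le,
        reference_le=ref_le,
        le_lost=ref_le - base_le,
        baseline_deaths=base_deaths,
        reference_deaths=ref_deaths,
        attributable_deaths=attributable,
        attributable_fraction=attributable / base_deaths if base_deaths else 0.0,
        calibrated=True,
        n=len(coded),
    )


# -- profiles ----------------------------------------------------------------


def profile_mask(coded: pd.DataFrame, profile: str | Mapping) -> np.ndarray:
    """Boolean mask of respondents matching a behaviour profile."""
    if isinstance(profile, str):
        if profile not in ("healthy", "unhealthy"):
            raise ValueError("profile must be 'healthy', 'unhealthy', or a dict")
        profile = HEALTHY_PROFILE if profile == "healthy" else UNHEALTHY_PROFILE
    mask = np.ones(len(coded), dtype=bool)
    if "smoking" in profile:
        mask &= coded["smoking_class"].isin(profile["smoking"]).to_numpy()
    if "alcohol" in profile:
        mask &= coded["alcohol_class"].isin(profile["alcohol"]).to_numpy()
    mets = coded["mets_per_day"].to_numpy(dtype=float)
    diet = coded["diet_score"].to_numpy(dtype=float)
    if "mets_min" in profile:
        mask &= mets >= profile["mets_min"]
    if "mets_max" in profile:
        mask &= mets < profile["mets_max"]
    if "diet_min" in profile:
        mask &= diet >= profile["diet_min"]
    if "diet_max" in profile:
        mask &= diet < profile["diet_max"]
    return mask


def profile_life_expectancy(
    algorithms: Mapping[str, riskengine.RiskAlgorithm],
    coded_or_vector,
    profile: str | Mapping | None = None,
    sex: str | None = None,
) -> float:
    """Life expectancy of the survey subset matching a profile, or of a
    fixed exposure vector (``coded_or_vector`` an :class:`ExposureVector`
    with ``sex`` required)."""
    if isinstance(coded_or_vector, ExposureVector):
        if sex is None:
            raise ValueError("sex is required in fixed-vector mode")
        alg = algorithms[sex]
        ages = np.arange(20.0, 100.0)
        lp = np.full(ages.shape, alg.linear_predictor_vector(coded_or_vector, 50.0))
        if alg.age_interactions:
            # interaction terms vary with age; recompute per age
            lp = np.array([
                alg.linear_predictor_vector(coded_or_vector, a) for a in ages
            ])
        risks = alg.predict_risk_lp(lp, ages, 1.0, truncate_horizon=True)
        table = lifetable.survey_life_table(risks, ages, np.ones_like(ages))
        return lifetable.life_expectancy(table)

    coded = coded_or_vector
    if sex is not None:
        coded = coded.loc[coded["sex"] == sex]
        algorithms = {sex: algorithms[sex]}
    mask = profile_mask(coded, profile) if profile is not None \
        else np.ones(len(coded), dtype=bool)
    if not mask.any():
        raise ValueError("no respondents match the profile")
    sub = coded.loc[mask]
    les = _sex_life_expectancies(algorithms, sub)
    if sex is not None:
        return les[sex]
    return _combine_le(les, sub)


# -- equity ------------------------------------------------------------------


def equity_table(
    algorithms: Mapping[str, riskengine.RiskAlgorithm],
    coded: pd.DataFrame,
    grouping: str,
    behaviours: Sequence[str],
    sex: str | None = None,
    min_group_size: int = 50,
) -> pd.DataFrame:
    """Per-group burden rows (attributable fraction, baseline and
    behaviour-deleted life expectancy, life expectancy lost).

    ``grouping`` is a categorical column of the coded frame (education,
    deprivation, smoking_class, ...).  Groups smaller than
    ``min_group_size`` are flagged.
    """
    if grouping not in coded.columns:
        raise KeyError(f"grouping column {grouping!r} not in survey")
    work = coded.loc[coded["sex"] == sex] if sex is not None else coded
    rows = []
    for value, sub in work.groupby(grouping, sort=True, observed=True):
        est = burden_estimate(algorithms, sub, behaviours, sex=sex)
        rows.append({
            "group": value,
            "n": len(sub),
            "attributable_fraction": est.attributable_fraction,
            "attributable_deaths": est.attributable_deaths,
            "baseline_le": est.baseline_le,
            "deleted_le": est.reference_le,
            "le_lost": est.le_lost,
            "flagged_small": len(sub) < min_group_size,
        })
    return pd.DataFrame(rows)
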