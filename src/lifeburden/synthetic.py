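"""Synthetic survey-like cohorts with known ground-truth mortality hazards.

The generator emulates a national health survey of adults aged 20-99: raw
behaviour answers (smoking, weekly alcohol, METs/day, diet frequencies),
sociodemographics, comorbidity flags and log-normal survey weights, with
per-sex category prevalences defaulting to those of a recent application
survey (e.g. male heavy-smoker share 8.2%).  Mortality follow-up is drawn
from a Gompertz baseline hazard on the age scale multiplied by
exp(true linear predictor), with administrative censoring, so that model
derivation, validation, recalibration and burden estimation can all be
tested against exact truth.

A single latent "unhealthiness" propensity correlates the behaviours with
low education and deprivation, which is what makes equity breakdowns
non-trivial in simulated data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import exposures
from .exposures import MODEL_TERMS, design_matrix

# -- configuration -----------------------------------------------------------

#: default true log hazard ratios, magnitudes in line with behavioural
#: mortality hazards reported for population cohorts (heavy smoking HR ~2.8)
DEFAULT_TRUE_LOG_HRS: dict[str, float] = {
    "smoke_heavy": math.log(2.8),
    "smoke_light": math.log(1.7),
    "smoke_former_heavy": math.log(1.9),
    "smoke_former_light": math.log(1.4),
    # recovery per year since quitting; bounded so a former smoker's total
    # effect never drops below the never-smoker reference within the
    # generator's 1-30 y quit range
    "years_since_quit": -0.010,
    "alc_heavy": math.log(1.3),
    "alc_moderate": math.log(0.9),
    "mets_per_day": -0.09,
    "diet_score": -0.045,
    "dep_moderate": math.log(1.10),
    "dep_high": math.log(1.25),
    "edu_lt_hs": math.log(1.30),
    "edu_hs_grad": math.log(1.15),
    "imm_0_15": math.log(0.70),
    "imm_16_30": math.log(0.80),
    "imm_31_45": math.log(0.90),
    "heart_disease": math.log(1.8),
    "stroke": math.log(1.8),
    "cancer": math.log(2.2),
    "diabetes": math.log(1.6),
    "bmi_ge_35": math.log(1.4),
}

_LOW_CELLS = [(1, 1), (1, 2), (2, 1), (2, 2)]
_HIGH_CELLS = [(4, 4), (4, 5), (5, 4), (5, 5)]
_MODERATE_CELLS = [
    (m, s)
    for m in range(1, 6)
    for s in range(1, 6)
    if (m, s) not in _LOW_CELLS and (m, s) not in _HIGH_CELLS
]


def _lognorm_params(median: float, iqr: tuple[float, float]) -> tuple[float, float]:
    """(mu, sigma) of a log-normal matching a median and interquartile range."""
    mu = math.log(median)
    sigma = math.log(iqr[1] / iqr[0]) / (2 * norm.ppf(0.75))
    return mu, sigma


@dataclass
class SexConfig:
    """Per-sex exposure prevalences and baseline mortality parameters.

    Categorical prevalence dicts must sum to 1.  ``gompertz`` is
    ``(hazard at age 20, log-slope per year of age)``; the defaults were
    chosen so unweighted crude death rates land near 100-130 per 10,000
    person-years, the scale seen in general adult survey cohorts.
    """

    smoking: dict[str, float]
    alcohol: dict[str, float]
    mets_lognorm: tuple[float, float]
    fv_lognorm: tuple[float, float]
    p_high_potato: float
    p_no_carrot: float
    p_high_juice: float
    deprivation: dict[str, float]
    education: dict[str, float]
    immigration: dict[str, float]
    p_heart: float
    p_stroke: float
    p_cancer: float
    p_diabetes: float
    p_bmi35: float
    gompertz: tuple[float, float]
    years_since_quit_range: tuple[float, float] = (1.0, 30.0)


def _default_male() -> SexConfig:
    return SexConfig(
        smoking={"heavy": 0.082, "light": 0.164, "former_heavy": 0.147,
                 "former_light": 0.160, "non": 0.447},
        alcohol={"heavy": 0.203, "moderate": 0.223, "light_non": 0.574},
        mets_lognorm=_lognorm_params(1.6, (0.6, 3.2)),
        fv_lognorm=_lognorm_params(3.3, (2.2, 4.8)),
        p_high_potato=0.109,
        p_no_carrot=0.109,
        p_high_juice=0.156,
        deprivation={"low": 0.176, "moderate": 0.669, "high": 0.155},
        education={"lt_hs": 0.138, "hs_grad": 0.233, "post_sec": 0.629},
        immigration={"imm_0_15": 0.094, "imm_16_30": 0.067,
                     "imm_31_45": 0.050, "born_or_gt_45": 0.789},
        p_heart=0.061, p_stroke=0.010, p_cancer=0.022,
        p_diabetes=0.080, p_bmi35=0.047,
        gompertz=(2.9e-4, 0.092),
    )


def _default_female() -> SexConfig:
    return SexConfig(
        smoking={"heavy": 0.040, "light": 0.147, "former_heavy": 0.076,
                 "former_light": 0.176, "non": 0.561},
        alcohol={"heavy": 0.073, "moderate": 0.203, "light_non": 0.724},
        mets_lognorm=_lognorm_params(1.3, (0.5, 2.7)),
        fv_lognorm=_lognorm_params(4.2, (2.9, 6.0)),
        p_high_potato=0.096,
        p_no_carrot=0.086,
        p_high_juice=0.116,
        deprivation={"low": 0.170, "moderate": 0.673, "high": 0.157},
        education={"lt_hs": 0.142, "hs_grad": 0.242, "post_sec": 0.616},
        immigration={"imm_0_15": 0.099, "imm_16_30": 0.062,
                     "imm_31_45": 0.047, "born_or_gt_45": 0.792},
        p_heart=0.044, p_stroke=0.011, p_cancer=0.020,
        p_diabetes=0.058, p_bmi35=0.056,
        gompertz=(2.0e-4, 0.094),
    )


class ConfigError(ValueError):
    """Invalid cohort configuration (e.g. prevalences not summing to 1)."""


@dataclass
class CohortConfig:
    """Full specification of a synthetic survey population."""

    n: int = 10_000
    seed: int = 0
    sex_split: float = 0.49  # male fraction
    male: SexConfig = field(default_factory=_default_male)
    female: SexConfig = field(default_factory=_default_female)
    true_log_hazard_ratios: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_LOG_HRS)
    )
    horizon_years: float = 5.0
    #: sigma of the log-normal raw survey weights
    weight_sigma: float = 0.5
    #: weights are normalized so each cohort represents this many people
    represented_total: float = 25_300_000.0
    #: Gaussian-copula correlation of every unhealthy draw with one latent
    #: propensity; links behaviours to low education/deprivation
    behaviour_ses_corr: float = 0.35
    #: age ~ 20 + 80 * Beta(a, b); defaults give median ~46, IQR ~33-59
    age_beta: tuple[float, float] = (1.7, 3.4)

    def __post_init__(self):
        if self.n <= 0:
            raise ConfigError("n must be positive")
        if self.horizon_years <= 0:
            raise ConfigError("horizon must be positive")
        if not 0 <= self.sex_split <= 1:
            raise ConfigError("sex_split must be in [0, 1]")
        for sex in ("male", "female"):
            sc = getattr(self, sex)
            for name in ("smoking", "alcohol", "deprivation", "education",
                         "immigration"):
                probs = getattr(sc, name)
                if any(p < 0 for p in probs.values()) or \
                        abs(sum(probs.values()) - 1.0) > 1e-6:
                    raise ConfigError(
                        f"{sex} {name} prevalences must be nonnegative and sum to 1"
                    )

    def sex_config(self, sex: str) -> SexConfig:
        return self.male if sex == "male" else self.female

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CohortConfig":
        raw = json.loads(text)
        for sex in ("male", "female"):
            sc = raw[sex]
            for key in ("mets_lognorm", "fv_lognorm", "gompertz",
                        "years_since_quit_range"):
                sc[key] = tuple(sc[key])
            raw[sex] = SexConfig(**sc)
        raw["age_beta"] = tuple(raw["age_beta"])
        return cls(**raw)


# -- generation --------------------------------------------------------------


def _corr_normal(rng: np.random.Generator, latent: np.ndarray, rho: float) -> np.ndarray:
    """Standard normal draws with correlation ``rho`` to the latent score."""
    eps = rng.standard_normal(latent.shape[0])
    return rho * latent + math.sqrt(1.0 - rho * rho) * eps


def _corr_uniform(rng, latent, rho) -> np.ndarray:
    return norm.cdf(_corr_normal(rng, latent, rho))


def _categorical(u: np.ndarray, probs: Mapping[str, float],
                 unhealthy_last: Sequence[str]) -> np.ndarray:
    """Map correlated uniforms to categories; ``unhealthy_last`` orders the
    levels healthy -> unhealthy so that a high latent score (high u) lands in
    the unhealthy levels."""
    levels = list(unhealthy_last)
    cum = np.cumsum([probs[k] for k in levels])
    cum[-1] = 1.0 + 1e-12
    idx = np.searchsorted(cum, u, side="right")
    return np.asarray(levels, dtype=object)[np.clip(idx, 0, len(levels) - 1)]


def _generate_sex_block(sex: str, n: int, config: CohortConfig,
                        rng: np.random.Generator) -> pd.DataFrame:
    sc = config.sex_config(sex)
    rho = config.behaviour_ses_corr
    latent = rng.standard_normal(n)  # unhealthiness propensity

    a, b = config.age_beta
    age = 20.0 + 80.0 * rng.beta(a, b, size=n)
    age = np.clip(age, 20.0, 99.0)

    # smoking
    u = _corr_uniform(rng, latent, rho)
    smoking = _categorical(
        u, sc.smoking, ("non", "former_light", "former_heavy", "light", "heavy")
    )
    status = np.where(np.isin(smoking, ["heavy", "light"]), "current",
                      np.where(smoking == "non", "never", "former"))
    cigs = np.select(
        [smoking == "heavy", smoking == "former_heavy",
         smoking == "light", smoking == "former_light"],
        [25.0, 25.0, 10.0, 10.0], default=np.nan)
    lo, hi = sc.years_since_quit_range
    tsq = np.where(np.char.startswith(smoking.astype(str), "former"),
                   rng.uniform(lo, hi, size=n), np.nan)
    # quitting cannot predate age 20
    tsq = np.fmin(tsq, np.maximum(age - 20.0, lo))

    # alcohol
    u = _corr_uniform(rng, latent, rho)
    alcohol = _categorical(u, sc.alcohol, ("light_non", "moderate", "heavy"))
    thr = 21.0 if sex == "male" else 14.0
    light_hi = 3.0 if sex == "male" else 2.0
    drinks = np.select(
        [alcohol == "heavy", alcohol == "moderate"],
        [np.floor(thr + 1 + rng.exponential(5.0, size=n)),
         np.floor(rng.uniform(light_hi + 1, thr + 0.999, size=n))],
        default=np.floor(rng.uniform(0, light_hi + 0.999, size=n)))
    max_day = np.where(alcohol == "heavy", 6.0, np.minimum(drinks, 3.0))
    binge = alcohol == "heavy"

    # physical activity (precomputed METs/day path)
    mu, sigma = sc.mets_lognorm
    z = _corr_normal(rng, latent, rho)
    mets = np.clip(np.exp(mu - sigma * z), 0.0, 12.0)

    # diet components
    mu, sigma = sc.fv_lognorm
    z = _corr_normal(rng, latent, rho)
    fv = np.clip(np.exp(mu - sigma * z), 0.0, 12.0)
    u = _corr_uniform(rng, latent, rho)
    pot_thr = 7.0 if sex == "male" else 5.0
    potato = np.where(u > 1 - sc.p_high_potato,
                      pot_thr + rng.uniform(0, 3, size=n),
                      rng.uniform(0, 0.6 * pot_thr, size=n))
    u = _corr_uniform(rng, latent, rho)
    carrot = np.where(u > 1 - sc.p_no_carrot, 0.0, rng.uniform(0.5, 7.0, size=n))
    u = _corr_uniform(rng, latent, rho)
    juice = np.where(u > 1 - sc.p_high_juice,
                     1.0 + rng.uniform(0.5, 4.0, size=n),
                     rng.uniform(0.0, 1.0, size=n))

    # sociodemographics (low SES correlates with the same latent score)
    u = _corr_uniform(rng, latent, rho)
    deprivation = _categorical(u, sc.deprivation, ("low", "moderate", "high"))
    cells = {"low": _LOW_CELLS, "moderate": _MODERATE_CELLS, "high": _HIGH_CELLS}
    mat = np.empty(n, dtype=int)
    soc = np.empty(n, dtype=int)
    for cat, cell_list in cells.items():
        mask = deprivation == cat
        pick = rng.integers(0, len(cell_list), size=int(mask.sum()))
        arr = np.asarray(cell_list)
        mat[mask] = arr[pick, 0]
        soc[mask] = arr[pick, 1]

    u = _corr_uniform(rng, latent, rho)
    education = _categorical(u, sc.education, ("post_sec", "hs_grad", "lt_hs"))
    immigration = _categorical(
        rng.uniform(size=n), sc.immigration,
        ("born_or_gt_45", "imm_31_45", "imm_16_30", "imm_0_15"))

    heart = rng.uniform(size=n) < sc.p_heart
    stroke = rng.uniform(size=n) < sc.p_stroke
    cancer = rng.uniform(size=n) < sc.p_cancer
    diabetes = rng.uniform(size=n) < sc.p_diabetes
    bmi35 = rng.uniform(size=n) < sc.p_bmi35

    raw_w = rng.lognormal(0.0, config.weight_sigma, size=n)

    return pd.DataFrame({
        "sex": sex,
        "age": np.round(age, 2),
        "smoking_status": status,
        "cigs_per_day": cigs,
        "lifetime_cigs_lt_100": np.where(smoking == "non", True, False),
        "years_since_quit": np.round(tsq, 2),
        "drinks_last_week": drinks,
        "max_drinks_any_day_last_week": max_day,
        "weekly_binge": binge,
        "mets_per_day": np.round(mets, 3),
        "fruit_veg_freq_per_day": np.round(fv, 3),
        "juice_freq_per_day": np.round(juice, 3),
        "potato_freq_per_week": np.round(potato, 2),
        "carrot_freq_per_week": np.round(carrot, 2),
        "material_quintile": mat,
        "social_quintile": soc,
        "education": education,
        "years_since_immigration": immigration,
        "heart_disease": heart,
        "stroke": stroke,
        "cancer": cancer,
        "diabetes": diabetes,
        "bmi_ge_35": bmi35,
        "weight": raw_w,
    })


def generate_cohort(config: CohortConfig, n: int | None = None,
                    seed: int | None = None) -> pd.DataFrame:
    """Draw a raw survey frame (no follow-up) reproducibly from ``config``.

    Weights are normalized so the cohort represents
    ``config.represented_total`` people.
    """
    n = int(config.n if n is None else n)
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    n_male = int(round(n * config.sex_split))
    blocks = []
    if n_male:
        blocks.append(_generate_sex_block("male", n_male, config, rng))
    if n - n_male:
        blocks.append(_generate_sex_block("female", n - n_male, config, rng))
    df = pd.concat(blocks, ignore_index=True)
    df.insert(0, "id", np.arange(len(df)))
    df["weight"] *= config.represented_total / df["weight"].sum()
    return df


# -- ground-truth hazards ----------------------------------------------------


def _cum_baseline(age: np.ndarray, h20: float, slope: float) -> np.ndarray:
    """Integrated Gompertz baseline hazard from age 20 to ``age``."""
    age = np.asarray(age, dtype=float)
    if slope == 0.0:
        return h20 * (age - 20.0)
    return h20 / slope * (np.exp(slope * (age - 20.0)) - 1.0)


def _true_linear_predictor(coded: pd.DataFrame, config: CohortConfig) -> np.ndarray:
    beta = np.array([config.true_log_hazard_ratios.get(t, 0.0) for t in MODEL_TERMS])
    return design_matrix(coded) @ beta


def _code_full(cohort: pd.DataFrame) -> pd.DataFrame:
    coded, dropped = exposures.code_survey(cohort)
    if len(dropped):
        raise ConfigError(
            f"generated cohort has {len(dropped)} uncodable records"
        )
    return coded


def simulate_followup(cohort: pd.DataFrame, config: CohortConfig,
                      seed: int | None = None) -> pd.DataFrame:
    """Attach ``(followup_years, died)`` drawn from the ground truth.

    Death ages come from the sex-specific Gompertz baseline on the age scale
    scaled by exp(true linear predictor); follow-up is administratively
    censored at ``config.horizon_years``.
    """
    seed = (config.seed + 1) if seed is None else seed
    rng = np.random.default_rng(seed)
    coded = _code_full(cohort)
    lp = _true_linear_predictor(coded, config)
    age = coded["age"].to_numpy()
    death_age = np.full(len(coded), np.inf)
    for sex in ("male", "female"):
        mask = (coded["sex"] == sex).to_numpy()
        if not mask.any():
            continue
        h20, slope = config.sex_config(sex).gompertz
        e = rng.exponential(size=int(mask.sum()))
        target = _cum_baseline(age[mask], h20, slope) + e / np.exp(lp[mask])
        if h20 == 0.0:
            death_age[mask] = np.inf
        elif slope == 0.0:
            death_age[mask] = 20.0 + target / h20
        else:
            death_age[mask] = 20.0 + np.log1p(slope * target / h20) / slope
    followup = np.minimum(death_age - age, config.horizon_years)
    out = cohort.copy()
    out["followup_years"] = np.round(followup, 6)
    out["died"] = (death_age - age <= config.horizon_years).astype(int)
    return out


def true_annual_risk(cohort: pd.DataFrame, config: CohortConfig,
                     horizon: float = 1.0,
                     counterfactual: Sequence[str] = ()) -> np.ndarray:
    """Exact ``horizon``-year death probability per respondent under the
    generator's truth, optionally after healthy-reference recoding of the
    listed behaviours (the generator's exact counterfactual)."""
    coded = _code_full(cohort)
    if counterfactual:
        from .burden import healthy_reference_coded
        coded = healthy_reference_coded(coded, counterfactual)
    lp = _true_linear_predictor(coded, config)
    age = coded["age"].to_numpy()
    risk = np.empty(len(coded))
    for sex in ("male", "female"):
        mask = (coded["sex"] == sex).to_numpy()
        if not mask.any():
            continue
        h20, slope = config.sex_config(sex).gompertz
        dh = _cum_baseline(age[mask] + horizon, h20, slope) - \
            _cum_baseline(age[mask], h20, slope)
        risk[mask] = 1.0 - np.exp(-dh * np.exp(lp[mask]))
    return risk


DEFAULT_AGE_BINS = tuple((lo, lo + 5) for lo in range(20, 100, 5))


def observed_rate_table(config: CohortConfig,
                        age_bins: Sequence[tuple[float, float]] = DEFAULT_AGE_BINS,
                        n_reference: int = 100_000,
                        seed: int | None = None,
                        perturb: float = 1.0) -> pd.DataFrame:
    """Age-sex annual mortality-rate table computed from the ground truth.

    Mimics the external "observed" rates a national statistics agency would
    publish: the weighted mean true 1-y death risk in each (sex, age-bin)
    cell of a large reference cohort, optionally multiplied by ``perturb``
    to exercise recalibration.  Empty cells are flagged with rate NaN.
    """
    seed = (config.seed + 2) if seed is None else seed
    ref = generate_cohort(config, n=n_reference, seed=seed)
    risk = true_annual_risk(ref, config)
    rows = []
    for sex in ("male", "female"):
        smask = (ref["sex"] == sex).to_numpy()
        for lo, hi in age_bins:
            m = smask & (ref["age"].to_numpy() >= lo) & (ref["age"].to_numpy() < hi)
            if not m.any():
                rate = np.nan
            else:
                w = ref["weight"].to_numpy()[m]
                rate = float(np.average(risk[m], weights=w)) * perturb
            rows.append({"sex": sex, "age_lo": lo, "age_hi": hi, "rate": rate})
    return pd.DataFrame(rows)
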