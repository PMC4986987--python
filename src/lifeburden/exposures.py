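"""Deterministic coding of raw survey answers into model risk factors.

Raw survey records (smoking questions, weekly drink counts, leisure-activity
histories, diet frequencies, neighbourhood deprivation quintiles, ...) are
mapped onto the covariate representation used by the mortality risk model:

* smoking in five mutually exclusive classes (heavy / light current smoker,
  former heavy / light, non-smoker) plus a continuous years-since-quitting
  term for former smokers;
* alcohol in three classes (heavy / moderate / light-or-non), sex-specific
  weekly cut-points with heavy triggered by volume, a single ≥5-drink day,
  or weekly bingeing;
* leisure-time physical activity as average METs per day;
* a 0-10 diet-quality score built from fruit/vegetable, fruit-juice, potato
  and carrot intake frequencies;
* area deprivation collapsed from the 5x5 material x social quintile grid
  into low / moderate / high.

Coding is strictly deterministic and complete-case: a record missing any
model field is excluded with a logged reason rather than imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

# -- category tokens --------------------------------------------------------

SEXES = ("male", "female")
SMOKING_STATUSES = ("current", "former", "never")
SMOKING_CLASSES = ("heavy", "light", "former_heavy", "former_light", "non")
ALCOHOL_CLASSES = ("heavy", "moderate", "light_non")
DEPRIVATION_CLASSES = ("low", "moderate", "high")
EDUCATION_LEVELS = ("lt_hs", "hs_grad", "post_sec")
IMMIGRATION_LEVELS = ("imm_0_15", "imm_16_30", "imm_31_45", "born_or_gt_45")

#: cigarettes per pack; "at least a pack a day" means >= one pack of 20
CIGARETTES_PER_PACK = 20

#: model covariates, in canonical order.  Reference levels (non-smoker,
#: light/non drinker, low deprivation, post-secondary education, born in
#: country or immigrated >45 y ago, disease-free, BMI < 35) carry no term.
MODEL_TERMS = (
    "smoke_heavy",
    "smoke_light",
    "smoke_former_heavy",
    "smoke_former_light",
    "years_since_quit",
    "alc_heavy",
    "alc_moderate",
    "mets_per_day",
    "diet_score",
    "dep_moderate",
    "dep_high",
    "edu_lt_hs",
    "edu_hs_grad",
    "imm_0_15",
    "imm_16_30",
    "imm_31_45",
    "heart_disease",
    "stroke",
    "cancer",
    "diabetes",
    "bmi_ge_35",
)

#: the four modifiable behaviours and the design columns each one drives
BEHAVIOURS = ("smoking", "alcohol", "activity", "diet")
BEHAVIOUR_TERMS = {
    "smoking": ("smoke_heavy", "smoke_light", "smoke_former_heavy",
                "smoke_former_light", "years_since_quit"),
    "alcohol": ("alc_heavy", "alc_moderate"),
    "activity": ("mets_per_day",),
    "diet": ("diet_score",),
}


class ValidationError(ValueError):
    """A raw field is present but outside its legal range."""


class MissingFieldError(KeyError):
    """A model field required for coding is absent; record is excluded."""

    def __init__(self, reason: str):
        self.reason = reason
        super().__init__(reason)


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return False


# -- domain records ----------------------------------------------------------


@dataclass
class Respondent:
    """One survey record: raw answers, sociodemographics, weight, optional
    mortality follow-up (``followup_years``/``died`` present only on linked
    cohorts)."""

    id: object
    sex: str
    age: float
    smoking_status: str | None = None
    cigs_per_day: float | None = None
    lifetime_cigs_lt_100: bool | None = None
    years_since_quit: float | None = None
    drinks_last_week: float | None = None
    max_drinks_any_day_last_week: float | None = None
    weekly_binge: bool | None = None
    activity_records: Sequence[tuple[float, float, float]] | None = None
    mets_per_day: float | None = None
    fruit_veg_freq_per_day: float | None = None
    juice_freq_per_day: float | None = None
    potato_freq_per_week: float | None = None
    carrot_freq_per_week: float | None = None
    material_quintile: int | None = None
    social_quintile: int | None = None
    education: str | None = None
    years_since_immigration: str | None = None
    heart_disease: bool | None = None
    stroke: bool | None = None
    cancer: bool | None = None
    diabetes: bool | None = None
    bmi_ge_35: bool | None = None
    weight: float = 1.0
    followup_years: float | None = None
    died: bool | None = None

    def __post_init__(self):
        if self.sex not in SEXES:
            raise ValidationError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if not (20 <= self.age <= 99):
            raise ValidationError(f"age must be in [20, 99], got {self.age}")
        if not self.weight > 0:
            raise ValidationError(f"survey weight must be positive, got {self.weight}")
        if self.followup_years is not None and self.followup_years < 0:
            raise ValidationError("followup_years must be >= 0")
        if self.cigs_per_day is not None and self.cigs_per_day < 0:
            raise ValidationError("cigs_per_day must be >= 0")


@dataclass
class ExposureVector:
    """Coded covariates for one respondent, ready for the risk model."""

    smoking_class: str
    time_since_quit: float
    alcohol_class: str
    mets_per_day: float
    diet_score: float
    deprivation: str
    education: str
    immigration: str
    heart_disease: bool
    stroke: bool
    cancer: bool
    diabetes: bool
    bmi_ge_35: bool

    def __post_init__(self):
        if self.smoking_class not in SMOKING_CLASSES:
            raise ValidationError(f"bad smoking class {self.smoking_class!r}")
        if self.alcohol_class not in ALCOHOL_CLASSES:
            raise ValidationError(f"bad alcohol class {self.alcohol_class!r}")
        if not 0 <= self.diet_score <= 10:
            raise ValidationError(f"diet score out of [0, 10]: {self.diet_score}")
        if self.time_since_quit > 0 and not self.smoking_class.startswith("former"):
            raise ValidationError("time_since_quit > 0 only valid for former smokers")

    def to_covariates(self) -> dict[str, float]:
        """Numeric design-row values keyed by :data:`MODEL_TERMS`."""
        sc = self.smoking_class
        return {
            "smoke_heavy": float(sc == "heavy"),
            "smoke_light": float(sc == "light"),
            "smoke_former_heavy": float(sc == "former_heavy"),
            "smoke_former_light": float(sc == "former_light"),
            "years_since_quit": float(self.time_since_quit),
            "alc_heavy": float(self.alcohol_class == "heavy"),
            "alc_moderate": float(self.alcohol_class == "moderate"),
            "mets_per_day": float(self.mets_per_day),
            "diet_score": float(self.diet_score),
            "dep_moderate": float(self.deprivation == "moderate"),
            "dep_high": float(self.deprivation == "high"),
            "edu_lt_hs": float(self.education == "lt_hs"),
            "edu_hs_grad": float(self.education == "hs_grad"),
            "imm_0_15": float(self.immigration == "imm_0_15"),
            "imm_16_30": float(self.immigration == "imm_16_30"),
            "imm_31_45": float(self.immigration == "imm_31_45"),
            "heart_disease": float(self.heart_disease),
            "stroke": float(self.stroke),
            "cancer": float(self.cancer),
            "diabetes": float(self.diabetes),
            "bmi_ge_35": float(self.bmi_ge_35),
        }


# -- smoking -----------------------------------------------------------------


def code_smoking(
    status: str,
    cigs_per_day: float | None = None,
    lifetime_cigs_lt_100: bool | None = None,
    years_since_quit: float | None = None,
) -> tuple[str, float]:
    """Classify smoking and return ``(class, time_since_quit)``.

    Current and former smokers split heavy/light at one pack (20 cigarettes)
    per day.  Never-smokers, and former *occasional* smokers with fewer than
    100 lifetime cigarettes, are non-smokers.  Current occasional smokers
    with no daily amount are coded light.  Only former classes carry a
    positive time since quitting.
    """
    if _is_missing(status):
        raise MissingFieldError("missing:smoking_status")
    if status not in SMOKING_STATUSES:
        raise ValidationError(f"smoking status must be one of {SMOKING_STATUSES}")

    if status == "never":
        return "non", 0.0

    if status == "current":
        if _is_missing(cigs_per_day):
            # occasional smoker, no daily amount reported
            return "light", 0.0
        return ("heavy" if cigs_per_day >= CIGARETTES_PER_PACK else "light"), 0.0

    # former
    if lifetime_cigs_lt_100 is True and _is_missing(cigs_per_day):
        # former occasional smoker below the lifetime threshold
        return "non", 0.0
    if _is_missing(cigs_per_day):
        raise MissingFieldError("missing:cigs_per_day")
    if _is_missing(years_since_quit):
        raise MissingFieldError("missing:years_since_quit")
    if years_since_quit < 0:
        raise ValidationError("years_since_quit must be >= 0")
    heavy = cigs_per_day >= CIGARETTES_PER_PACK
    return ("former_heavy" if heavy else "former_light"), float(years_since_quit)


# -- alcohol -----------------------------------------------------------------

_HEAVY_WEEKLY = {"male": 21.0, "female": 14.0}
_LIGHT_UPPER = {"male": 3.0, "female": 2.0}


def code_alcohol(
    sex: str,
    drinks_last_week: float,
    max_drinks_any_day: float = 0.0,
    weekly_binge: bool = False,
) -> str:
    """Classify weekly alcohol consumption as heavy / moderate / light_non.

    Heavy is triggered by any of: more than 21 (men) / 14 (women) drinks in
    the previous week, at least 5 drinks on any single day, or bingeing
    (>=5 drinks on an occasion) on a weekly basis.
    """
    if _is_missing(drinks_last_week):
        raise MissingFieldError("missing:drinks_last_week")
    if drinks_last_week < 0 or (max_drinks_any_day or 0) < 0:
        raise ValidationError("drink counts must be >= 0")
    if sex not in SEXES:
        raise ValidationError(f"sex must be one of {SEXES}")

    if (
        drinks_last_week > _HEAVY_WEEKLY[sex]
        or (max_drinks_any_day or 0) >= 5
        or bool(weekly_binge)
    ):
        return "heavy"
    if drinks_last_week > _LIGHT_UPPER[sex]:
        return "moderate"
    return "light_non"


# -- physical activity -------------------------------------------------------


def mets_per_day(
    activity_records: Iterable[tuple[float, float, float]],
) -> float:
    """Average daily MET-hours of leisure activity over the previous month.

    Each record is ``(met_value, times_per_month, minutes_per_session)``;
    the contribution of an activity is met x monthly hours / 30 days.
    """
    total = 0.0
    for met, times, minutes in activity_records:
        if times < 0 or minutes < 0 or met < 0:
            raise ValidationError("activity records must be nonnegative")
        total += met * (times * minutes / 60.0) / 30.0
    return total


# -- diet --------------------------------------------------------------------

_HIGH_POTATO = {"male": 7.0, "female": 5.0}


def diet_score(
    sex: str,
    fruit_veg_freq_per_day: float,
    juice_freq_per_day: float,
    potato_freq_per_week: float,
    carrot_freq_per_week: float,
) -> float:
    """Diet-quality score on 0-10.

    2 baseline points; +1 per daily fruit/vegetable frequency (juice
    excluded, capped at 8); -2 per daily juice frequency beyond once a day
    (floored at -10); -2 for high potato intake (>=7/week men, >=5 women);
    -2 for no carrot intake.  Negative totals recode to 0; totals above 10
    clamp to 10.
    """
    for v in (fruit_veg_freq_per_day, juice_freq_per_day,
              potato_freq_per_week, carrot_freq_per_week):
        if _is_missing(v):
            raise MissingFieldError("missing:diet")
        if v < 0:
            raise ValidationError("diet frequencies must be >= 0")
    if sex not in SEXES:
        raise ValidationError(f"sex must be one of {SEXES}")

    score = 2.0
    score += min(fruit_veg_freq_per_day, 8.0)
    score -= min(2.0 * max(0.0, juice_freq_per_day - 1.0), 10.0)
    if potato_freq_per_week >= _HIGH_POTATO[sex]:
        score -= 2.0
    if carrot_freq_per_week == 0:
        score -= 2.0
    return min(max(score, 0.0), 10.0)


# -- deprivation -------------------------------------------------------------


def deprivation_category(material_quintile: int, social_quintile: int) -> str:
    """Collapse the 25 material x social quintile cells to low/moderate/high.

    Low when both quintiles are 1 or 2 (4 cells); high when both are 4 or 5
    (4 cells); the remaining 17 cells are moderate.
    """
    for q in (material_quintile, social_quintile):
        if _is_missing(q):
            raise MissingFieldError("missing:deprivation")
        if q not in (1, 2, 3, 4, 5):
            raise ValidationError(f"quintile out of range 1-5: {q}")
    if material_quintile <= 2 and social_quintile <= 2:
        return "low"
    if material_quintile >= 4 and social_quintile >= 4:
        return "high"
    return "moderate"


# -- full vector -------------------------------------------------------------


def build_exposure_vector(r: Respondent) -> ExposureVector:
    """Code one respondent; raises :class:`MissingFieldError` (with a
    ``missing:<field>`` reason) when any model field is absent, implementing
    the complete-case rule."""
    smoking_class, tsq = code_smoking(
        r.smoking_status, r.cigs_per_day, r.lifetime_cigs_lt_100, r.years_since_quit
    )
    if _is_missing(r.drinks_last_week):
        raise MissingFieldError("missing:alcohol")
    alcohol_class = code_alcohol(
        r.sex,
        r.drinks_last_week,
        r.max_drinks_any_day_last_week or 0.0,
        bool(r.weekly_binge),
    )
    if not _is_missing(r.mets_per_day):
        mets = float(r.mets_per_day)
    elif r.activity_records is not None:
        mets = mets_per_day(r.activity_records)
    else:
        raise MissingFieldError("missing:activity")
    try:
        dscore = diet_score(
            r.sex,
            r.fruit_veg_freq_per_day,
            r.juice_freq_per_day,
            r.potato_freq_per_week,
            r.carrot_freq_per_week,
        )
    except MissingFieldError:
        raise MissingFieldError("missing:diet")
    deprivation = deprivation_category(r.material_quintile, r.social_quintile)
    if _is_missing(r.education) or r.education not in EDUCATION_LEVELS:
        raise MissingFieldError("missing:education")
    if (
        _is_missing(r.years_since_immigration)
        or r.years_since_immigration not in IMMIGRATION_LEVELS
    ):
        raise MissingFieldError("missing:immigration")
    for flag in ("heart_disease", "stroke", "cancer", "diabetes", "bmi_ge_35"):
        if _is_missing(getattr(r, flag)):
            raise MissingFieldError(f"missing:{flag}")

    return ExposureVector(
        smoking_class=smoking_class,
        time_since_quit=tsq,
        alcohol_class=alcohol_class,
        mets_per_day=mets,
        diet_score=dscore,
        deprivation=deprivation,
        education=r.education,
        immigration=r.years_since_immigration,
        heart_disease=bool(r.heart_disease),
        stroke=bool(r.stroke),
        cancer=bool(r.cancer),
        diabetes=bool(r.diabetes),
        bmi_ge_35=bool(r.bmi_ge_35),
    )


# -- batch coding ------------------------------------------------------------


def _respondent_from_row(row: pd.Series) -> Respondent:
    kwargs = {}
    valid = {f.name for f in fields(Respondent)}
    for key, value in row.items():
        if key in valid and not _is_missing(value):
            kwargs[key] = value
    return Respondent(**kwargs)


def code_respondents(survey: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Row-by-row reference implementation of :func:`code_survey`."""
    records: list[dict] = []
    dropped: list[dict] = []
    for i, (_, row) in enumerate(survey.iterrows()):
        rid = row.get("id", i)
        try:
            r = _respondent_from_row(row)
            vec = build_exposure_vector(r)
        except MissingFieldError as e:
            dropped.append({"row": i, "id": rid, "reason": e.reason})
            continue
        except (ValidationError, TypeError) as e:
            dropped.append({"row": i, "id": rid, "reason": f"invalid:{e}"})
            continue
        rec = {
            "id": r.id,
            "sex": r.sex,
            "age": float(r.age),
            "weight": float(r.weight),
            "smoking_class": vec.smoking_class,
            "alcohol_class": vec.alcohol_class,
            "deprivation": vec.deprivation,
            "education": vec.education,
            "immigration": vec.immigration,
        }
        if r.followup_years is not None:
            rec["followup_years"] = float(r.followup_years)
            rec["died"] = int(bool(r.died))
        rec.update(vec.to_covariates())
        records.append(rec)

    coded = pd.DataFrame.from_records(records)
    exclusions = pd.DataFrame(dropped, columns=["row", "id", "reason"])
    return coded, exclusions


def _num(survey: pd.DataFrame, col: str) -> np.ndarray:
    if col not in survey.columns:
        return np.full(len(survey), np.nan)
    return pd.to_numeric(survey[col], errors="coerce").to_numpy(dtype=float)


def _obj(survey: pd.DataFrame, col: str) -> np.ndarray:
    if col not in survey.columns:
        return np.full(len(survey), None, dtype=object)
    return survey[col].to_numpy(dtype=object)


def _boolish(survey: pd.DataFrame, col: str) -> tuple[np.ndarray, np.ndarray]:
    """(value, present) for a boolean column with possible NaN."""
    if col not in survey.columns:
        n = len(survey)
        return np.zeros(n, dtype=bool), np.zeros(n, dtype=bool)
    raw = survey[col]
    present = raw.notna().to_numpy()
    val = raw.fillna(False).astype(bool).to_numpy()
    return val, present


def code_survey(survey: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Code a raw survey frame into a design frame (vectorized).

    Returns ``(coded, exclusions)``.  ``coded`` has one row per included
    respondent with id / sex / age / weight, follow-up columns when
    present, the categorical classes, and the numeric :data:`MODEL_TERMS`
    columns.  ``exclusions`` lists (row, id, reason) for complete-case
    drops (reason ``missing:<field>``) and range failures (reason
    ``invalid:...``).  Agrees row-for-row with the scalar coding functions
    (see :func:`code_respondents`).
    """
    n = len(survey)
    reason = np.full(n, None, dtype=object)

    def flag(mask: np.ndarray, why: str) -> None:
        fresh = mask & (reason == None)  # noqa: E711
        reason[fresh] = why

    sex = _obj(survey, "sex")
    age = _num(survey, "age")
    weight = _num(survey, "weight") if "weight" in survey.columns \
        else np.ones(n)
    followup = _num(survey, "followup_years")
    has_followup = "followup_years" in survey.columns
    died = _num(survey, "died")

    # record-level validity (mirrors Respondent invariants)
    flag(~np.isin(sex.astype(str), SEXES), "invalid:sex")
    flag(~((age >= 20) & (age <= 99)), "invalid:age must be in [20, 99]")
    flag(~(weight > 0), "invalid:survey weight must be positive")
    if has_followup:
        flag(np.nan_to_num(followup, nan=0.0) < 0,
             "invalid:followup_years must be >= 0")

    # smoking
    status = _obj(survey, "smoking_status")
    cigs = _num(survey, "cigs_per_day")
    lt100, _ = _boolish(survey, "lifetime_cigs_lt_100")
    tsq_raw = _num(survey, "years_since_quit")
    status_str = status.astype(str)
    flag(cigs < 0, "invalid:cigs_per_day must be >= 0")
    flag(pd.isna(status), "missing:smoking_status")
    known = np.isin(status_str, SMOKING_STATUSES)
    flag(~known & (reason == None), "invalid:smoking status")  # noqa: E711
    former = status_str == "former"
    current = status_str == "current"
    cigs_missing = np.isnan(cigs)
    former_occasional_non = former & lt100 & cigs_missing
    flag(former & ~former_occasional_non & cigs_missing, "missing:cigs_per_day")
    flag(former & ~former_occasional_non & np.isnan(tsq_raw),
         "missing:years_since_quit")
    flag(former & (np.nan_to_num(tsq_raw, nan=0.0) < 0),
         "invalid:years_since_quit must be >= 0")
    heavy_amt = np.nan_to_num(cigs, nan=0.0) >= CIGARETTES_PER_PACK
    smoking_class = np.select(
        [current & heavy_amt, current,
         former_occasional_non,
         former & heavy_amt, former],
        ["heavy", "light", "non", "former_heavy", "former_light"],
        default="non")
    time_since_quit = np.where(
        np.char.startswith(smoking_class.astype(str), "former"),
        np.nan_to_num(tsq_raw, nan=0.0), 0.0)

    # alcohol
    drinks = _num(survey, "drinks_last_week")
    max_day = np.nan_to_num(_num(survey, "max_drinks_any_day_last_week"), nan=0.0)
    binge, _ = _boolish(survey, "weekly_binge")
    flag(np.isnan(drinks), "missing:alcohol")
    flag((drinks < 0) | (max_day < 0), "invalid:drink counts must be >= 0")
    weekly_thr = np.where(sex == "male", 21.0, 14.0)
    light_hi = np.where(sex == "male", 3.0, 2.0)
    alcohol_class = np.select(
        [(drinks > weekly_thr) | (max_day >= 5) | binge,
         drinks > light_hi],
        ["heavy", "moderate"], default="light_non")

    # physical activity (precomputed METs, or per-row activity records)
    mets = _num(survey, "mets_per_day")
    if "activity_records" in survey.columns:
        need = np.isnan(mets) & survey["activity_records"].notna().to_numpy()
        for i in np.nonzero(need)[0]:
            try:
                mets[i] = mets_per_day(survey["activity_records"].iloc[i])
            except ValidationError:
                flag(np.eye(1, n, i, dtype=bool)[0], "invalid:activity records")
    flag(np.isnan(mets), "missing:activity")

    # diet
    fv = _num(survey, "fruit_veg_freq_per_day")
    juice = _num(survey, "juice_freq_per_day")
    potato = _num(survey, "potato_freq_per_week")
    carrot = _num(survey, "carrot_freq_per_week")
    flag(np.isnan(fv) | np.isnan(juice) | np.isnan(potato) | np.isnan(carrot),
         "missing:diet")
    flag((fv < 0) | (juice < 0) | (potato < 0) | (carrot < 0),
         "invalid:diet frequencies must be >= 0")
    pot_thr = np.where(sex == "male", 7.0, 5.0)
    score = (2.0 + np.fmin(fv, 8.0)
             - np.fmin(2.0 * np.fmax(0.0, juice - 1.0), 10.0)
             - 2.0 * (potato >= pot_thr)
             - 2.0 * (carrot == 0))
    diet = np.clip(score, 0.0, 10.0)

    # deprivation
    mat = _num(survey, "material_quintile")
    soc = _num(survey, "social_quintile")
    flag(np.isnan(mat) | np.isnan(soc), "missing:deprivation")
    flag(~(np.isin(np.nan_to_num(mat, nan=1), (1, 2, 3, 4, 5))
           & np.isin(np.nan_to_num(soc, nan=1), (1, 2, 3, 4, 5))),
         "invalid:quintile out of range 1-5")
    deprivation = np.select(
        [(mat <= 2) & (soc <= 2), (mat >= 4) & (soc >= 4)],
        ["low", "high"], default="moderate")

    # sociodemographics / flags
    education = _obj(survey, "education")
    flag(~np.isin(education.astype(str), EDUCATION_LEVELS), "missing:education")
    immigration = _obj(survey, "years_since_immigration")
    flag(~np.isin(immigration.astype(str), IMMIGRATION_LEVELS),
         "missing:immigration")
    flags = {}
    for col in ("heart_disease", "stroke", "cancer", "diabetes", "bmi_ge_35"):
        val, present = _boolish(survey, col)
        flag(~present, f"missing:{col}")
        flags[col] = val

    keep = reason == None  # noqa: E711
    ids = (_obj(survey, "id") if "id" in survey.columns
           else np.arange(n, dtype=object))
    dropped = pd.DataFrame({
        "row": np.nonzero(~keep)[0],
        "id": ids[~keep],
        "reason": reason[~keep],
    }, columns=["row", "id", "reason"])

    coded = pd.DataFrame({
        "id": ids[keep],
        "sex": sex[keep],
        "age": age[keep],
        "weight": weight[keep],
        "smoking_class": smoking_class[keep],
        "alcohol_class": alcohol_class[keep],
        "deprivation": deprivation[keep],
        "education": education[keep],
        "immigration": immigration[keep],
    })
    if has_followup:
        coded["followup_years"] = followup[keep]
        coded["died"] = np.nan_to_num(died[keep], nan=0.0).astype(int)
    sc = smoking_class[keep]
    ac = alcohol_class[keep]
    dep = deprivation[keep]
    edu = education[keep].astype(str)
    imm = immigration[keep].astype(str)
    coded["smoke_heavy"] = (sc == "heavy").astype(float)
    coded["smoke_light"] = (sc == "light").astype(float)
    coded["smoke_former_heavy"] = (sc == "former_heavy").astype(float)
    coded["smoke_former_light"] = (sc == "former_light").astype(float)
    coded["years_since_quit"] = time_since_quit[keep]
    coded["alc_heavy"] = (ac == "heavy").astype(float)
    coded["alc_moderate"] = (ac == "moderate").astype(float)
    coded["mets_per_day"] = mets[keep]
    coded["diet_score"] = diet[keep]
    coded["dep_moderate"] = (dep == "moderate").astype(float)
    coded["dep_high"] = (dep == "high").astype(float)
    coded["edu_lt_hs"] = (edu == "lt_hs").astype(float)
    coded["edu_hs_grad"] = (edu == "hs_grad").astype(float)
    coded["imm_0_15"] = (imm == "imm_0_15").astype(float)
    coded["imm_16_30"] = (imm == "imm_16_30").astype(float)
    coded["imm_31_45"] = (imm == "imm_31_45").astype(float)
    for col, val in flags.items():
        coded[col] = val[keep].astype(float)
    return coded.reset_index(drop=True), dropped.reset_index(drop=True)


def design_matrix(coded: pd.DataFrame, terms: Sequence[str] = MODEL_TERMS) -> np.ndarray:
    """Extract the (n x p) design array for ``terms`` from a coded frame."""
    missing = [t for t in terms if t not in coded.columns]
    if missing:
        raise KeyError(f"coded frame lacks terms: {missing}")
    if len(coded) == 0:
        return np.empty((0, len(terms)))
    return coded.loc[:, list(terms)].to_numpy(dtype=float)
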