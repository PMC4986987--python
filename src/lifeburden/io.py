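"""File formats, run configuration and end-to-end pipeline orchestration.

Tabular data (surveys, observed-rate tables, life tables, burden and
equity outputs) travel as UTF-8 CSV; risk algorithms, model specs and run
configurations as JSON/YAML.  Survey reading is schema-checked: mandatory
columns must be present (error naming the column), extra columns are
preserved but ignored, and rows failing validation (e.g. age outside
20-99) are excluded with a per-row log entry rather than aborting.

``run_pipeline`` chains the full analysis — simulate (or load) a linked
derivation cohort, fit sex-specific models, validate, apply to an unlinked
survey, recalibrate to observed rates, build life tables, estimate burden
with bootstrap CIs and equity breakdowns — and writes a provenance
manifest (input hashes, config, version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import burden as burden_mod
from . import hazard, lifetable, riskengine, synthetic, uncertainty, validation

logger = logging.getLogger(__name__)

MANDATORY_SURVEY_COLUMNS = ("sex", "age", "weight")

_BOOL_COLUMNS = (
    "lifetime_cigs_lt_100", "weekly_binge", "heart_disease", "stroke",
    "cancer", "diabetes", "bmi_ge_35",
)
_NUMERIC_COLUMNS = (
    "age", "cigs_per_day", "years_since_quit", "drinks_last_week",
    "max_drinks_any_day_last_week", "mets_per_day", "fruit_veg_freq_per_day",
    "juice_freq_per_day", "potato_freq_per_week", "carrot_freq_per_week",
    "weight", "followup_years",
)


class SurveyFormatError(ValueError):
    pass


def _parse_bool(series: pd.Series) -> pd.Series:
    mapping = {"true": True, "false": False, "1": True, "0": False,
               "yes": True, "no": False}
    def conv(v):
        if pd.isna(v):
            return np.nan
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        return mapping.get(str(v).strip().lower(), np.nan)
    return series.map(conv)


def read_survey(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a respondent CSV; returns ``(survey, row_report)``.

    ``row_report`` lists excluded rows with 1-based row numbers and
    reasons.  Raises :class:`SurveyFormatError` naming any missing
    mandatory column.
    """
    df = pd.read_csv(path)
    for col in MANDATORY_SURVEY_COLUMNS:
        if col not in df.columns:
            raise SurveyFormatError(f"missing column: {col}")
    report = []
    for col in _NUMERIC_COLUMNS:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        for i in np.nonzero(bad.to_numpy())[0]:
            report.append({"row": int(i) + 1, "id": df.iloc[i].get("id", i),
                           "reason": f"unparseable:{col}"})
        df[col] = coerced
    for col in _BOOL_COLUMNS:
        if col in df.columns:
            df[col] = _parse_bool(df[col])
    if "died" in df.columns:
        df["died"] = pd.to_numeric(df["died"], errors="coerce")

    bad_rows = pd.Series(False, index=df.index)
    if report:
        bad_rows[[r["row"] - 1 for r in report]] = True
    age_bad = ~df["age"].between(20, 99)
    for i in np.nonzero((age_bad & ~bad_rows).to_numpy())[0]:
        report.append({"row": int(i) + 1, "id": df.iloc[i].get("id", i),
                       "reason": "invalid:age outside [20, 99]"})
    bad_rows |= age_bad
    w_bad = ~(df["weight"] > 0)
    for i in np.nonzero((w_bad & ~bad_rows).to_numpy())[0]:
        report.append({"row": int(i) + 1, "id": df.iloc[i].get("id", i),
                       "reason": "invalid:nonpositive weight"})
    bad_rows |= w_bad

    kept = df.loc[~bad_rows].reset_index(drop=True)
    for r in report:
        logger.warning("survey row %d excluded: %s", r["row"], r["reason"])
    return kept, pd.DataFrame(report, columns=["row", "id", "reason"])


def write_survey(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_rate_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    needed = {"sex", "age_lo", "age_hi", "rate"}
    missing = needed - set(df.columns)
    if missing:
        raise SurveyFormatError(f"rate table missing columns: {sorted(missing)}")
    return df


def write_rate_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


# -- run configuration -------------------------------------------------------


@dataclass
class RunConfig:
    """End-to-end pipeline settings; paths are optional — absent inputs are
    simulated from the default synthetic population."""

    out_dir: str = "lifeburden_out"
    seed: int = 0
    survey_path: str | None = None          # unlinked application survey
    derivation_path: str | None = None      # linked cohort (followup + died)
    observed_rates_path: str | None = None
    algorithm_paths: dict | None = None     # {"male": ..., "female": ...}
    n_derivation: int = 50_000
    n_application: int = 20_000
    behaviours: tuple[str, ...] = ("smoking", "alcohol", "activity", "diet")
    group_by: tuple[str, ...] = ("education", "deprivation")
    bootstrap_B: int = 200
    horizon: float = 5.0
    log_level: str = "INFO"

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        raw = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("behaviours", "group_by"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def run_pipeline(config: RunConfig) -> dict:
    """Run derivation -> validation -> application end to end.

    Returns a manifest dict (also written to ``manifest.json``) listing the
    outputs, input hashes and headline numbers.  All randomness derives
    from ``config.seed``; reruns are numerically identical.
    """
    from . import __version__
    from .exposures import code_survey

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    stage = "setup"
    input_hashes = {}
    try:
        # -- inputs / simulation --------------------------------------------
        stage = "derivation-data"
        cohort_config = synthetic.CohortConfig(
            n=config.n_derivation, seed=config.seed)
        if config.derivation_path:
            input_hashes["derivation"] = sha256_file(config.derivation_path)
            linked, _ = read_survey(config.derivation_path)
        else:
            linked = synthetic.simulate_followup(
                synthetic.generate_cohort(cohort_config), cohort_config)
        coded_linked, excl = code_survey(linked)
        logger.info("derivation cohort: %d records, %d excluded",
                    len(coded_linked), len(excl))

        stage = "fit"
        algorithms = {}
        fit_rows = []
        for sex in ("male", "female"):
            if config.algorithm_paths and sex in config.algorithm_paths:
                p = config.algorithm_paths[sex]
                input_hashes[f"algorithm_{sex}"] = sha256_file(p)
                algorithms[sex] = riskengine.algorithm_from_json(
                    Path(p).read_text())
                continue
            spec = hazard.ModelSpec(sex=sex)
            model = hazard.fit_ph(coded_linked, spec)
            algorithms[sex] = hazard.extract_algorithm(model)
            fit_rows.append({"sex": sex, "n": model.n,
                             "deaths": model.n_deaths,
                             "person_years": model.person_years})
            (out / f"algorithm_{sex}.json").write_text(
                riskengine.algorithm_to_json(algorithms[sex]))
        if fit_rows:
            pd.DataFrame(fit_rows).to_csv(out / "fit_summary.csv", index=False)

        stage = "validate"
        val_rows = []
        for sex, alg in algorithms.items():
            rep = validation.validate_algorithm(
                coded_linked, alg, horizon=config.horizon,
                n_bootstrap=0, seed=config.seed)
            val_rows.append({"sex": sex, "c_statistic": rep.c_statistic,
                             "ratio_90_10": rep.ratio_90_10})
            rep.decile_table.assign(sex=sex).to_csv(
                out / f"calibration_deciles_{sex}.csv", index=False)
        validation_summary = pd.DataFrame(val_rows)
        validation_summary.to_csv(out / "validation.csv", index=False)

        stage = "application-data"
        if config.survey_path:
            input_hashes["survey"] = sha256_file(config.survey_path)
            survey, _ = read_survey(config.survey_path)
        else:
            survey = synthetic.generate_cohort(
                cohort_config, n=config.n_application,
                seed=config.seed + 10)
        coded_survey, excl = code_survey(survey)
        logger.info("application survey: %d records, %d excluded",
                    len(coded_survey), len(excl))

        stage = "calibrate"
        if config.observed_rates_path:
            input_hashes["observed_rates"] = sha256_file(
                config.observed_rates_path)
            rates = read_rate_table(config.observed_rates_path)
        else:
            rates = synthetic.observed_rate_table(
                cohort_config, seed=config.seed + 20)
        write_rate_table(rates, out / "observed_rates.csv")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            algorithms = {
                sex: riskengine.recalibrate(alg, coded_survey, rates)
                for sex, alg in algorithms.items()
            }

        stage = "lifetable"
        risks = riskengine.apply_to_survey(algorithms, coded_survey)
        le = {}
        for sex in algorithms:
            m = risks["sex"] == sex
            table = lifetable.survey_life_table(
                risks.loc[m, "risk_1y"], risks.loc[m, "age"],
                risks.loc[m, "weight"])
            ci = lifetable.le_variance(table)
            table.to_csv(out / f"life_table_{sex}.csv", index=False)
            le[sex] = {"life_expectancy": ci["life_expectancy"],
                       "se": ci["se"], "ci": list(ci["ci"])}

        stage = "burden"
        boot_cfg = uncertainty.BootstrapConfig(
            B=config.bootstrap_B, seed=config.seed + 30)
        est = uncertainty.bootstrap_burden(
            algorithms, coded_survey, config.behaviours, boot_cfg)
        burden_frame = pd.DataFrame([dataclasses.asdict(est)])
        burden_frame.to_csv(out / "burden.csv", index=False)

        singles = []
        for b in config.behaviours:
            e = burden_mod.burden_estimate(algorithms, coded_survey, (b,))
            singles.append({"behaviour": b,
                            "attributable_deaths": e.attributable_deaths,
                            "attributable_fraction": e.attributable_fraction,
                            "le_lost": e.le_lost})
        pd.DataFrame(singles).to_csv(out / "burden_by_behaviour.csv",
                                     index=False)

        stage = "equity"
        for grouping in config.group_by:
            eq = burden_mod.equity_table(
                algorithms, coded_survey, grouping, config.behaviours)
            eq.to_csv(out / f"equity_{grouping}.csv", index=False)

        stage = "manifest"
        manifest = {
            "version": __version__,
            "config": dataclasses.asdict(config),
            "input_hashes": input_hashes,
            "life_expectancy": le,
            "validation": validation_summary.to_dict(orient="records"),
            "burden": {
                "behaviours": list(est.behaviours),
                "le_lost": est.le_lost,
                "attributable_deaths": est.attributable_deaths,
                "attributable_fraction": est.attributable_fraction,
                "ci": est.ci,
            },
            "outputs": sorted(p.name for p in out.iterdir()),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest
    except Exception as e:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {e}") from e
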