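"""Risk prediction and external recalibration.

A :class:`RiskAlgorithm` is a self-contained, serializable sex-specific
scoring rule: model terms with log-hazard-ratio coefficients, a baseline
survival curve S0 on an integer age grid (20-100), and multiplicative
age-bin calibration factors (default 1).  The ``h``-year death risk of a
respondent aged ``a`` with linear predictor LP is

    risk = factor(age bin) * [1 - (S0(a+h) / S0(a)) ** exp(LP)]

clamped to [0, 1]; log S0 is linearly interpolated between grid ages.

Recalibration against an external observed age-sex mortality-rate table
multiplies each bin's factor by O/P, the ratio of the observed rate to the
survey-weighted mean predicted annual risk in the bin, so that after one
pass the weighted predicted bin rates reproduce the observed table exactly
and a second pass changes nothing.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .exposures import ExposureVector, design_matrix

AGE_GRID = np.arange(20, 101)

DEFAULT_CALIBRATION_BINS = tuple((lo, lo + 5) for lo in range(20, 100, 5))


class RecalibrationError(ValueError):
    """Observed-rate table does not cover the survey's age bins."""


def _default_calibration(bins=DEFAULT_CALIBRATION_BINS) -> pd.DataFrame:
    return pd.DataFrame(
        {"age_lo": [b[0] for b in bins],
         "age_hi": [b[1] for b in bins],
         "factor": 1.0}
    )


@dataclass
class RiskAlgorithm:
    """Sex-specific mortality risk scoring rule (see module docstring)."""

    sex: str
    terms: tuple[str, ...]
    coefficients: np.ndarray          # aligned with coefficient_names()
    s0: np.ndarray                    # baseline survival on AGE_GRID
    age_interactions: tuple[str, ...] = ()
    age_center: float = 50.0
    coef_covariance: np.ndarray | None = None
    calibration: pd.DataFrame = field(default_factory=_default_calibration)
    schema_version: int = 1

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.s0 = np.asarray(self.s0, dtype=float)
        if self.s0.shape != AGE_GRID.shape:
            raise ValueError("s0 must be on the integer age grid 20..100")
        if np.any(self.s0 <= 0) or np.any(self.s0 > 1.0 + 1e-12):
            raise ValueError("S0 must lie in (0, 1]")
        if np.any(np.diff(self.s0) > 1e-12):
            raise ValueError("S0 must be non-increasing in age")
        if len(self.coefficients) != len(self.coefficient_names()):
            raise ValueError("coefficient vector does not match term list")
        if np.any(self.calibration["factor"].to_numpy() <= 0):
            raise ValueError("calibration factors must be positive")

    def coefficient_names(self) -> list[str]:
        return list(self.terms) + [f"age_x_{t}" for t in self.age_interactions]

    # -- linear predictor ----------------------------------------------------

    def linear_predictor(self, coded: pd.DataFrame) -> np.ndarray:
        """LP for each row of a coded frame (uses its ``age`` column for
        age x behaviour interaction terms)."""
        X = design_matrix(coded, self.terms)
        p = len(self.terms)
        lp = X @ self.coefficients[:p]
        if self.age_interactions:
            age = coded["age"].to_numpy(dtype=float)
            Xi = design_matrix(coded, self.age_interactions)
            lp = lp + (Xi * (age - self.age_center)[:, None]) @ self.coefficients[p:]
        return lp

    def linear_predictor_vector(self, vec: ExposureVector, age: float) -> float:
        cov = vec.to_covariates()
        row = pd.DataFrame([cov])
        row["age"] = age
        return float(self.linear_predictor(row)[0])

    # -- prediction ----------------------------------------------------------

    def _log_s0(self, age: np.ndarray) -> np.ndarray:
        return np.interp(age, AGE_GRID, np.log(self.s0))

    def calibration_factor(self, age: np.ndarray) -> np.ndarray:
        """Factor of the calibration bin containing each (start) age; ages
        outside every bin take factor 1."""
        age = np.atleast_1d(np.asarray(age, dtype=float))
        lo = self.calibration["age_lo"].to_numpy(dtype=float)
        hi = self.calibration["age_hi"].to_numpy(dtype=float)
        fac = self.calibration["factor"].to_numpy(dtype=float)
        out = np.ones_like(age)
        idx = np.searchsorted(lo, age, side="right") - 1
        valid = (idx >= 0) & (age < hi[np.clip(idx, 0, len(hi) - 1)])
        out[valid] = fac[idx[valid]]
        return out

    def predict_risk_lp(self, lp: np.ndarray, age: np.ndarray,
                        horizon_years: float,
                        truncate_horizon: bool = False) -> np.ndarray:
        """Death risk over ``horizon_years`` given linear predictors.

        With ``truncate_horizon`` the horizon is shortened so the endpoint
        never exceeds the top of the age grid (used for whole-survey sweeps
        where respondents near the table's upper bound remain scoreable).
        """
        age = np.asarray(age, dtype=float)
        lp = np.asarray(lp, dtype=float)
        if np.any(age < AGE_GRID[0]):
            raise ValueError("age below the algorithm's age grid")
        end = age + horizon_years
        if truncate_horizon:
            end = np.minimum(end, AGE_GRID[-1])
        elif np.any(end > AGE_GRID[-1]):
            raise ValueError("age + horizon exceeds the algorithm's age grid")
        log_ratio = self._log_s0(end) - self._log_s0(age)
        raw = 1.0 - np.exp(np.exp(lp) * log_ratio)
        return np.clip(self.calibration_factor(age) * raw, 0.0, 1.0)


def predict_risk(algorithm: RiskAlgorithm, exposure: ExposureVector,
                 age: float, horizon_years: float = 5.0) -> float:
    """Calibrated death risk over 1 or 5 years for one respondent."""
    lp = algorithm.linear_predictor_vector(exposure, age)
    return float(
        algorithm.predict_risk_lp(np.array([lp]), np.array([age]),
                                  horizon_years)[0]
    )


def apply_to_survey(algorithms: Mapping[str, RiskAlgorithm],
                    coded: pd.DataFrame) -> pd.DataFrame:
    """Per-respondent annual and 5-y calibrated risks for a coded survey.

    For respondents within 5 years of the top of the age grid the 5-y
    horizon is truncated at the grid end.  Row order is preserved.
    """
    out = coded.loc[:, ["id", "sex", "age", "weight"]].copy()
    risk1 = np.full(len(coded), np.nan)
    risk5 = np.full(len(coded), np.nan)
    for sex, alg in algorithms.items():
        mask = (coded["sex"] == sex).to_numpy()
        if not mask.any():
            continue
        sub = coded.loc[mask]
        lp = alg.linear_predictor(sub)
        age = sub["age"].to_numpy(dtype=float)
        risk1[mask] = alg.predict_risk_lp(lp, age, 1.0, truncate_horizon=True)
        risk5[mask] = alg.predict_risk_lp(lp, age, 5.0, truncate_horizon=True)
    out["risk_1y"] = risk1
    out["risk_5y"] = risk5
    return out


# -- recalibration -----------------------------------------------------------


def recalibrate(algorithm: RiskAlgorithm, coded: pd.DataFrame,
                observed_rates: pd.DataFrame) -> RiskAlgorithm:
    """Update calibration factors against an external observed-rate table.

    ``observed_rates`` has columns (sex, age_lo, age_hi, rate) with annual
    rates on [0, 1]; its bins for ``algorithm.sex`` become the calibration
    bins and must cover every survey respondent of that sex.  Bins with no
    respondents or zero predicted risk keep their previous factor (with a
    warning).  Applying the same table twice is a no-op the second time.
    """
    obs = observed_rates.loc[observed_rates["sex"] == algorithm.sex]
    if obs.empty:
        raise RecalibrationError(f"no observed rates for sex {algorithm.sex!r}")
    obs = obs.sort_values("age_lo").reset_index(drop=True)

    sub = coded.loc[coded["sex"] == algorithm.sex]
    age = sub["age"].to_numpy(dtype=float)
    w = sub["weight"].to_numpy(dtype=float)
    lo = obs["age_lo"].to_numpy(dtype=float)
    hi = obs["age_hi"].to_numpy(dtype=float)
    if len(sub):
        covered = (age[:, None] >= lo) & (age[:, None] < hi)
        uncovered = ~covered.any(axis=1)
        if uncovered.any():
            bad = np.sort(np.unique(np.floor(age[uncovered] / 5) * 5))
            raise RecalibrationError(
                f"observed table missing bins covering ages {bad.tolist()} "
                f"for sex {algorithm.sex!r}"
            )

    old_factor = algorithm.calibration_factor(age) if len(sub) else np.array([])
    lp = algorithm.linear_predictor(sub) if len(sub) else np.array([])
    predicted = (algorithm.predict_risk_lp(lp, age, 1.0, truncate_horizon=True)
                 if len(sub) else np.array([]))

    new = obs.loc[:, ["age_lo", "age_hi"]].copy()
    factors = np.ones(len(obs))
    for i in range(len(obs)):
        in_bin = (age >= lo[i]) & (age < hi[i]) if len(sub) else np.array([], bool)
        # carry forward the factor this algorithm already applies in the bin
        prev = algorithm.calibration_factor(np.array([(lo[i] + hi[i]) / 2.0]))[0]
        o = obs["rate"].iloc[i]
        if not in_bin.any() or not np.isfinite(o):
            warnings.warn(
                f"calibration bin [{lo[i]}, {hi[i]}) empty or unobserved; "
                "factor unchanged", stacklevel=2)
            factors[i] = prev
            continue
        p = np.average(predicted[in_bin], weights=w[in_bin])
        if p <= 0:
            warnings.warn(
                f"zero predicted risk in bin [{lo[i]}, {hi[i]}); factor "
                "unchanged", stacklevel=2)
            factors[i] = prev
            continue
        factors[i] = prev * o / p
    new["factor"] = factors
    return replace(algorithm, calibration=new)


# -- serialization -----------------------------------------------------------


def algorithm_to_json(algorithm: RiskAlgorithm) -> str:
    payload = {
        "schema_version": algorithm.schema_version,
        "sex": algorithm.sex,
        "terms": list(algorithm.terms),
        "age_interactions": list(algorithm.age_interactions),
        "age_center": algorithm.age_center,
        "coefficients": algorithm.coefficients.tolist(),
        "s0": algorithm.s0.tolist(),
        "coef_covariance": (None if algorithm.coef_covariance is None
                            else np.asarray(algorithm.coef_covariance).tolist()),
        "calibration": algorithm.calibration.to_dict(orient="list"),
    }
    return json.dumps(payload, indent=2)


def algorithm_from_json(text: str) -> RiskAlgorithm:
    raw = json.loads(text)
    return RiskAlgorithm(
        sex=raw["sex"],
        terms=tuple(raw["terms"]),
        age_interactions=tuple(raw["age_interactions"]),
        age_center=raw["age_center"],
        coefficients=np.asarray(raw["coefficients"]),
        s0=np.asarray(raw["s0"]),
        coef_covariance=(None if raw["coef_covariance"] is None
                         else np.asarray(raw["coef_covariance"])),
        calibration=pd.DataFrame(raw["calibration"]),
        schema_version=raw.get("schema_version", 1),
    )
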