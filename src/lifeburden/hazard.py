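"""Sex-specific proportional-hazards model derivation on linked cohorts.

Mortality is modelled with a Cox proportional-hazards model on the **age
time scale**: a respondent surveyed at age ``a`` with ``t`` years of
follow-up enters the risk set at age ``a`` (left truncation / delayed
entry) and exits at ``a + t``.  This makes age a continuous, implicitly
time-dependent quantity — the age effect, including its non-linearity, is
absorbed into the baseline hazard rather than entering as a spline
covariate — and is the standard epidemiological device for cohorts whose
outcome risk is driven primarily by attained age.  Ties are handled with
the Efron approximation (the lifelines default).

Covariates are the coded behaviour, sociodemographic and disease terms,
optionally with (age - 50) x behaviour interaction terms.  Beyond plain
fitting, the module implements the calibration-driven covariate inclusion
rule (add a candidate factor only if omitting it leaves some subgroup
holding >5% of deaths with a >20% gap between predicted and observed
deaths) and a sensitivity refit that discards the first years of follow-up
to damp the healthy-respondent effect.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

from . import validation as _validation
from .exposures import MODEL_TERMS, design_matrix
from .riskengine import AGE_GRID, RiskAlgorithm


class FitError(RuntimeError):
    """Model fitting failed (no events, no data, or non-convergence)."""


@dataclass
class ModelSpec:
    """Covariate specification for one sex-specific model."""

    sex: str
    terms: tuple[str, ...] = MODEL_TERMS
    #: behaviour terms interacted with (linear age - age_center)
    age_interactions: tuple[str, ...] = ()
    age_center: float = 50.0

    def coefficient_names(self) -> list[str]:
        return list(self.terms) + [f"age_x_{t}" for t in self.age_interactions]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        raw = json.loads(text)
        raw["terms"] = tuple(raw["terms"])
        raw["age_interactions"] = tuple(raw["age_interactions"])
        return cls(**raw)


@dataclass
class FittedModel:
    """A fitted proportional-hazards model plus its baseline hazard."""

    spec: ModelSpec
    params: pd.Series
    covariance: pd.DataFrame
    baseline_cumhaz: pd.Series  # on the integer age grid, at covariates = 0
    n: int
    n_deaths: int
    person_years: float
    log: dict = field(default_factory=dict)

    def standard_errors(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.covariance.to_numpy())),
                         index=self.params.index)


def _fit_frame(coded: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    sub = coded.loc[coded["sex"] == spec.sex]
    if "followup_years" not in sub.columns or "died" not in sub.columns:
        raise FitError("cohort has no follow-up columns")
    df = pd.DataFrame({
        "entry_age": sub["age"].to_numpy(dtype=float),
        "exit_age": sub["age"].to_numpy(dtype=float)
        + np.maximum(sub["followup_years"].to_numpy(dtype=float), 1e-6),
        "died": sub["died"].to_numpy(dtype=int),
    })
    for t in spec.terms:
        df[t] = sub[t].to_numpy(dtype=float)
    for t in spec.age_interactions:
        df[f"age_x_{t}"] = (
            (sub["age"].to_numpy(dtype=float) - spec.age_center)
            * sub[t].to_numpy(dtype=float)
        )
    return df


def _breslow_baseline(entry: np.ndarray, exit_: np.ndarray, died: np.ndarray,
                      theta: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Breslow cumulative baseline hazard on ``grid`` with delayed entry.

    dH0(t) = d(t) / sum_{j at risk at t} theta_j with the risk set
    restricted to entry_j < t <= exit_j.  (The fitting library's own
    baseline ignores entry times, which understates early hazard in
    age-scale cohorts.)
    """
    event_ages = exit_[died]
    times, counts = np.unique(event_ages, return_counts=True)
    # risk-set sums: sum(theta | exit >= t) - sum(theta | entry >= t)
    order_exit = np.argsort(exit_)
    exit_sorted = exit_[order_exit]
    csum_exit = np.concatenate([[0.0], np.cumsum(theta[order_exit])])
    total = csum_exit[-1]
    sum_exit_ge = total - csum_exit[np.searchsorted(exit_sorted, times, "left")]
    order_entry = np.argsort(entry)
    entry_sorted = entry[order_entry]
    csum_entry = np.concatenate([[0.0], np.cumsum(theta[order_entry])])
    sum_entry_ge = total - csum_entry[np.searchsorted(entry_sorted, times, "left")]
    denom = sum_exit_ge - sum_entry_ge
    dh = counts / np.maximum(denom, 1e-300)
    cumhaz = np.cumsum(dh)
    idx = np.searchsorted(times, grid, side="right")
    out = np.zeros(len(grid))
    out[idx > 0] = cumhaz[idx[idx > 0] - 1]
    return out


def fit_ph(coded: pd.DataFrame, spec: ModelSpec,
           min_deaths: int = 50, penalizer: float = 0.0) -> FittedModel:
    """Fit the Cox model on the age scale with delayed entry.

    ``coded`` is a coded linked cohort (both sexes allowed; rows of
    ``spec.sex`` are used).  Raises :class:`FitError` when there are no
    events, fewer than ``min_deaths`` events, or the partial-likelihood
    maximization fails to converge.
    """
    df = _fit_frame(coded, spec)
    n_deaths = int(df["died"].sum())
    if n_deaths == 0:
        raise FitError("no deaths in cohort; cannot fit")
    if n_deaths < min_deaths:
        raise FitError(f"only {n_deaths} deaths; minimum is {min_deaths}")

    cph = CoxPHFitter(penalizer=penalizer)
    try:
        cph.fit(df, duration_col="exit_age", event_col="died",
                entry_col="entry_age")
    except ConvergenceError as e:
        raise FitError(f"Cox fit did not converge: {e}") from e

    # baseline cumulative hazard at covariates = 0, on the integer age grid,
    # via the Breslow estimator with left-truncated risk sets (a subject is
    # at risk at age t only once entered: entry < t <= exit)
    names = spec.coefficient_names()
    lp = df[names].to_numpy(dtype=float) @ cph.params_.reindex(names).to_numpy()
    baseline = pd.Series(
        _breslow_baseline(
            df["entry_age"].to_numpy(), df["exit_age"].to_numpy(),
            df["died"].to_numpy(dtype=bool), np.exp(lp), AGE_GRID),
        index=AGE_GRID)

    return FittedModel(
        spec=spec,
        params=cph.params_.copy(),
        covariance=cph.variance_matrix_.copy(),
        baseline_cumhaz=baseline,
        n=len(df),
        n_deaths=n_deaths,
        person_years=float((df["exit_age"] - df["entry_age"]).sum()),
        log={
            "log_likelihood": float(cph.log_likelihood_),
            "max_observed_event_age": float(
                df.loc[df["died"] == 1, "exit_age"].max()),
        },
    )


def sensitivity_refit_excluding_early_followup(
    coded: pd.DataFrame, spec: ModelSpec, years: float = 2.0, **fit_kwargs
) -> FittedModel:
    """Refit after discarding the first ``years`` of follow-up.

    Respondents who died or were censored within the window are excluded;
    survivors enter the risk set ``years`` later (entry age shifted, follow-up
    shortened).  ``years = 0`` reproduces :func:`fit_ph` exactly.
    """
    if years < 0:
        raise ValueError("exclusion window must be >= 0")
    if years == 0:
        return fit_ph(coded, spec, **fit_kwargs)
    keep = coded["followup_years"].to_numpy(dtype=float) > years
    if not keep.any():
        raise FitError("exclusion window longer than every follow-up")
    shifted = coded.loc[keep].copy()
    shifted["age"] = shifted["age"] + years
    shifted["followup_years"] = shifted["followup_years"] - years
    return fit_ph(shifted, spec, **fit_kwargs)


# -- baseline survival extraction -------------------------------------------


def _extrapolate_tail(cumhaz: np.ndarray) -> np.ndarray:
    """Extend the Breslow baseline beyond the last observed event age.

    The Breslow estimator is flat after the last death, which would imply
    zero old-age risk; instead the annual log-hazard increments over the
    last decade with events are extended linearly (a local Gompertz tail).
    """
    h = np.diff(cumhaz)
    nz = np.nonzero(h > 0)[0]
    if len(nz) < 3:
        return cumhaz
    last = nz[-1]
    if last == len(h) - 1:
        return cumhaz
    lo = max(nz[0], last - 10)
    window = np.arange(lo, last + 1)
    vals = np.maximum(h[window], 1e-12)
    slope, intercept = np.polyfit(window, np.log(vals), 1)
    slope = max(slope, 0.0)  # never let the tail hazard decline
    ages = np.arange(last + 1, len(h))
    h = h.copy()
    h[ages] = np.exp(intercept + slope * ages)
    out = np.empty_like(cumhaz)
    out[0] = cumhaz[0]
    out[1:] = cumhaz[0] + np.cumsum(h)
    return out


def extract_algorithm(model: FittedModel) -> RiskAlgorithm:
    """Convert a fitted model into a self-contained risk algorithm.

    Coefficients and the baseline survival curve are taken directly from
    the fit; the baseline hazard is extrapolated past the last observed
    event age so the full 20-100 grid is usable.
    """
    cumhaz = _extrapolate_tail(model.baseline_cumhaz.to_numpy(dtype=float))
    # floor keeps S0 strictly positive when the extrapolated tail explodes
    # on sparse cohorts; risks at that point are already ~1
    s0 = np.maximum(np.exp(-cumhaz), 1e-15)
    s0 = np.minimum.accumulate(s0)
    names = model.spec.coefficient_names()
    return RiskAlgorithm(
        sex=model.spec.sex,
        terms=model.spec.terms,
        age_interactions=model.spec.age_interactions,
        age_center=model.spec.age_center,
        coefficients=model.params.reindex(names).to_numpy(dtype=float),
        s0=s0,
        coef_covariance=model.covariance.reindex(
            index=names, columns=names).to_numpy(dtype=float),
    )


# -- criterion-driven covariate inclusion ------------------------------------


def criterion_driven_inclusion(
    coded: pd.DataFrame,
    base_spec: ModelSpec,
    candidate_factors: Mapping[str, Sequence[str]],
    subgroups: Mapping[str, np.ndarray | Callable[[pd.DataFrame], np.ndarray]],
    threshold: float = 0.20,
    min_death_share: float = 0.05,
    horizon: float = 5.0,
    **fit_kwargs,
) -> ModelSpec:
    """Select candidate factor groups by the subgroup-calibration rule.

    For each named candidate group of terms, the model is fitted with all
    *other* candidates plus the base terms; the candidate is retained when
    its omission leaves at least one subgroup — among subgroups carrying
    more than ``min_death_share`` of total deaths — with a relative gap
    between predicted and observed deaths above ``threshold``.
    """
    if not candidate_factors:
        return base_spec

    sub = coded.loc[coded["sex"] == base_spec.sex].reset_index(drop=True)
    masks = {}
    for name, m in subgroups.items():
        arr = m(sub) if callable(m) else np.asarray(m)
        if arr.shape[0] != len(sub):
            raise ValueError(f"subgroup {name!r} mask length mismatch")
        masks[name] = arr.astype(bool)

    included: list[str] = []
    all_names = list(candidate_factors)
    for name in all_names:
        other_terms: list[str] = []
        for other in all_names:
            if other != name:
                other_terms.extend(candidate_factors[other])
        spec_without = dataclasses.replace(
            base_spec,
            terms=tuple(base_spec.terms) + tuple(other_terms),
        )
        model = fit_ph(sub, spec_without, **fit_kwargs)
        alg = extract_algorithm(model)
        report = _validation.subgroup_calibration(
            sub, alg, masks, horizon=horizon,
            min_death_share=min_death_share)
        eligible = report.loc[report["eligible"] & report["flagged"]]
        if len(eligible):
            included.append(name)

    extra: list[str] = []
    for name in included:
        extra.extend(candidate_factors[name])
    return dataclasses.replace(
        base_spec, terms=tuple(base_spec.terms) + tuple(extra)
    )


# -- multicollinearity -------------------------------------------------------


def variance_inflation(coded: pd.DataFrame,
                       terms: Sequence[str] = MODEL_TERMS,
                       flag_above: float = 10.0) -> pd.DataFrame:
    """Variance inflation factor per term, flagging VIF > ``flag_above``."""
    X = design_matrix(coded, terms)
    X = np.column_stack([np.ones(len(X)), X])
    rows = []
    for j, t in enumerate(terms, start=1):
        others = np.delete(X, j, axis=1)
        beta, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
        resid = X[:, j] - others @ beta
        ss_tot = np.sum((X[:, j] - X[:, j].mean()) ** 2)
        r2 = 0.0 if ss_tot == 0 else 1.0 - np.sum(resid**2) / ss_tot
        vif = np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
        rows.append({"term": t, "vif": vif, "flagged": vif > flag_above})
    return pd.DataFrame(rows)
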