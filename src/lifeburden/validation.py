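"""Discrimination and calibration assessment of a risk algorithm.

Discrimination is summarized by the concordance statistic adapted to
left-truncated survival on the age scale — a pair is comparable only when
the non-failing member is actually under observation at the failure age —
and by the 90:10 risk percentile ratio (mean predicted risk in the top
decile over the bottom decile).  Calibration compares observed deaths
within a horizon to the sum of predicted risks, by user-defined subgroup
and by predicted-risk decile, flagging any subgroup whose relative gap
exceeds 20%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd

#: relative predicted-vs-observed gap considered material for calibration
CALIBRATION_FLAG_THRESHOLD = 0.20


@dataclass
class ValidationReport:
    c_statistic: float
    c_ci: tuple[float, float] | None
    ratio_90_10: float
    subgroup_table: pd.DataFrame
    decile_table: pd.DataFrame


# -- concordance -------------------------------------------------------------


def concordance(predicted_risks, entry_ages, exit_ages, died) -> float:
    """Concordance for left-truncated, right-censored data.

    For each death at age ``t``, every other subject observed at ``t``
    (entered before ``t`` and not yet failed or censored) forms a
    comparable pair; the pair is concordant when the decedent carried the
    higher predicted risk, and risk ties count 1/2.  Pairs of deaths tied
    on age are not comparable.  Raises when no pair is comparable.
    """
    risk = np.asarray(predicted_risks, dtype=float)
    entry = np.asarray(entry_ages, dtype=float)
    exit_ = np.asarray(exit_ages, dtype=float)
    event = np.asarray(died).astype(bool)
    if np.any(exit_ <= entry):
        raise ValueError("every exit age must exceed its entry age")

    num = 0.0
    den = 0
    for i in np.nonzero(event)[0]:
        t = exit_[i]
        at_risk = (entry < t) & ((exit_ > t) | ((exit_ == t) & ~event))
        at_risk[i] = False
        n_cmp = int(at_risk.sum())
        if n_cmp == 0:
            continue
        den += n_cmp
        num += np.sum(risk[i] > risk[at_risk]) + 0.5 * np.sum(
            risk[i] == risk[at_risk]
        )
    if den == 0:
        raise ValueError("no comparable pairs")
    return num / den


def concordance_ci(predicted_risks, entry_ages, exit_ages, died,
                   n_bootstrap: int = 200, seed: int = 0,
                   level: float = 0.95) -> tuple[float, float]:
    """Percentile bootstrap CI for the concordance (resampling subjects)."""
    risk = np.asarray(predicted_risks, dtype=float)
    entry = np.asarray(entry_ages, dtype=float)
    exit_ = np.asarray(exit_ages, dtype=float)
    event = np.asarray(died).astype(bool)
    rng = np.random.default_rng(seed)
    stats = []
    n = len(risk)
    for _ in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        try:
            stats.append(concordance(risk[idx], entry[idx], exit_[idx],
                                     event[idx]))
        except ValueError:
            continue
    if not stats:
        raise ValueError("no bootstrap replicate had comparable pairs")
    alpha = (1.0 - level) / 2.0
    return (float(np.quantile(stats, alpha)),
            float(np.quantile(stats, 1.0 - alpha)))


# -- 90:10 percentile ratio --------------------------------------------------


def percentile_ratio(predicted_risks) -> float:
    """Mean predicted risk of the top decile over the bottom decile."""
    risk = np.sort(np.asarray(predicted_risks, dtype=float))
    n = len(risk)
    if n < 10:
        raise ValueError("need at least 10 risks for a 90:10 ratio")
    k = n // 10
    bottom = risk[:k].mean()
    if bottom <= 0:
        raise ValueError("bottom-decile mean risk is zero")
    return float(risk[-k:].mean() / bottom)


# -- calibration -------------------------------------------------------------


def _horizon_frame(coded: pd.DataFrame, algorithm, horizon: float) -> pd.DataFrame:
    """Respondents assessable at ``horizon``: at least ``horizon`` potential
    follow-up, or an earlier death.  Adds observed-death and predicted-risk
    columns."""
    fu = coded["followup_years"].to_numpy(dtype=float)
    died = coded["died"].to_numpy(dtype=int).astype(bool)
    assessable = (fu >= horizon) | died
    sub = coded.loc[assessable].reset_index(drop=True)
    fu = fu[assessable]
    d = died[assessable]
    observed = d & (fu <= horizon)
    lp = algorithm.linear_predictor(sub)
    pred = algorithm.predict_risk_lp(
        lp, sub["age"].to_numpy(dtype=float), horizon, truncate_horizon=True)
    out = sub.copy()
    out["observed_death"] = observed.astype(int)
    out["predicted_risk"] = pred
    return out


def subgroup_calibration(
    coded: pd.DataFrame,
    algorithm,
    subgroups: Mapping[str, np.ndarray | Callable[[pd.DataFrame], np.ndarray]],
    horizon: float = 5.0,
    min_death_share: float = 0.05,
    threshold: float = CALIBRATION_FLAG_THRESHOLD,
) -> pd.DataFrame:
    """Observed vs predicted deaths per subgroup within ``horizon`` years.

    Respondents censored before the horizon are excluded (administrative-
    censoring-aware observed risk).  ``eligible`` marks subgroups holding
    more than ``min_death_share`` of all observed deaths; ``flagged`` marks
    a relative gap above ``threshold``.  Subgroups with zero observed
    deaths get an undefined (NaN) percent difference and are flagged
    separately via ``zero_observed``.
    """
    sub = coded.loc[coded["sex"] == algorithm.sex].reset_index(drop=True) \
        if "sex" in coded.columns else coded.reset_index(drop=True)
    frame = _horizon_frame(sub, algorithm, horizon)
    total_deaths = frame["observed_death"].sum()
    rows = []
    for name, m in subgroups.items():
        mask = m(sub) if callable(m) else np.asarray(m)
        mask = mask.astype(bool)
        # masks are defined on the full (sex-restricted) cohort; restrict to
        # the assessable rows
        fu = sub["followup_years"].to_numpy(dtype=float)
        died = sub["died"].to_numpy(dtype=int).astype(bool)
        assessable = (fu >= horizon) | died
        gmask = mask[assessable]
        obs = int(frame.loc[gmask, "observed_death"].sum())
        pred = float(frame.loc[gmask, "predicted_risk"].sum())
        if obs > 0:
            pct = (pred - obs) / obs
        else:
            pct = np.nan
        rows.append({
            "subgroup": name,
            "n": int(gmask.sum()),
            "observed_deaths": obs,
            "predicted_deaths": pred,
            "pct_difference": pct,
            "zero_observed": obs == 0,
            "eligible": total_deaths > 0 and obs > min_death_share * total_deaths,
            "flagged": bool(obs > 0 and abs(pct) > threshold),
        })
    return pd.DataFrame(rows)


def decile_calibration(coded: pd.DataFrame, algorithm,
                       horizon: float = 5.0) -> pd.DataFrame:
    """Observed vs predicted deaths by decile of predicted risk."""
    sub = coded.loc[coded["sex"] == algorithm.sex].reset_index(drop=True) \
        if "sex" in coded.columns else coded.reset_index(drop=True)
    frame = _horizon_frame(sub, algorithm, horizon)
    decile = pd.qcut(frame["predicted_risk"].rank(method="first"),
                     10, labels=False)
    rows = []
    for d in range(10):
        g = frame.loc[decile == d]
        obs = int(g["observed_death"].sum())
        pred = float(g["predicted_risk"].sum())
        rows.append({
            "decile": d + 1,
            "n": len(g),
            "observed_deaths": obs,
            "predicted_deaths": pred,
            "pct_difference": (pred - obs) / obs if obs else np.nan,
        })
    return pd.DataFrame(rows)


def validate_algorithm(coded: pd.DataFrame, algorithm,
                       subgroups: Mapping | None = None,
                       horizon: float = 5.0,
                       n_bootstrap: int = 200,
                       seed: int = 0) -> ValidationReport:
    """Full discrimination + calibration report on a linked cohort."""
    sub = coded.loc[coded["sex"] == algorithm.sex].reset_index(drop=True)
    lp = algorithm.linear_predictor(sub)
    age = sub["age"].to_numpy(dtype=float)
    risk = algorithm.predict_risk_lp(lp, age, horizon, truncate_horizon=True)
    entry = age
    exit_ = age + np.maximum(sub["followup_years"].to_numpy(dtype=float), 1e-9)
    died = sub["died"].to_numpy(dtype=int)
    c = concordance(risk, entry, exit_, died)
    ci = None
    if n_bootstrap:
        ci = concordance_ci(risk, entry, exit_, died,
                            n_bootstrap=n_bootstrap, seed=seed)
    ratio = percentile_ratio(risk)
    sg = subgroup_calibration(sub, algorithm, subgroups or {}, horizon=horizon)
    dec = decile_calibration(sub, algorithm, horizon=horizon)
    return ValidationReport(
        c_statistic=c, c_ci=ci, ratio_90_10=ratio,
        subgroup_table=sg, decile_table=dec,
    )
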