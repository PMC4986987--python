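"""Survey-weighted abridged period life tables and Chiang life expectancy.

Individual predicted annual death risks are aggregated into 5-year interval
death probabilities ([20,25) ... [95,100)), from which a standard abridged
life table is built: survivors l, decedent years via the fraction-of-
interval-lived constant a (2.5 y for every interval, including the closed
terminal interval where q = 1), person-years L, cumulative T and remaining
life expectancy e.  The variance of interval probabilities propagates to
Var(e20) by Chiang's delta-method formula, giving normal-theory confidence
intervals for life expectancy.

Interval q comes from the weighted mean annual risk in the interval,
treating annual risk as constant within the interval:
q = 1 - (1 - qbar)^5.  Intervals with no respondents are filled by
log-linear interpolation of qbar between neighbouring intervals.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

INTERVAL_YEARS = 5.0
INTERVALS = tuple((lo, lo + 5) for lo in range(20, 100, 5))
#: years lived within an interval by those dying in it
DEFAULT_A = 2.5
RADIX = 100_000.0


class LifeTableError(ValueError):
    pass


# -- interval aggregation ----------------------------------------------------


def aggregate_interval_q(annual_risks, ages, weights) -> pd.DataFrame:
    """Weighted interval death probabilities from individual annual risks.

    Returns one row per 5-y interval with the weighted mean annual risk
    ``qbar``, the 5-y probability ``q``, its sampling variance ``var_q``
    (delta method from the variance of the weighted mean), the respondent
    count, and whether the interval was ``filled`` by interpolation.
    """
    risk = np.asarray(annual_risks, dtype=float)
    age = np.asarray(ages, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise LifeTableError("weights must be positive")
    if np.any((age < INTERVALS[0][0]) | (age >= INTERVALS[-1][1])):
        raise LifeTableError("ages must lie in [20, 100)")

    idx = ((age - 20) // 5).astype(int)
    k = len(INTERVALS)
    sw = np.bincount(idx, weights=w, minlength=k)
    swr = np.bincount(idx, weights=w * risk, minlength=k)
    n = np.bincount(idx, minlength=k)
    if not n.any():
        raise LifeTableError("no respondents in any interval")

    qbar = np.full(k, np.nan)
    nonempty = n > 0
    qbar[nonempty] = swr[nonempty] / sw[nonempty]

    # variance of the weighted mean annual risk per interval
    var_qbar = np.zeros(k)
    dev = risk - qbar[idx]
    sw2d = np.bincount(idx, weights=(w * dev) ** 2, minlength=k)
    var_qbar[nonempty] = sw2d[nonempty] / sw[nonempty] ** 2

    filled = ~nonempty
    if filled.any():
        mids = np.array([(lo + hi) / 2 for lo, hi in INTERVALS])
        good = nonempty & (qbar > 0)
        if not good.any():
            raise LifeTableError("cannot interpolate: no positive intervals")
        qbar[filled] = np.exp(
            np.interp(mids[filled], mids[good], np.log(qbar[good]))
        )
        logger.debug("filled %d empty life-table interval(s) by log-linear "
                    "interpolation: %s", filled.sum(),
                    [INTERVALS[i] for i in np.nonzero(filled)[0]])

    q = 1.0 - (1.0 - qbar) ** INTERVAL_YEARS
    var_q = (INTERVAL_YEARS * (1.0 - qbar) ** (INTERVAL_YEARS - 1)) ** 2 * var_qbar
    return pd.DataFrame({
        "age_lo": [lo for lo, _ in INTERVALS],
        "age_hi": [hi for _, hi in INTERVALS],
        "n": n,
        "qbar": qbar,
        "q": q,
        "var_q": var_q,
        "filled": filled,
    })


# -- table construction ------------------------------------------------------


def build_table(q_by_interval, a: float = DEFAULT_A,
                radix: float = RADIX) -> pd.DataFrame:
    """Abridged life table from 5-y interval death probabilities.

    ``q_by_interval`` is an array of length 16 (or a frame from
    :func:`aggregate_interval_q`).  The terminal interval [95,100) is
    closed with q = 1.  Columns: age_lo, age_hi, q, l, d, L, T, e, a,
    var_q (zeros unless supplied).
    """
    if isinstance(q_by_interval, pd.DataFrame):
        q = q_by_interval["q"].to_numpy(dtype=float).copy()
        var_q = (q_by_interval["var_q"].to_numpy(dtype=float).copy()
                 if "var_q" in q_by_interval else np.zeros_like(q))
    else:
        q = np.asarray(q_by_interval, dtype=float).copy()
        var_q = np.zeros_like(q)
    k = len(INTERVALS)
    if q.shape != (k,):
        raise LifeTableError(f"need {k} interval probabilities, got {q.shape}")
    if np.any((q < 0) | (q > 1)) or np.any(~np.isfinite(q)):
        raise LifeTableError("interval q must be finite and within [0, 1]")
    q[-1] = 1.0
    var_q[-1] = 0.0

    n = INTERVAL_YEARS
    l = np.empty(k + 1)
    l[0] = radix
    for i in range(k):
        l[i + 1] = l[i] * (1.0 - q[i])
    d = l[:-1] - l[1:]
    L = n * l[1:] + a * d
    T = np.cumsum(L[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(l[:-1] > 0, T / l[:-1], 0.0)

    return pd.DataFrame({
        "age_lo": [lo for lo, _ in INTERVALS],
        "age_hi": [hi for _, hi in INTERVALS],
        "q": q,
        "l": l[:-1],
        "d": d,
        "L": L,
        "T": T,
        "e": e,
        "a": a,
        "var_q": var_q,
    })


def life_expectancy(table: pd.DataFrame) -> float:
    """Life expectancy on the full-lifespan scale: starting age + e at the
    first interval (e.g. 20 + e20)."""
    return float(table["age_lo"].iloc[0] + table["e"].iloc[0])


# -- variance ----------------------------------------------------------------


def le_variance(table: pd.DataFrame, level: float = 0.95) -> dict:
    """Chiang variance of e20 propagated from interval-q variances.

    Var(e20) = sum_x (l_x / l_20)^2 * ((n - a) + e_{x+n})^2 * Var(q_x),
    with the terminal interval fixed (q = 1, zero variance).  Returns the
    point estimate on the lifespan scale with a normal-theory CI.
    """
    from scipy.stats import norm

    q = table["q"].to_numpy(dtype=float)
    var_q = table["var_q"].to_numpy(dtype=float)
    l = table["l"].to_numpy(dtype=float)
    e = table["e"].to_numpy(dtype=float)
    a = float(table["a"].iloc[0])
    n = INTERVAL_YEARS
    if np.any(var_q < 0):
        raise LifeTableError("var_q must be >= 0")

    e_next = np.append(e[1:], 0.0)
    weights = (l / l[0]) ** 2 * ((n - a) + e_next) ** 2
    var_e = float(np.sum(weights[:-1] * var_q[:-1]))  # terminal fixed
    se = np.sqrt(var_e)
    z = norm.ppf(0.5 + level / 2.0)
    le = life_expectancy(table)
    return {
        "life_expectancy": le,
        "var_e": var_e,
        "se": se,
        "ci": (le - z * se, le + z * se),
    }


# -- pipeline helper ---------------------------------------------------------


def survey_life_table(annual_risks, ages, weights,
                      a: float = DEFAULT_A) -> pd.DataFrame:
    """Aggregate individual annual risks and build the life table."""
    agg = aggregate_interval_q(annual_risks, ages, weights)
    return build_table(agg, a=a)
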