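"""Bootstrap confidence intervals for burden quantities.

Two sources of uncertainty are combined, replicate by replicate, in the
spirit of survey bootstrap schemes for out-of-sample prediction:

* **coefficients** — the risk algorithm's coefficient vector is redrawn
  from a multivariate normal centred at the estimates with the fitted
  covariance (parameter uncertainty);
* **survey** — respondents are resampled with replacement and their
  weights rescaled to preserve the represented total (exposure-distribution
  uncertainty).

Each replicate recomputes attributable deaths, attributable fraction and
life expectancy lost from scratch through the same formulas as the point
estimate; percentile intervals are reported (life expectancy lost can be
skewed, so normal-theory intervals are avoided).  Baseline survival and
calibration factors are held fixed across replicates.  User-supplied
replicate weights (common in public survey releases) can be passed instead
of the with-replacement resample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import lifetable
from .burden import BurdenEstimate, _check_behaviours, healthy_reference_coded
from .riskengine import AGE_GRID, RiskAlgorithm


@dataclass
class BootstrapConfig:
    B: int = 500
    seed: int = 0
    #: subset of {"coefficients", "survey"}; empty = degenerate (point only)
    sources: tuple[str, ...] = ("coefficients", "survey")
    level: float = 0.95

    def __post_init__(self):
        if self.B < 2:
            raise ValueError("B must be >= 2")
        if not 0 < self.level < 1:
            raise ValueError("level must be in (0, 1)")
        bad = set(self.sources) - {"coefficients", "survey"}
        if bad:
            raise ValueError(f"unknown uncertainty sources {sorted(bad)}")


# -- fast per-replicate evaluation -------------------------------------------


class _SexBlock:
    """Precomputed arrays for one sex: design matrices for baseline and
    counterfactual exposures, ages, weights, interval ids, calibration
    factors, and interpolated log-S0 one-year ratios."""

    def __init__(self, alg: RiskAlgorithm, coded: pd.DataFrame,
                 behaviours: Sequence[str]):
        ref_coded = healthy_reference_coded(coded, behaviours)
        self.Xb = self._design(alg, coded)
        self.Xr = self._design(alg, ref_coded)
        self.age = coded["age"].to_numpy(dtype=float)
        self.w = coded["weight"].to_numpy(dtype=float)
        self.interval = ((self.age - 20) // 5).astype(int)
        self.factor = alg.calibration_factor(self.age)
        log_s0 = np.log(alg.s0)
        self.log_ratio = (np.interp(np.minimum(self.age + 1.0, AGE_GRID[-1]),
                                    AGE_GRID, log_s0)
                          - np.interp(self.age, AGE_GRID, log_s0))
        self.beta = alg.coefficients
        self.cov = alg.coef_covariance
        self.n = len(coded)

    @staticmethod
    def _design(alg: RiskAlgorithm, coded: pd.DataFrame) -> np.ndarray:
        from .exposures import design_matrix
        X = design_matrix(coded, alg.terms)
        if alg.age_interactions:
            age = coded["age"].to_numpy(dtype=float)
            Xi = design_matrix(coded, alg.age_interactions)
            X = np.column_stack([X, Xi * (age - alg.age_center)[:, None]])
        return X

    def risks(self, beta: np.ndarray, idx: np.ndarray | None):
        Xb, Xr = self.Xb, self.Xr
        lr, fac = self.log_ratio, self.factor
        if idx is not None:
            Xb, Xr, lr, fac = Xb[idx], Xr[idx], lr[idx], fac[idx]
        qb = np.clip(fac * -np.expm1(np.exp(Xb @ beta) * lr), 0.0, 1.0)
        qr = np.clip(fac * -np.expm1(np.exp(Xr @ beta) * lr), 0.0, 1.0)
        return qb, qr


def _fast_le(qbar: np.ndarray) -> float:
    """Remaining-LE-at-20 on the lifespan scale from interval mean annual
    risks (NaN intervals filled by log-linear interpolation)."""
    k = len(lifetable.INTERVALS)
    mids = np.arange(22.5, 100.0, 5.0)
    good = np.isfinite(qbar) & (qbar > 0)
    if not good.all():
        if not good.any():
            raise lifetable.LifeTableError("no positive intervals")
        qbar = qbar.copy()
        qbar[~good] = np.exp(np.interp(mids[~good], mids[good],
                                       np.log(qbar[good])))
    q = 1.0 - (1.0 - qbar) ** 5.0
    q[-1] = 1.0
    surv = np.cumprod(1.0 - q)
    l = np.empty(k + 1)
    l[0] = 1.0
    l[1:] = surv
    d = l[:-1] - l[1:]
    L = 5.0 * l[1:] + 2.5 * d
    return 20.0 + float(L.sum())


def _interval_means(q: np.ndarray, w: np.ndarray, interval: np.ndarray,
                    k: int) -> np.ndarray:
    sw = np.bincount(interval, weights=w, minlength=k)
    swq = np.bincount(interval, weights=w * q, minlength=k)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(sw > 0, swq / np.maximum(sw, 1e-300), np.nan)


def _quantities(blocks: dict[str, _SexBlock],
                betas: Mapping[str, np.ndarray],
                idx: Mapping[str, np.ndarray] | None,
                weights: Mapping[str, np.ndarray] | None = None,
                ) -> dict[str, float]:
    k = len(lifetable.INTERVALS)
    base_deaths = ref_deaths = 0.0
    les_b, les_r, tot_w = {}, {}, {}
    for sex, blk in blocks.items():
        sub_idx = None if idx is None else idx[sex]
        qb, qr = blk.risks(betas[sex], sub_idx)
        if weights is not None:
            w = weights[sex]
        else:
            w = blk.w if sub_idx is None else blk.w[sub_idx]
        if sub_idx is not None:
            w = w * (blk.w.sum() / w.sum())
        interval = blk.interval if sub_idx is None else blk.interval[sub_idx]
        base_deaths += float(np.sum(w * qb))
        ref_deaths += float(np.sum(w * qr))
        les_b[sex] = _fast_le(_interval_means(qb, w, interval, k))
        les_r[sex] = _fast_le(_interval_means(qr, w, interval, k))
        tot_w[sex] = float(w.sum())
    total = sum(tot_w.values())
    base_le = sum(les_b[s] * tot_w[s] for s in les_b) / total
    ref_le = sum(les_r[s] * tot_w[s] for s in les_r) / total
    attr = base_deaths - ref_deaths
    out = {
        "baseline_le": base_le,
        "reference_le": ref_le,
        "le_lost": ref_le - base_le,
        "baseline_deaths": base_deaths,
        "reference_deaths": ref_deaths,
        "attributable_deaths": attr,
        "attributable_fraction": attr / base_deaths if base_deaths else 0.0,
    }
    for sex in les_b:
        out[f"le_lost_{sex}"] = les_r[sex] - les_b[sex]
    return out


def _coef_sampler(blk: _SexBlock):
    """Cholesky factor for coefficient draws, or None when degenerate."""
    if blk.cov is None:
        return None
    cov = np.asarray(blk.cov, dtype=float)
    try:
        return np.linalg.cholesky(cov + 1e-12 * np.eye(len(cov)))
    except np.linalg.LinAlgError:
        return None


def bootstrap_burden(
    algorithms: Mapping[str, RiskAlgorithm],
    coded: pd.DataFrame,
    behaviours: Sequence[str],
    config: BootstrapConfig,
    sex: str | None = None,
    return_replicates: bool = False,
    replicate_weights: np.ndarray | None = None,
):
    """Burden estimate with percentile bootstrap CIs.

    Returns a :class:`~lifeburden.burden.BurdenEstimate` whose ``ci`` maps
    each quantity to ``(lo, hi)``; with ``return_replicates`` also returns
    the replicate frame for audit.  Deterministic given ``config.seed``.

    ``replicate_weights`` — an array of shape (B, n) aligned with the rows
    of ``coded`` — replaces the with-replacement survey resample with the
    survey provider's own bootstrap replicate weights when available.
    """
    behaviours = _check_behaviours(behaviours)
    if sex is not None:
        coded = coded.loc[coded["sex"] == sex].reset_index(drop=True)
        algorithms = {sex: algorithms[sex]}

    blocks = {
        s: _SexBlock(alg, coded.loc[coded["sex"] == s].reset_index(drop=True),
                     behaviours)
        for s, alg in algorithms.items()
        if (coded["sex"] == s).any()
    }
    if not blocks:
        raise ValueError("empty survey")

    point = _quantities(blocks, {s: b.beta for s, b in blocks.items()}, None)

    rng = np.random.default_rng(config.seed)
    draw_coefs = "coefficients" in config.sources
    draw_survey = "survey" in config.sources
    chol = {s: _coef_sampler(b) for s, b in blocks.items()}
    if draw_coefs and any(c is None for c in chol.values()):
        warnings.warn(
            "degenerate or missing coefficient covariance; falling back to "
            "survey-only resampling", stacklevel=2)
        draw_coefs = False

    sex_rows = None
    if replicate_weights is not None:
        replicate_weights = np.asarray(replicate_weights, dtype=float)
        if replicate_weights.shape != (config.B, len(coded)):
            raise ValueError(
                f"replicate_weights must have shape (B, n) = "
                f"({config.B}, {len(coded)})")
        sex_rows = {s: np.nonzero((coded["sex"] == s).to_numpy())[0]
                    for s in blocks}

    reps = []
    for b in range(config.B):
        betas = {}
        for s, blk in blocks.items():
            if draw_coefs:
                z = rng.standard_normal(len(blk.beta))
                betas[s] = blk.beta + chol[s] @ z
            else:
                betas[s] = blk.beta
        if replicate_weights is not None:
            w_b = {s: replicate_weights[b][rows]
                   for s, rows in sex_rows.items()}
            reps.append(_quantities(blocks, betas, None, weights=w_b))
            continue
        idx = None
        if draw_survey:
            idx = {s: rng.integers(0, blk.n, size=blk.n)
                   for s, blk in blocks.items()}
        reps.append(_quantities(blocks, betas, idx))
    rep_frame = pd.DataFrame(reps)

    alpha = (1.0 - config.level) / 2.0
    varies = draw_coefs or draw_survey or replicate_weights is not None
    ci = {}
    for key in point:
        if varies:
            lo = float(rep_frame[key].quantile(alpha))
            hi = float(rep_frame[key].quantile(1.0 - alpha))
            # the point estimate is by construction inside its own interval
            lo, hi = min(lo, point[key]), max(hi, point[key])
        else:
            lo = hi = point[key]
        ci[key] = (lo, hi)

    est = BurdenEstimate(
        behaviours=behaviours,
        sex=sex,
        baseline_le=point["baseline_le"],
        reference_le=point["reference_le"],
        le_lost=point["le_lost"],
        baseline_deaths=point["baseline_deaths"],
        reference_deaths=point["reference_deaths"],
        attributable_deaths=point["attributable_deaths"],
        attributable_fraction=point["attributable_fraction"],
        n=len(coded),
        ci=ci,
    )
    if return_replicates:
        return est, rep_frame
    return est
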