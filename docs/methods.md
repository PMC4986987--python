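# Methods

This note records the modelling choices behind `lifeburden`, in the spirit
of a statistical appendix: what is assumed, what is configurable, what the
synthetic data do and do not emulate, and where the genuinely open design
decisions fell.

## Exposure coding

Raw survey answers are mapped deterministically onto the model's covariate
representation; no imputation is performed (complete-case rule — records
missing any model field are excluded with a `missing:<field>` reason).

* **Smoking.** Current and former smokers split heavy/light at one pack a
  day; a pack is taken as 20 cigarettes (the convention is not universal,
  so the constant is exposed as `CIGARETTES_PER_PACK`). Never-smokers and
  former *occasional* smokers with fewer than 100 lifetime cigarettes are
  non-smokers; current occasional smokers with no daily amount are coded
  light. Former classes carry a continuous years-since-quitting term.
* **Alcohol.** Heavy is any of: >21 (men) / >14 (women) drinks in the
  previous week, ≥5 drinks on any single day of that week, or weekly
  bingeing (≥5 drinks on an occasion). The single-day rule and the weekly
  bingeing rule are kept as distinct OR-conditions. Light/non is ≤3
  (men) / ≤2 (women) drinks; the moderate band's upper bounds are
  inclusive.
* **Physical activity.** METs/day = Σ over leisure activities of
  met_value × (monthly sessions × minutes/60) / 30 — a daily average of
  last-month leisure-time energy expenditure. A precomputed `mets_per_day`
  column bypasses this.
* **Diet.** Score = 2 baseline points + min(fruit/veg per day, 8)
  − 2·max(0, juice per day − 1) (floored at −10) − 2·[high potato intake:
  ≥7/week men, ≥5 women] − 2·[no carrot intake], clamped to [0, 10]. The
  juice penalty is linear in daily frequency beyond once a day; "no
  carrots" means exactly zero weekly frequency.
* **Deprivation.** The 5×5 material × social quintile grid collapses to
  low (both ≤2; 4 cells), high (both ≥4; 4 cells), moderate (17 cells).

## Hazard model

A sex-specific Cox proportional-hazards model is fitted with **age as the
time scale**: entry at survey age, exit at survey age + follow-up, Efron
ties. This makes age a continuous time-dependent quantity whose full
non-linear effect lives in the baseline hazard, so no age spline covariate
is needed; an age spline would only re-enter under a time-on-study scale,
which this package does not use. Age × behaviour interactions are
available as (age − 50) × indicator terms (off by default; the generator's
truth has none). Sex-specific models are two independent fits.

Coefficients and their covariance come from lifelines'
`CoxPHFitter`. The baseline cumulative hazard, however, is computed by
this package with a Breslow estimator whose risk sets honour delayed
entry (a subject is at risk at age t only if entry < t ≤ exit); the
library's own baseline ignores entry times, which understates early-age
hazard several-fold in left-truncated cohorts. Beyond the last observed
death age the annual log-hazard increments are extended linearly from the
last populated decade (a local Gompertz tail), and the resulting survival
is floored at 1e-15.

**Covariate inclusion criterion.** Candidate factor groups beyond age and
behaviours are admitted only if their omission leaves at least one
subgroup — among subgroups carrying more than 5% of deaths — with a
relative gap between predicted and observed deaths above 20%. The
subgroup list is user-supplied (the policy-defined list used in any
particular application is not canonical). Multicollinearity is screened
with a variance-inflation report (flag at VIF > 10).

**Sensitivity refit.** To probe a healthy-respondent effect, the model can
be refitted excluding the first *w* years of follow-up: early deaths and
early-censored records are dropped and survivors' entry shifts by *w*.

## Risk engine and recalibration

The h-year risk is `1 − (S0(a+h)/S0(a))^exp(LP)` with log S₀ interpolated
linearly between integer ages, multiplied by the calibration factor of the
5-year age bin containing the starting age and clamped to [0, 1]. The
calibration factor multiplies **risk**, not hazard — a deliberate
simplification that makes the recalibration identity exact: after
`α ← α·O/P` the survey-weighted predicted annual rate in every bin equals
the observed rate to machine precision, and recalibration is idempotent.
Whole-survey sweeps truncate the horizon at the top of the age grid (age
100) so respondents aged 96+ remain scoreable.

## Life tables

Abridged period tables on [20,25) … [95,100), radix 100 000. Interval
probability q = 1 − (1 − q̄)⁵ where q̄ is the survey-weighted mean
predicted annual risk among respondents in the interval (annual risk is
treated as constant within the interval — a documented approximation).
Decedents live a = 2.5 years of the interval, including the terminal
interval, which is closed with q = 1 (no open-ended extrapolation past
100). Empty intervals are filled by log-linear interpolation of q̄ between
populated neighbours and flagged. Life expectancy is reported on the
lifespan scale (20 + e₂₀). Var(e₂₀) follows Chiang:
Σ (l_x/l₂₀)² ((n − a) + e_{x+n})² Var(q_x), with Var(q̄) the variance of
the weighted mean; the terminal interval is fixed and contributes none.
Sexes are reported separately; the combined-sex figure is a
survey-weight-weighted average of the two and is flagged as a
non-canonical summary.

## Burden and counterfactuals

Healthy-reference recoding: non-smoker with the quit clock zeroed; METs
raised to 3/day; diet score raised to 8; heavy drinkers moved to
light/non. The recode is a no-op for respondents already at the reference
and touches nothing else — mediators (BMI, diabetes, heart disease,
stroke) are held fixed, which matches full-model attribution and likely
understates total burden; an external hazard-ratio file can decouple
attribution hazards from baseline risk when a causal specification is
preferred. Attributable deaths use the 1-year calibrated risks (annual
death framing); whether to use annual or lifetime-table deaths is not
canonical, and annual was chosen and documented. Profile life expectancies
(healthy: non-smoker, not heavy-drinking, ≥3 METs/day, diet ≥8;
unhealthy: heavy smoker, heavy drinker, <1.5 METs/day, diet <2) and
per-group equity tables reuse the same machinery; groups below 50
respondents are flagged rather than suppressed.

## Bootstrap uncertainty

Each replicate redraws (i) the coefficient vector from a multivariate
normal at the estimates with the fitted covariance and (ii) a
with-replacement respondent resample with weights rescaled to the
represented total, then recomputes every burden quantity. Percentile
intervals are reported because LE lost is skewed. Baseline survival and
calibration factors are held fixed across replicates, so their estimation
error is not propagated — the main reason intervals can run slightly
anti-conservative at small derivation sizes. A hook accepts user-supplied
replicate weights where a survey provides them; the exact
design-information bootstrap used with restricted survey files is not
reproducible outside those settings, and this two-source scheme is the
package's stated stand-in. Degenerate covariance falls back to
survey-only resampling with a warning.

## Synthetic cohorts

The generator emulates a national adult health survey: per-sex category
prevalences default to a recent application survey (e.g. male heavy-smoker
share 8.2%, heavy-drinker 20.3%), METs and fruit/vegetable frequencies are
log-normal matched to published medians/IQRs, ages follow
20 + 80·Beta(1.7, 3.4) (median ≈ 46, IQR ≈ 33–59), and weights are
log-normal (σ = 0.5) normalized to a represented population of 25.3 M.
Mortality is Gompertz in age per sex — (h₂₀ = 2.9e−4, slope 0.092/y for
men; 2.0e−4, 0.094 for women), chosen so unweighted crude rates land near
100–130 per 10 000 person-years — scaled by exp(true linear predictor)
with true hazard ratios of published magnitude (heavy smoking HR 2.8,
−0.09 per MET, −0.045 per diet point, …; the per-year quit-recovery
effect is −0.01 so a former smoker never undercuts the never-smoker
reference within the generator's 1–30 y quit range). A single latent
"unhealthiness" propensity (Gaussian copula, ρ = 0.35) correlates the
behaviours with low education and deprivation, making equity analyses
non-trivial. Follow-up is administratively censored at 5 years.

What the generator does **not** emulate: stratified multistage cluster
sampling and design effects, nonresponse, measurement error and
under-reporting (notably of alcohol), age-dependent comorbidity
prevalence, cohort trends in behaviour, and non-proportional hazards.
Passing tests therefore demonstrate internal correctness of the method
under a well-specified proportional-hazards world, not robustness to
those real-data features.

## Validation metrics

The concordance statistic restricts comparable pairs under left
truncation: a death at age t is compared only with subjects under
observation at t (entered before t, not yet exited); risk ties count ½ and
death-age ties are not comparable. This conditions the statistic on age
overlap, so its numeric level is lower than a calendar-time C computed on
the same data — the published comparable-pair rule for time-dependent
covariates is not fully specified anywhere we can check, and this rule is
our stated choice. The 90:10 ratio is the mean predicted risk of the top
decile over the bottom decile (n//10 observations each). Subgroup
calibration compares observed deaths within the horizon (respondents
censored earlier are excluded — simpler than inverse-censoring weighting
and adequate under administrative censoring) with the sum of predicted
risks; the C-statistic CI uses a respondent bootstrap (default 200
resamples).

## Problem sizes and numerical choices

Test-suite study sizes are chosen to put each check's noise floor well
below its assertion: parameter/attribution recovery uses the default
derivation cohort of 50 000 with a 20 000-respondent application survey;
decile self-calibration uses 120 000 so a 20% gap is ≈4 binomial SEs;
bootstrap coverage uses 100 replicates of (derivation 25 000, survey
2 000, B = 100) against a truth computed on 150 000 respondents. Ridge
penalization is off; fits failing to converge raise with the iteration
context rather than returning estimates. Follow-up times of zero are
nudged by 1e−6 years to satisfy entry < exit.

## Known limitations

* Baseline-hazard and calibration uncertainty are not propagated into the
  bootstrap (above).
* The interval-constant annual-risk approximation slightly distorts q in
  intervals with steep age gradients.
* Counterfactual recoding keeps mediators fixed; burden is a
  conditional-on-mediators estimate.
* The concordance level depends on the left-truncation comparability rule
  and is not comparable across rules.
* Exposure-distribution re-centering (a second calibration layer) is not
  implemented.
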