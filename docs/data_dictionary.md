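# Data dictionary

All tabular files are UTF-8 CSV with a header row; missing values are
empty cells. Categorical codes are lower-case snake tokens. Ages are in
years.

## Respondent survey (`lifeburden.io.read_survey` / `write_survey`)

Mandatory columns: `sex`, `age`, `weight`. Unknown columns are preserved
but ignored.

| column | type | meaning |
| --- | --- | --- |
| `id` | any | respondent identifier (row number if absent) |
| `sex` | `male` / `female` | sex |
| `age` | real, 20–99 | age at survey |
| `smoking_status` | `current` / `former` / `never` | smoking status |
| `cigs_per_day` | real ≥ 0 | daily cigarettes (current/former daily smokers) |
| `lifetime_cigs_lt_100` | bool | fewer than 100 lifetime cigarettes |
| `years_since_quit` | real ≥ 0 | years since quitting (former smokers) |
| `drinks_last_week` | real ≥ 0 | drinks in the previous week |
| `max_drinks_any_day_last_week` | real ≥ 0 | most drinks on any single day last week |
| `weekly_binge` | bool | ≥5 drinks on an occasion, weekly |
| `mets_per_day` | real ≥ 0 | average daily leisure METs (precomputed) |
| `activity_records` | list of (met, times/month, minutes) | alternative to `mets_per_day` (API only) |
| `fruit_veg_freq_per_day` | real ≥ 0 | daily fruit/vegetable frequency, juice excluded |
| `juice_freq_per_day` | real ≥ 0 | daily fruit-juice frequency |
| `potato_freq_per_week` | real ≥ 0 | weekly potato frequency |
| `carrot_freq_per_week` | real ≥ 0 | weekly carrot frequency |
| `material_quintile` | 1–5 | material deprivation quintile (1 = least deprived) |
| `social_quintile` | 1–5 | social deprivation quintile |
| `education` | `lt_hs` / `hs_grad` / `post_sec` | highest education |
| `years_since_immigration` | `imm_0_15` / `imm_16_30` / `imm_31_45` / `born_or_gt_45` | immigration recency |
| `heart_disease`, `stroke`, `cancer`, `diabetes` | bool | self-reported physician-diagnosed conditions |
| `bmi_ge_35` | bool | body-mass index ≥ 35 |
| `weight` | real > 0 | survey weight |
| `followup_years` | real ≥ 0 | follow-up time (linked cohorts only) |
| `died` | 0/1 | death during follow-up (linked cohorts only) |

Booleans accept `true/false`, `1/0`, `yes/no` (case-insensitive).

## Observed-rate table (`read_rate_table`)

| column | type | meaning |
| --- | --- | --- |
| `sex` | `male` / `female` | sex |
| `age_lo`, `age_hi` | real | age bin [lo, hi) |
| `rate` | real in [0, 1] | observed annual death risk per person |

## Risk algorithm (JSON)

`sex`, `terms`, `age_interactions`, `age_center`, `coefficients` (aligned
with `terms` then `age_x_<term>`), `s0` (baseline survival on integer ages
20–100), `coef_covariance` (optional), `calibration`
(age_lo/age_hi/factor), `schema_version`.

## Coded survey frame (in-memory, `exposures.code_survey`)

Meta columns `id`, `sex`, `age`, `weight` (plus `followup_years`, `died`
when present); categorical classes `smoking_class`, `alcohol_class`,
`deprivation`, `education`, `immigration`; and the numeric model terms
listed in `lifeburden.exposures.MODEL_TERMS`.

## Life table CSV

`age_lo`, `age_hi`, `q` (interval death probability), `l` (survivors of
100 000), `d` (deaths), `L` (person-years), `T` (cumulative person-years),
`e` (remaining life expectancy), `a` (years lived by decedents), `var_q`.
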