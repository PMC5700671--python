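# Methods

This note documents the statistical procedures, the generating model of the
synthetic EHR, the defaults and the numerical choices, in the package's own
terms. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Sodium categorisation

Admission serum sodium (mmol/L) is partitioned into seven bins:

| category          | interval      |
|-------------------|---------------|
| severe_hypo       | (0, 125)      |
| mild_hypo         | [125, 130)    |
| borderline_hypo   | [130, 135)    |
| normal            | [135, 145]    |
| borderline_hyper  | (145, 150]    |
| mild_hyper        | (150, 155]    |
| severe_hyper      | (155, ∞)      |

The bins partition the positive reals exactly: the hypo arm is half-open on
the right, the normal band is closed, and the hyper arm is half-open on the
left, so 135 and 145 are normal, 150 is borderline_hyper and 155 is
mild_hyper. The upper severe bound is > 155, consistent with the mild band
(150, 155]. Values must be finite and positive; sodium is taken as reported,
with no correction for hyperglycaemia. Bin edges are deliberately *not*
configurable: the partition is a definitional constant of the analysis and
the exact-boundary behaviour is pinned by tests.

## Cohort extraction

**Eligibility.** A stay qualifies if (i) at least one sodium value is
timestamped on the admission calendar date and (ii) the stay lasts at least
2 days, where duration = discharge date − admission date in whole calendar
days. The comparator is configurable (`>= 2` default, `> 2` optional)
because "at least two days" and "more than two days" are both defensible
readings of the inclusion rule. "Day of admission" means the admission
calendar date, not a 24-hour window. The admission sodium is the
chronologically first value of that date; exact timestamp ties are broken
by lab-table row order, deterministically.

**Severity-priority deduplication.** A patient hospitalised several times
may appear with different categories. The ladder
severe_hyper > mild_hyper > borderline_hyper > severe_hypo > mild_hypo >
borderline_hypo > normal assigns each patient the highest-priority category
among their eligible stays; the index stay is the earliest stay exhibiting
it (for all-normal patients, the first eligible encounter). The vectorised
implementation is verified against an independent nested-loop oracle.

**Covariates** are taken from the index stay only (an explicit convention;
"any stay" is the other defensible reading): stay flags (emergency
admission, ICU, surgery, palliative care, dialysis), length of stay, the
number of distinct diagnosis codes, dementia (presence of a configurable
code set, default F00–F03/G30), and the Charlson comorbidity index. Age is
computed at index admission, floor of years. Continuous covariates enter
models as the categorical bands listed in `dysnat.cohort` (age decades,
length-of-stay bands ≤7/…/>42 days, code-count bands, Charlson bands
0/1/2/3–4/5–9/≥10), each with the lowest band as reference.

**Charlson index.** Weighted sum of the original category weights over the
distinct comorbidity categories matched by the patient's ICD-10 codes, each
category once, with the usual hierarchy (metastatic disease absorbs
any-malignancy, moderate/severe liver disease absorbs mild, complicated
diabetes absorbs uncomplicated). The prefix mapping ships as an editable
CSV (`data/charlson_icd10.csv`) so sites can substitute their own
adaptation; the index is monotone under code-set inclusion, which is
property-tested.

## Descriptive statistics

Frequencies are compared across the seven categories with the chi-squared
test (no continuity correction); 2×2 tables with any expected cell < 5 fall
back to Fisher's exact test. For r×c tables with small expected cells no
exact fallback exists in scipy, so the chi-squared p is kept and a warning
logged. Skewed continuous variables are compared with Kruskal–Wallis (k > 2
groups) or the Wilcoxon rank-sum (k = 2): a *signed-rank* test is paired
and cannot compare independent groups, so it is deliberately not used.
Univariate mortality odds ratios are 2×2 cross-products against each
factor's reference level with Wald 95% CIs on the log scale; zero cells
receive the Haldane–Anscombe 0.5 correction and are flagged. Percentages
are displayed with one decimal.

## Phenome-wide screens

Codes are truncated to their 3-character ICD-10 category prefix. Three
screens are run: trait = death (whole cohort), trait = borderline
hyponatremia and trait = borderline hypernatremia (each compared against
normal-category patients only, configurable to rest-of-cohort). Every code
*observed in the analysed subset* is tested — m is data-determined, not an
ontology size — in a 2×2 table with the chi-squared score test and Fisher
fallback; a per-code univariate logistic option exists and agrees with the
table log-OR on clean tables (tested to 1e-6). The family-wise threshold is
α/m (α = 0.05 default) with strict inequality p < α/m. Confounders are the
intersection of the death-significant and exposure-significant code sets,
kept regardless of direction (protective codes are confounders too). Under
the global null the per-code test holds its nominal level and the
Bonferroni screen's family-wise error stays at or below α plus Monte-Carlo
error; both are checked by simulation in the acceptance suite.

## Adjusted models

`logit P(death) = β0 + β1·(category vs normal) + Σ βi·xi`, fitted by
maximum likelihood (statsmodels `Logit`). Two exposure modes exist: one
7-level factor with normal as reference ("all", used for dose-response
style output) and a pairwise mode restricting the cohort to one borderline
category plus normals (used for the model-comparison table). The classical
covariate set defaults to age, length of stay, number of codes, emergency
admission, ICU, dialysis, palliative care and the Charlson band — sex and
dementia are deliberately not in the default (the configurable
`classical_covariates` list can override). Three specs — classical, PheWAS
codes, combined — are compared by AIC (= 2k − 2 log L, identity asserted to
1e-8); exact ties go to the fewer-parameter model. Backward elimination
then removes, one per iteration, the screen code with the largest Wald
p > 0.05 from the combined model; classical covariates and the exposure are
never candidates. Wald inference throughout: CI = exp(β ± 1.96·SE).

Numerical policy for sparse designs: constant and collinear columns are
dropped (greedy rank completion, earlier columns kept); a 0/1 dummy whose
level has a constant outcome is quasi-separated and dropped; if a banded
covariate's *reference cell* has a constant outcome the whole dummy block
separates jointly, so the lowest remaining band is merged into the
reference until the cell is mixed; any term still exceeding |β| > 15 after
convergence is dropped and the model refit. All removals are reported in
`ModelFit.dropped_columns`. A separated *exposure* term is never repaired —
it raises a `FitError` naming the term, because silently altering the
exposure contrast would change the estimand. Rows with missing covariates
are dropped with a logged count.

The classical confounder screen tests each classical factor against the
seven-level category (one-way ANOVA on the numeric value for continuous
factors, chi-squared for binary ones) and against death (univariate
logistic, likelihood-ratio p), selecting factors with p < 0.05 on both —
the pattern by which a factor associated with mortality alone (or with
neither, like surgery in the default generating model) is excluded.

## Synthetic EHR generating model

One patient has 1 + Poisson(λ − 1) stays (default mean λ = 1.3); stay
length is min_stay_days − 1 + Geometric(p = 0.2) days (median ≈ 4); gaps
between admissions are uniform 14–365 days on a fixed 2010 epoch (only
durations matter downstream). Sex is male with probability 0.593, age at
first admission N(60.8, 18.5²) clipped to [18, 100]. **Sodium is drawn per
stay** from N(138.3, 3.9²) — so one patient can occupy different categories
across stays, which is exactly the branch the deduplication ladder must
resolve. Stay flags are independent Bernoulli at prevalences ICU 0.204,
emergency 0.121, dialysis 0.044, palliative 0.011, surgery 0.35.

Death per stay follows
`logit P = β0 + β_cat(category) + Σ βi·flag_i + β_age·(age−60.8)/10`,
with defaults β0 = −4.2 and category effects at the published adjusted odds
ratios (borderline_hypo 1.57, mild_hypo 2.48, severe_hypo 3.44,
borderline_hyper 3.47, mild_hyper 4.42, severe_hyper 4.07); surgery has no
mortality effect by design. β0 was set so the default deduplicated cohort's
mortality is ≈ 4% once the dispersion of the age and flag effects is
accounted for. After a death stay no further stays are generated, so death
occurs at most once per patient and always on the last stay.

**Code planting** supports two mechanisms:

* `outcome_conditional` (default): each panel code joins a stay with
  probability `expit(logit(p0) + b_e·exposed + b_d·death)` where `exposed`
  marks the configured exposure category. Conditioning on the realised
  outcome gives closed-form 2×2 target odds ratios, so marginal planted
  effects are directly recoverable from contingency tables (the screens'
  recovery tests use this). The price is that codes are *colliders* of
  exposure and death: adjusting for them in a regression is not expected to
  recover the exposure effect, and the package's own demo shows the
  collider-biased estimates this produces.
* `causal`: codes are drawn from exposure alone
  (`expit(logit(p0) + b_e·exposed)`) and `b_d·code` is added to the death
  linear predictor, making planted codes genuine confounders. Here the
  code-adjusted exposure coefficient targets the configured β_cat, the
  crude estimate is biased away from it, and adjustment moves the estimate
  toward truth — the behaviour the adjustment-recovery simulations assert.

The default panel contains the 13 published dual-associated codes (sepsis
A41, cardiac I20/I25/I48, aortic I71, pneumonia J15, ARDS J80, respiratory
failure J96, peritonitis K65, chest pain R07, shock R57, aftercare Z48/Z51)
at their published odds-ratio scales, padded with 47 null codes so screens
face a realistic multiplicity burden. Roughly 5% of stays lack an
admission-day sodium (they get a day-2 value instead, exercising the
exclusion path), 20% get a second same-day sodium at 14:00 (exercising the
first-of-day rule), and 20% of emitted codes carry a ".9" subcode suffix
(exercising 3-character truncation and prefix matching).

All randomness flows from a single `numpy` Generator seeded by
`SynthConfig.seed`; identical configurations produce byte-identical CSV
tables. `ground_truth()` returns every generator parameter keyed like the
fitted-model coefficients for recovery assertions.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: coding intensity that varies with admission type,
longitudinal disease progression, correlated comorbidity structure, seasonal
admission patterns, sodium measurement error or repeat-testing bias, and
informative missingness. Recovery results demonstrate the pipeline's
correctness under its stated model, not robustness to these violations.

## Problem sizes

The test and acceptance simulations use sizes chosen to make the assertions
statistically decisive on one CPU: parameter recovery runs once at
n = 50,000 patients (selection must be exact and the exposure coefficient
within 3 SE of log 2) and 50 replicates at n = 20,000 for the
adjusted-vs-crude direction check — the planted confounding bias is ≈ 0.49
on the log-odds scale, so replicate SEs must sit well below that for the
direction comparison to be informative. Error calibration uses 1,000
per-code null tests and 200 family-wise replicates; extraction is verified
on 1,000 random patient histories; the logistic-vs-cross-product oracle on
100 random tables (agreement to 1e-6).

## Known limitations

* Fisher's exact fallback exists only for 2×2 tables; r×c descriptive
  tests with sparse cells keep the asymptotic p (flagged in logs).
* Quasi-separation handling merges sparse bands into the reference; at
  very small n the fitted "band" coefficients therefore describe merged
  levels (always listed in `dropped_columns`).
* The per-code screen treats codes independently; no ontology rollup
  beyond 3-character truncation, no phenotype groupings.
* Printed univariate report ORs in the source material are not exactly
  reproducible from its own stratified counts; the package computes
  cross-product ORs and documents the discrepancy rather than matching
  either number.
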