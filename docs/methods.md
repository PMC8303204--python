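# Methods

`crfmet` implements a sex-stratified association analysis between
cardiorespiratory fitness — peak oxygen uptake (VO2peak, mL·kg⁻¹·min⁻¹)
measured by incremental spiroergometry — and a multi-platform plasma
metabolome panel, together with a synthetic cohort generator that makes
every stage testable end to end. This note records the statistical model
behind each stage, the defaults and why they were chosen, what the
generator does and does not emulate, and the numerical conventions.

## Data model

A cohort consists of a metabolite intensity matrix (samples × analytes)
and a phenotype table. Intensity cells are tri-state: a nonnegative
number, *below the limit of detection* (LOD), or *missing*. The two
non-numeric states are deliberately distinct: LOD cells carry the
information "present but small" and therefore participate in rank-based
transforms as a tied block at the bottom of the ranking, while missing
cells carry no information and propagate as missing. An analyte counts
as *detected* in a sample only when the cell is numeric; this detection
definition is a package convention (configurable) since "detected" can
reasonably be read either way for LOD cells.

Each analyte carries a platform label (NMR, GC×GC-MS, targeted GC-MS
fatty acids, and three LC-MS assays), a quantitative rank (1 = most
quantitative), an identification flag (identified compounds vs unknown
spectral features), one of eight major metabolic pathways (or `unknown`),
and an optional duplicate group linking the same chemical measured on
several platforms.

The phenotype table holds sex, age (18–80 y), menopausal status (women
only), VO2peak, and 21 phenotypical/clinical covariates: body
composition (lean body mass, fat mass %, visceral adipose tissue mass,
bone mineral content, height), blood biochemistry (hemoglobin, glucose,
insulin, HbA1c, triglycerides, HDL, LDL), hemodynamics and function
(resting heart rate, systolic/diastolic blood pressure, pulse wave
velocity, maximal vital capacity, FEV1), activity (activity energy
expenditure in kcal/day, total MET), and a diet-quality index. Only AEE
and PWV may be missing; they are imputed (below).

## Preprocessing

The pipeline order is fixed: duplicate resolution → detection-frequency
filter → per-sex Van der Waerden transform → confounder residualization.
The order matters (the frequency filter must see the de-duplicated
matrix; scores are sex-specific because all downstream statistics are)
and is asserted by the tests.

**Duplicate resolution.** Within each duplicate group only the analyte
with the smallest quantitative rank survives; ties break by platform
enum order, then analyte id, so the outcome is deterministic.

**Detection filter.** An analyte is kept iff its detection frequency is
at least 20% (default) in *both* sex subgroups; an analyte rare in
either subgroup is dropped.

**Van der Waerden (VdW) scores.** Values are ranked (average ranks on
ties; all below-LOD entries share the tied minimum rank), mapped to
(0, 1) as rank/(n+1), and transformed by the standard normal quantile
function. The n+1 denominator keeps the extreme quantiles finite.
Missing entries do not enter n and stay missing. The transform is
monotone and idempotent; a fully tied vector is degenerate and maps to
all-zero scores (or an error in strict mode). Scores are computed within
each sex subgroup, because every downstream statistic is sex-specific.

**Confounder adjustment.** Age (as VdW scores) and, in women, a 0/1
post-menopause indicator are removed from every variable by ordinary
least-squares residualization with intercept. "Adjusted for" is read as
OLS residuals — the conventional interpretation; residuals are mean-zero
and orthogonal to the covariates to ~1e-10, which the score container
validates.

**Covariate imputation.** Missing AEE/PWV values are imputed by a random
forest (500 trees, default split parameters, single pass) trained on
complete cases with age, sex, and the remaining covariates as features.
A single pass rather than iterated refitting keeps the step
deterministic and cheap; with only two sporadically missing covariates
the iteration would change little. Forest predictions are averages of
observed values, so imputations always stay within the observed range.

## Bivariate stage

For each analyte the partial Pearson correlation with VO2peak is the
correlation of the two residual vectors after removing the same
covariate set from both (joint residualization — standard partial
correlation). Two adjustment profiles are exposed: `star` (confounders
only) and `doublestar` (confounders plus all 21 covariates).

Significance is purely interval-based: the Fisher-z 95% interval
tanh(atanh(r) ± z₀.₉₇₅/√(n−3)) must exclude zero. Two conventions are
worth flagging. First, the standard error uses n−3 with *no*
degrees-of-freedom correction for the removed covariates; this is
validated against the worked interval examples in the test suite
(r = 0.37, n = 102 → (0.19, 0.53); r = −0.25, n = 150 → (−0.39, −0.09))
and makes the `doublestar` profile mildly anti-conservative (effective
df is n − 2 − 23, not n − 2). Second, there is no multiple-testing
control across the hundreds of analytes — both choices mirror the
method this package implements, and users should treat per-analyte
significance flags as descriptive screening, not confirmatory
inference.

Summaries: per-pathway counts of significant analytes under both
profiles (with a grand-total row that must equal the post-filter analyte
count — a cross-stage conservation law), and top-k tables of positive
and negative correlations with |r| ≥ 0.25 flagged as "relevant".

## Multivariate stage: PLS rank products

The multivariate association statistic asks which analytes contribute
*consistently* to predicting adjusted VO2peak from all analytes jointly.

Over 20 random 80/20 calibration/test splits (outer loop), a
single-response NIPALS PLS regression is fitted on the calibration
samples: predictors are unit-variance scaled using calibration means and
standard deviations, and the number of latent components (at most 10) is
tuned by a single random 8-fold cross-validation on RMSE (inner loop),
taking the smallest count within numerical tolerance of the minimal
RMSE. In each split every analyte is ranked by descending absolute
regression coefficient (rank 1 = most influential, average ranks on
ties, so each split's ranks sum to p(p+1)/2). The per-analyte **rank
product** is the geometric mean of its ranks across splits; model
performance is the mean test-set RMSE.

Significance comes from permutations of the adjusted response (default
2500 at full fidelity): an analyte's permutation frequency is the
fraction of permutations whose rank product falls *strictly below* the
observed one, and the analyte is significant when that frequency is
≤ 0.05. Ties count as not below. The permuted models' mean test RMSE is
recorded alongside: when permuted models predict no worse than the real
one, the multivariate association as a whole carries no information and
per-analyte significance flags should be disregarded.

Two permutation modes exist because the cost is dominated by re-tuning:
`full_refit` re-runs the whole outer procedure per permutation;
`fast_reuse` (default) keeps the observed splits and tuned component
counts and only refits the final models. The two modes agree on
significance calls in the planted-signal simulations; neither mode is
claimed to be uniquely faithful, since the original procedure's behavior
under permutation (re-tune or not, redraw splits or not) is
underdetermined. Permutations shuffle the *confounder-adjusted*
response: shuffling raw VO2peak would leak age/menopause group structure
into the null distribution.

The volcano table joins both views: x = partial correlation, y = −log10
of the permutation frequency floored at 1/(n_permutations+1) so an
empirical zero stays finite. The relevance classes follow the
interpretation rule: an analyte is relevant if |r| ≥ 0.25 or its
multivariate contribution is significant.

The orchestration adjusts all variables for confounders once, before
splitting. `outer_rank_products` performs unit-variance scaling inside
each split from calibration data only; re-estimating the confounder
regression itself inside every split is not currently wired into the
pipeline (a known limitation — with two confounders the leakage from
adjusting once is small, but it is leakage).

## Stepwise explanation models

Three approaches build linear models of adjusted VO2peak from adjusted
variables: (1) only the 21 phenotypical/clinical covariates compete;
(2) all 21 enter as a fixed block and only analytes compete; (3) all
variables compete. Entry is greedy in-sample R² maximization — no
p-to-enter, no backward elimination; ties break by variable id, and a
candidate that is collinear with the current model is skipped.

Stability selection: on each of 1000 (default) random 80/20 splits,
forward selection runs on the calibration set and each step's test-set
RMSE is tracked; selection stops the first time test RMSE rises, and the
degrading variable is excluded ("the last non-degrading model is kept").
Test-set evaluation starts after the fixed block, so fixed variables
never face the stopping rule. "Predictive accuracy decreased" is
operationalized as test RMSE increased; on a fixed test set this is
monotone-equivalent to test R², so nothing hangs on the choice. A
variable's selection frequency is the fraction of repeats in which it
survives; all variables at frequency ≥ 0.05 enter a final least-squares
model on all samples, reported with R² and adjusted
R² = 1 − (1−R²)(n−1)/(n−p−1).

## Cohort descriptives

Participants are grouped by sex-specific VO2peak quartiles (type-7
quantile convention; a value tied with a boundary falls into the lower
quarter — both conventions are package choices, stated because neither
is canonical). Numeric characteristics are compared across quarters by
Welch's heteroscedastic ANOVA with Satterthwaite denominator degrees of
freedom (implemented directly from the closed formula; validated against
an independent implementation in the tests), categorical ones by
Pearson's chi-squared test without continuity correction (a warning is
emitted when an expected cell is below 5). Relative means (quarter mean
over first-quarter mean) provide radar-plot-ready tables. Quarter
summaries are computed after AEE/PWV imputation, so every variable uses
the full subgroup n; summaries restricted to pre-imputation complete
cases are not reproduced.

## Synthetic cohorts

The generator draws cohorts with the statistical structure the analysis
assumes, with a ground-truth table, so that type-I error, power,
attenuation, and selection behavior can be measured. Defaults are the
study conditions: 102 women and 150 men, age uniform on [18, 80],
menopausal status switching by a logistic law centered at age 50,
120 analytes (scaled down from 427 to keep the full pipeline in
minutes; scalable by config).

VO2peak is generated per sex as
`a_sex − 0.35·age − b_fm·(FM% − FM%_mean) − 2·post + ε`, with b_fm and
the noise standard deviation calibrated so fat-mass percentage explains
≈ 33.5% (women) / 42.3% (men) of the age-adjusted VO2peak variance and
the pooled mean and SD sit near 38.9 ± 11.7 mL·kg⁻¹·min⁻¹. The 21
covariates are linear in age, FM%, and adjusted VO2peak plus noise, with
loadings chosen so their confounder-adjusted correlations with fitness
reproduce the reported profile: FM% dominant (|r| ≈ 0.6), visceral fat
≈ −0.45, HDL ≈ +0.35, pulse wave velocity ≈ −0.35, triglycerides
≈ −0.3, activity energy expenditure ≈ +0.2, the rest weak. When
computing such loadings the age component must be excluded from the
denominator, since adjustment removes it — an easy miscalibration
(documented in the repository history) that initially made PWV much too
strong.

Analytes fall into blocks with known roles. Sex-specific and shared
blocks load on the confounder-adjusted VO2peak z-score at a target
partial correlation drawn from (0.2, 0.4); confounder-only analytes load
on age; covariate-mediated analytes load on FM% with the loading scaled
by 1/corr(FM%, adjusted VO2peak) so that their *induced* fitness
correlation hits the configured target — these are the analytes that
must lose significance under the fully adjusted profile; the null block
is pure noise. Latent scores map to raw intensities through log-normal
marginals (the pipeline's rank-normal transform recovers the planted
correlations in expectation), each analyte is censored below a random
quantile up to 15%, a configurable fraction of analytes is duplicated
onto a second platform with multiplicative noise and a worse
quantitative rank, and AEE/PWV are set missing at 5%.

What the generator does *not* emulate: real metabolite covariance
(analytes are conditionally independent given their drivers), platform
batch/drift effects, distributional asymmetries beyond log-normality,
and peri-menopausal or unknown hormonal states. Passing tests therefore
demonstrate the statistical machinery's operating characteristics under
the planted model, not performance on real cohort data.

Two power properties are size-dependent by design and are measured at
larger n. Planted-effect recovery (empirical partial correlation within
0.05 of target) is checked at n = 2000. "FM% enters the model first" is
asymptotic: at the study scale, the maximum observed correlation over
~50 planted analytes with |r| ≤ 0.4 overlaps FM%'s sampling
distribution (≈0.58/0.65), so first entry is only near-certain at larger
cohorts; the property is verified, and the explained-variance anchors
reproduced, on 600-per-sex cohorts.

## Numerical conventions and problem sizes

* Reals serialize with 17 significant digits; text round trips are exact
  to 1e-12 relative error.
* Component-count ties in PLS tuning resolve to the smallest count
  within 1e-8 relative RMSE tolerance.
* Outer splits derive per-split child seeds from the run seed, so any
  split can be regenerated in isolation; every pipeline stage receives
  its own deterministic sub-seed, printed in the run manifest.
* The test and acceptance suites run at scaled-down sizes chosen to keep
  the whole battery within minutes on one CPU: null suites with p = 60
  analytes and 200 permutations in `fast_reuse` mode, dominant-analyte
  recovery over 8–10 seeded runs at p = 40, attenuation over 2–3
  study-scale cohorts, stepwise stability with 40–60 repeats, and
  selection-dominance checks on 600-per-sex cohorts. Full-fidelity
  settings (2500 permutations, `full_refit`) are available through
  configuration; the CLI warns about their cost.

## Known limitations

* CI-based significance without df correction or multiplicity control is
  a faithful but statistically lenient convention (see above).
* Confounder adjustment happens once, outside the resampling loops.
* Below-LOD handling assumes a shared detection limit per analyte; the
  generator censors at one quantile per analyte accordingly.
* The final stepwise models inherit all the usual caveats of
  post-selection inference; no coefficient inference is offered.
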