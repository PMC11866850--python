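# Methods

This note documents the models, conventions and design choices behind
`actifrail`, in the order the pipeline runs them.

## Synthetic cohort generator

The generator (`actifrail.synthetic_cohort`) emulates a prospective
accelerometer sub-cohort of ~78k community-dwelling adults aged 45–80:
7 consecutive 24-h wear days recorded in 30-s epochs, 49 self-reported
health deficits, a standard covariate panel, and all-cause mortality
follow-up. Its defaults are the study conditions every test runs under.

**Demographics.** Age ~ truncated normal(62.0, 7.8²) on [45, 80] years;
55.5% women. These match the cohort descriptives the generator targets.

**Exposures.** A Gaussian copula links a latent frailty liability and the
four exposures. Marginals: TVPA and MVPA are lognormal (right-skewed,
positive) matched to mean (SD) 38.4 (11.9) mg and 0.517 (0.447) h/day;
LPA and ST are zero-truncated normals matched to 5.27 (1.58) and
7.98 (1.60) h/day. The correlation targets are round values with the
expected signs (activity measures positively related, each negatively
related to sedentary time; liability negatively related to activity) —
cohort reports of this design publish the correlation structure only
graphically, so these are design choices, not estimates. Behaviour hours
are capped at the 16-h awake window with ST renormalised as the remainder.

**Deficits and frailty.** Each participant carries one standard-normal
liability. Binary item j has deficit probability
expit(a_j + shift + b_j·(liability + 0.42·age_z)); the 40 binary base
prevalences are spread log-odds-linearly between ~2% and ~25%, and the 9
ordinal items (five 3-level, four 5-level, equally spaced scores) use the
same linear predictor against evenly spaced thresholds drawn with a single
uniform. The global shift (−0.30) and loading (0.60) were calibrated once,
by simulation at the defaults, so the cohort splits ~63% / 33% / 4% across
robust / pre-frailty / frailty — the prevalence structure of the cohort the
generator emulates. FI right-skew follows automatically from the
low-prevalence items.

**Injected hazards.** Ground truth is a proportional-hazards model on the
9 joint groups (FI category × TVPA tertile, computed on the generated
sample itself). Default true HRs versus robust × T1 run from 0.62
(robust × T3) to 1.90 (frail × T1); the extreme contrast frail-inactive vs
robust-active is ≈ 3.05, the scale reported for cohorts of this design.
The baseline hazard is Gompertz in attained age with shape ln 2 / 8 per
year (mortality doubling every 8 years) and rate 1.03 × 10⁻³ at age 50,
the latter calibrated once so the default cohort experiences ~2.9% deaths.
Event times come from exact inverse-transform sampling; censoring is the
administrative horizon (8.15 y minus a uniform 0–2.5 y recruitment offset,
giving a ~6.9-y median follow-up) plus a 0.2%/year dropout hazard.
Because the true hazard is log-linear in age, a Cox model with the group
indicators plus linear age is *correctly specified*, which is what makes
the parameter-recovery and CI-coverage tests exact rather than approximate.

**Epochs.** Per participant and day, behaviour-labelled epochs are laid out
in blocks inside 06:00–22:00 (sedentary, light, MVPA, then waking-rest
labelled sleep); night epochs are sleep. Counts are the target hours
rounded to whole 30-s epochs, so aggregation reproduces the targets to
within 1/240 h. Per-epoch ENMO is gamma noise (shape 4) around
behaviour-specific levels, rescaled per participant so the pooled
awake-window mean equals the TVPA target exactly. Epoch streams are keyed
on (seed, participant id), so output is identical however the cohort is
chunked. Wear schedules are a mixture: 72% full weeks, 25% missing 1–2
weekdays, 3% invalid (2 days only, or weekdays only) to exercise the
exclusion filters.

What the generator does **not** emulate: raw 100-Hz signal, device
calibration and non-wear artifacts, circadian or seasonal behaviour
patterns within the day (block layout is temporally unrealistic but
irrelevant to window-based aggregation), informative (non-MCAR)
missingness, and covariate–outcome confounding (covariates other than age
are independent of the hazard, so adjusted and unadjusted fits estimate the
same group contrasts). Passing tests therefore demonstrate correctness of
the estimators under the stated model, not robustness to real-data
violations of it.

## Frailty index

Complete-case by default: any missing item flags the participant
`incomplete` for upstream exclusion, mirroring designs that require
complete 49-item data. An optional `min_fraction_scored` mode rescales the
denominator to the items scored. Category boundaries assign 0.12 to robust
and 0.24 to frail, matching the "≤ 0.12" and "≥ 0.24" anchors of the
category definitions. The default codebook is a structurally faithful
synthetic stand-in (the published item list lives in access-controlled
supplementary material); it is user-overridable via JSON.

## Exposure derivation

* Day validity: ≥ 75% of the 24 h covered by epochs (configurable); this
  threshold is a QC convention, not a published constant.
* TVPA pools ENMO over awake epochs across valid days (not day-means of
  means); the difference is second-order.
* Sleep-labelled epochs inside the awake window count toward TVPA (the
  total volume is defined by the clock window) but not toward MVPA/LPA/ST.
* Tertile cuts at the 33⅓ / 66⅔ percentiles (linear interpolation) with
  ties resolving to the lower tertile; labels are therefore invariant to
  monotone transforms of the exposure.

## Survival models

Efron's approximation handles tied event times (month-resolution follow-up
produces many ties); fits use a Newton tolerance of 1e-9 so toy fits agree
with brute-force partial-likelihood maximisation to 1e-4. Assessment
centre enters as a fixed categorical covariate, not strata. The restricted
cubic spline uses Harrell's truncated-cube parameterisation (k knots →
k−1 columns, linear beyond the boundary knots), knots and reference on the
FI-stratified analysis sample. RERI CIs default to the parametric
bootstrap (reusing the life-table bootstrap machinery); the delta method is
available as an option. The proportional-hazards check regresses
Schoenfeld residuals on the rank of event time in the Grambsch–Therneau
form, using the fit covariance as the average-information approximation;
its type-I error is verified by simulation in the test suite. Two-sided
α = 0.05 throughout, no multiplicity correction.

## Life expectancy

Conventions, declared rather than inferred (they are rarely printed in
papers of this design):

* Rate → probability: q(a) = 1 − exp(−m(a)); person-years
  L(a) = l(a)·(1 − q(a)/2) (deaths at mid-year, a_x = 0.5).
* Closed cohort over integer ages 50–100 inclusive (51 year-rows); no
  open-ended interval and no forced terminal death, so for constant hazard
  the table agrees with the analytic integral of e^(−mt) over the 51-year
  horizon to < 0.05 y, and exactly with the geometric series
  Σₖ e^(−mk)(1 − q/2).
* HRs are applied age-constant within sex; prevalences are the observed
  sex-specific group frequencies of the analysis cohort.
* The reference-rate back-calculation m_ref = m_pop / Σ p_g·HR_g is the
  unique construction that reproduces the population rates exactly as the
  prevalence-weighted average of the group rates — an identity the tests
  check at machine precision.
* Bootstrap: β* ~ MVN(β̂, Σ) via Cholesky (PSD-projected with a warning if
  Σ has negative eigenvalues), percentile 2.5/97.5 CIs, default 10,000
  runs (reduced in tests), fully seeded.

## Pipeline

Exclusion cascade in flowchart order: invalid wear → incomplete FI →
missing mortality → age < 45, with optional landmark (drop deaths in the
first 2 years) and shift-worker exclusions as sensitivity toggles. The log
telescopes exactly. Covariate imputation is mode/median by default;
`forest-iterative` runs sklearn's chained iterative imputer with
extra-trees regressors on integer-coded categoricals (a tree-ensemble
analogue of missForest-style imputation). Outcome, exposure and deficit
columns are never imputed. Re-running a configuration is byte-identical;
every stochastic stage draws from an explicitly seeded generator.

## Problem sizes and tolerances in the test suite

The suite validates distributional claims at sizes chosen for statistical
power per CPU-second: calibration of the default generator at the full
n = 78,508 (epoch emission subsampled to 10,000 participants);
CI coverage of the 9-group model over 500 replicates of n = 5,000;
LRT type-I error over 500 null replicates of n = 1,500; life-expectancy
bootstrap coverage over 400 replicates of 1,000 runs. Reduced-size
replicates raise the Gompertz baseline rate (4–5 × 10⁻³ at age 50) so the
sparse frail cells carry enough events for stable fits — a power choice,
not a change to the injected hazard ratios. Coverage assertions use the
93–97% band appropriate to binomial noise at these replicate counts.

## Known limitations

* The deficit codebook is synthetic; FI distributions match in structure
  (category prevalences, right skew), not item-by-item.
* Injected truth ties hazards to the TVPA-based joint groups only; for the
  other three exposures the generator induces effects indirectly through
  the exposure correlations, so their joint tables are qualitative.
* MCAR missingness only; the forest-vs-simple imputation comparison is on
  recovery RMSE, not downstream bias.
* Sex-specific life-table fits need every joint cell to carry events;
  at desk scale this requires either n ≳ 8,000 or a boosted event rate.
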