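# Methods

## Accelerometer data reduction

Raw input is a per-child series of non-negative integer counts at a fixed
epoch length (1 s by default; any divisor of 60 s). Reduction proceeds in
this order:

1. **Non-wear detection** on the full 24 h record: maximal runs of
   consecutive *strictly zero* epochs lasting ≥ 60 min. No spike tolerance
   is applied — a single non-zero epoch breaks a run. Detection precedes
   windowing so that a zero-run straddling 06:00 still counts as non-wear.
2. **Windowing**: only epochs with clock time in [06:00, 24:00) contribute
   to wear. The upper bound is taken as midnight exclusive, i.e. a
   1080-minute ceiling.
3. **Band classification** per epoch against cpm cut-points via the cpm
   equivalent count × 60 / epoch_s; bands are integer-bounded and
   contiguous (0–99, 100–249, …, 9500–9999, ≥ 10 000 — 23 bands). Broad
   categories use their own cut-points (sedentary 0–99, light 100–2295,
   moderate 2296–4011, vigorous ≥ 4012 cpm); these do not align with the
   23-band edges, so broad minutes are accumulated per epoch, never by
   summing bands.
4. **Validity**: a day is valid with ≥ 8 h wear (boundary inclusive); a
   child is valid with ≥ 4 valid days. Profiles average band minutes over
   valid days only; invalid children are returned flagged, not dropped
   silently. Total activity is Σ counts during wear / Σ wear minutes over
   valid days (cpm).

Single-axis counts are assumed throughout; no imputation of non-wear time
is attempted.

## Outcome scoring

The physical well-being scale sums five ordinal items (1..5, optional
reverse-keying) into a raw score 5..25 and maps it linearly to a T-score,
t = 50 + 10 (raw − ref_mean)/ref_sd. Reference moments default to the
complete-case sample moments; official norm-table (Rasch) scoring is not
reproduced, so absolute T-levels are comparable within a cohort but not
against published norms. Children with any missing item are excluded
(complete-case policy) and counted in the exclusion cascade. Cronbach's α
uses sample variances with the n−1 denominator; floor/ceiling effects are
exact counts at the scale bounds.

## Adjustment

Only the outcome is residualized (OLS with intercept, via statsmodels);
predictors enter raw. Residualizing X as well is available as a
sensitivity option (`residualize_x=True`). The covariate set follows the
stratification: total sample {age, sex, waist}; sex strata {age, waist};
sex × weight strata {age} — a stratifying variable is never also adjusted
for. Standardization (mean 0, SD 1, n−1 denominator) is computed within
each stratum after subsetting, which keeps the outcome unit-variance in
every model; zero-variance columns are dropped with a logged warning.

## PLS, component selection, inference

PLS1 components are extracted by NIPALS deflation; the regression vector is
b = W (P′W)⁻¹ q, where P′W is unit upper-triangular, and an A-component
path costs one pass, so cross-validation reuses a single extraction per
split. Extraction stops early (logged) if the residual outcome becomes
numerically orthogonal to the deflated predictors.

Component count: Monte-Carlo cross-validation with 100 repetitions of
random 50/50 child-level splits (unstratified). Candidate sizes are
0..A_max (default 10); A = 0 predicts the calibration mean, making "no
predictive model" reachable. Within each repetition, centering uses
calibration means. The selected A minimises the median RMSEP over
repetitions; ties go to the smaller A.

Per-band effects are multivariate correlation coefficients from target
projection: r_k = corr(x_k, X b/‖b‖), identical to corr(x_k, ŷ). 95% CIs
are percentile intervals of r_k over refits (selected A) on the 100
calibration halves, each refit sign-aligned to the full-data regression
vector, since PLS directions are sign-indeterminate across subsamples. A
band is flagged significant when its CI excludes zero; no multiplicity
correction is applied across the 23 bands, so under a global null roughly
one band in twenty is flagged. The CI construction is a documented choice —
resampling-percentile methods vary across software and none is canonical
for this estimator.

Explained variance is reported twice: calibration R² (1 − SSE/SST of the
full fit, non-decreasing in A) and validated R² = 1 − median RMSEP(A)²
(variance of the standardized outcome is 1). The validated figure is the
headline number. Note its interpretation: it measures the *half-sample*
model's prediction error, so it sits systematically below the population
R² of the generating signal — with n ≈ 700, 23 predictors and a true R² of
0.09, the expected shortfall is roughly 0.01–0.02 and no generating
structure removes it without concentrating the signal into a single
dominant predictor direction. Simulation checks against a known generating
R² should therefore expect this pessimism; it is the price of reporting a
cross-validated rather than an in-sample quantity.

## Synthetic cohorts

The generator defines the study conditions and is itself tested code.

* **Covariates**: age ~ N(10.2, 0.3²) years, waist ~ N(61.8, 7.4²) cm,
  51% boys; covariates are independent of activity by default (the joint
  distribution is not identified by published summaries). Overweight/
  obesity is a per-sex waist cutoff at the (1 − prevalence) quantile of
  the generating distribution — a stand-in for age- and sex-adjusted
  reference values, with prevalence 0.20 (typical for Norwegian
  10-year-olds and large enough to keep sex × weight strata above the
  n = 50 modelling guardrail).
* **Band minutes**: per-sex means/SDs fixed to observed magnitudes for
  10-year-olds (sedentary ≈ 600 min/day declining to < 1 min/day at
  9500–9999 cpm). Deviations follow a stationary AR(1) process along the
  band axis (adjacent-band correlation 0.6, decaying with band distance;
  sedentary sign-flipped so it opposes activity; an optional global
  activity factor can be mixed in). Local correlation dominating
  long-range correlation reflects that neighbouring bands are fine
  subdivisions of the same behaviour; a single global factor instead makes
  the selected PLS direction the factor itself and washes the correlation
  profile flat, which would make peak-position recovery meaningless.
  Values are truncated at zero.
* **Outcome**: y = standardized(band minutes)·β + ε, mapped affinely to
  the T scale. The default β is the `rising_peak` profile: −1 for
  sedentary time, a gentle positive floor (≈ 0.05–0.1) across active
  bands, and a locally prominent peak of 1.0 at band 14 (6000–6499 cpm)
  with shoulders 0.6/0.3 below and 0.75/0.4 above (the higher right
  shoulder encodes the plateau-then-diminish shape above the peak). Noise
  is either explicit (noise_sd) or solved from a target signal R²
  (default 0.09). Per-group amplitude multipliers support stratified
  scenarios; `stratified_scenario_config()` uses 1.5 / 1.0 / 1.25 / 0.0
  (boys ow, boys normal, girls ow, girls normal) with an overall target
  R² of 0.20 — higher than the post-adjustment totals it produces, because
  residualizing on waist and sex absorbs part of the group-differentiated
  signal.
* **Items**: five ordinal items from the latent well-being plus
  independent N(0, 1.118²) noise, rounded and clipped to 1..5, centred at
  3.6 so ratings skew high (ceiling > floor, as observed for child
  HRQoL). The implied inter-item consistency is α ≈ 0.75–0.8. The
  analysis outcome defaults to the continuous T-score; analysing the
  scored item sum instead (`outcome="scored_items"`) attenuates R² by
  ~20% through discretization.
* **Epoch series**: a two-state (sedentary / activity-bout) semi-Markov
  process at 1 s resolution — exponential sedentary gaps (20 bouts/h),
  lognormal bout durations (median 45 s) and intensities (median 1500
  cpm, σ = 1), Poisson counts within bouts, occasional single counts in
  sedentary time (so worn idle time is not mistaken for non-wear), zeros
  overnight, and 60–90 min injected non-wear blocks. It feeds the
  reduction tests; cohort-scale statistics are drawn directly from the
  band-minute model above, which is several orders of magnitude cheaper
  than simulating 722 × 7 × 86 400 epochs and equivalent for every
  analysis stage downstream of reduction.
* **Reproducibility**: all randomness flows from one root seed; per-child
  epoch series use spawned per-child seeds, so cohorts are reproducible
  under parallel generation.

What the generator does **not** emulate: triaxial/vector-magnitude signals,
seasonal or weekday structure, covariate–activity dependence, informative
missingness, and the real joint band distribution beyond its first two
moments and local correlation. Passing tests therefore certify the
machinery (rules, estimators, selection, inference) under a controlled
truth, not distributional realism of any particular cohort.

## Numerical choices and degenerate inputs

* Band bounds are integers, inclusive on both ends; contiguity is
  guaranteed by construction. The open top band uses a representative
  midpoint of 12 000 cpm where a scalar summary (total cpm) is needed.
* Zero-variance predictor columns are dropped (logged); a zero-variance
  outcome raises.
* Rank-deficient covariate designs raise an error naming the collinear
  columns.
* Strata below 50 children return `no_model` ("insufficient n") — an
  artifact guardrail, not a substantive rule.
* Median-RMSEP ties select the smaller A (parsimony); argmin takes the
  first index.
* Early-stopped PLS paths reuse the last fitted model's error for larger
  candidate sizes.
* All report files serialize deterministically (sorted keys, fixed float
  formats, no timestamps); two runs with one seed are byte-identical.

## Problem sizes

Default analysis settings (100 MCCV repetitions, A_max = 10, 23 bands,
cohorts of 400–722 children, 50-seed simulation batteries for recovery and
null checks) run the full test suite in well under a minute on one CPU;
the complete seven-stratum pipeline takes ~1 s per cohort. These sizes are
the package's chosen defaults for desk-scale verification and match the
magnitudes of the motivating study design.
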