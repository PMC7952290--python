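# Methods

This note documents the statistical content of `utilmap`: the models, the
numerical choices, what the synthetic-data generator does and does not
emulate, and the design decisions taken where more than one reading was
defensible.

## Instruments and scoring

QoL-AD responses are encoded poor→1, fair→2, good→3, excellent→4
(case-insensitive labels or integer levels). The 13-item composite is the
plain item sum (13–52). When item 7 (marriage) is excluded — the default,
because that item is inapplicable for many respondents and drives most
item-level missingness — the 12-item sum (range 12–48) is standardised back
onto [13, 52] by the unique affine map

    score = 13 + (sum_of_12 − 12) × 39/36.

The source material states only that the reduced score is "standardised to
maintain a range from 13 to 52"; this formula is adopted because it is the
one affine map consistent with that range and it reproduces all three
printed worked examples (sums 23, 32, 42 → 24.9, 34.7, 45.5 at 1 d.p.).
Full precision is kept internally; rounding to 1 d.p. is display only.

## Value sets and crosswalk

EQ-5D-3L tariffs are additive:
`u = 1 − c·1{any level>1} − Σ_d δ(d, level_d) − n3·1{any level=3}`,
with all decrements ≥ 0, so full health is exactly 1 and utility is
monotone non-increasing in every dimension. The published UK (Dolan)
coefficients ship as `data/uk_tariff_3l.csv`. Value sets are data, not
code: any tariff in the same CSV schema loads with `load_value_set`.

5L→3L crosswalks are exact 3,125-row lookup tables, validated on load
(complete key set, no duplicates, utilities ≤ 1). The published crosswalk
table is licensed material that does not ship here;
`synthetic_uk_crosswalk()` constructs a clearly-labelled synthetic stand-in:
each 5L level is spread onto the two nearest 3L levels (1/3/5 map exactly
to 3L 1/2/3; levels 2/4 split 50:50, independently across dimensions) and
each 5L state receives the expected UK-tariff utility of the induced
3L-state distribution, rounded to 6 decimals. The stand-in preserves the
structural properties the pipeline relies on (full health = 1, worst state
= UK 3L worst = −0.594, monotonicity); it is not the published valuation.
Every test that depends on crosswalk correctness also runs against toy
tables, so nothing hinges on the stand-in's provenance. Analyses intended
for publication should load the official table via `load_crosswalk`.

## Scenario assembly

A scenario fixes (predictor rater, target rater, item-7 inclusion, age/sex
inclusion). Complete-case filtering keeps rows with every required QoL-AD
item, the target utility, and (when included) age and sex; inclusion and
exclusion counts are reported. Predictor encodings:

- `score`: the standardised composite as one continuous column;
- `categorical` (the default for almost all families): each item as
  indicator contrasts with level 1 (poor) as reference, so the intercept is
  the all-poor case;
- `continuous_items`: each item as a continuous 1–4 score.

Age enters uncentred in years; sex as a male indicator (female reference).
The coding is arbitrary but serialised with every model, so predictions are
coding-invariant. Item levels never observed in the estimation data are
dropped from the design with a warning (the sparse-cell problem typical of
these data); at prediction time a row exhibiting such a level raises an
error rather than being silently mapped to the reference level.

## Direct mapping families

- **OLS** (continuous score or categorical items), predictions clamped
  above at 1.
- **Tobit**: observed utility y = min(y*, 1), y* ~ N(x'β, σ²); maximised
  log-likelihood Σ_unc [log φ((y−x'β)/σ) − log σ] + Σ_cens log Φ((x'β−1)/σ)
  over (β, log σ) by BFGS with the analytic score, started at OLS.
  Predictions use the censored expectation
  E[min(y*,1)] = 1 − [(1−x'β)Φ(a) + σφ(a)], a = (1−x'β)/σ, which is
  strictly below 1 for all finite parameters (the shortfall is positive by
  the Mills-ratio inequality); the cruder min(x'β, 1) is available via
  `predict(kind="clamped")`. The censored expectation is the default
  because fitted maximum predictions strictly below 1 are the observable
  signature of a censored-mean predictor.
- **CLAD** (Powell): iterate {exact LAD fit on the kept rows; keep rows
  with x'β̂ < 1} until the kept set is stable, cap 400 iterations. LAD
  subproblems are solved exactly as linear programs (HiGHS), giving
  reproducible tie handling. On hitting the cap the last iterate is kept
  with a warning — the trimming sequence can cycle, a known property of the
  estimator. No standard errors are reported for CLAD (Powell SEs need a
  density estimate at the median; out of scope), and no cluster adjustment
  is applied to it.
- **Two-part**: logistic model of 1{utility = 1} plus OLS on the rows below
  the ceiling, combined as Utility = Pr + (1 − Pr)·Y and clamped at 1.
  Separation or cap problems in the logistic part retain the last iterate
  with a warning.

Only the ceiling at 1 is modelled as censoring; the utility floor is left
free, since the motivation for the censored families is the mass of
observations at full health.

## Response mapping

One model per EQ-5D-5L dimension from the shared design: multinomial logit
(reference = lowest observed level), ordered (proportional-odds) logit, or
OLS treating the level as continuous, with OLS predictions converted to a
one-hot distribution at the fitted value rounded to the nearest level —
halves rounding toward the worse level (a fixed, serialised convention) —
clamped to [1, 5]. Levels never observed get structural-zero probability.

The five per-dimension distributions are combined assuming independence
across dimensions (each dimension is modelled separately, so no dependence
structure is estimated); the default utility conversion is the exact
expectation over all 5⁵ = 3,125 joint states,

    E[U] = Σ_s [Π_d p_d(s_d)] × crosswalk(s),

computed by tensor contraction with no sampling. A modal-state conversion
(per-dimension argmax, ties to the lower level, one crosswalk lookup) is
provided as the alternative reading; the expectation is the default because
it is deterministic and is the estimand cost-effectiveness analysis needs.
No penalisation is applied to perfectly-predicted sparse cells; the fitted
coefficients are reported as estimated, with convergence flags.

## Estimation numerics

Iterative fits cap at 200 iterations (400 for the CLAD trimming loop);
non-convergence keeps the last iterate, flags the results object and warns.
Before likelihood fits the design columns are max-abs rescaled — an exact
reparameterisation undone on the returned coefficients — so indicator
columns and age (scale ~80) condition the optimiser comparably; multinomial
logit tries Newton first and falls back to L-BFGS when the Hessian is
singular (sparse cells). Rank-deficient designs raise an error naming the
aliased columns, found by pivoted QR.

Cluster-robust covariance (repeated visits within subject) is the sandwich
estimator with score contributions summed within clusters and a G/(G−1)
small-sample factor; it affects standard errors only, never point
estimates. With singleton clusters it reduces to the HC0 estimator times
n/(n−1).

## Evaluation

RMSE, MAE and "accuracy within 0.1" (|error| ≤ 0.1, boundary inclusive —
the convention here, since the source is silent on the boundary) are
computed on the final, post-clamping predictions, pooled over observations.
Calibration rows use quartiles of the observed utilities (type-7 sample
quantiles; boundary ties to the lower quartile) and summarise the
predictions per quartile by median, IQR and 10th–90th centiles.

## Synthetic data generator

`simulate_dataset` emulates the data structure a mapping study of this kind
rests on: ~450 subjects × 3 visits (defaults), a latent health factor with
between-subject SD 0.8 and within-subject SD 0.6, 13 QoL-AD items obtained
by thresholding the latent plus item noise (thresholds set so an average
self-rated composite sits near 35 with SD ≈ 6–7), proxy ratings shifted
down by 0.55 latent SD (composite ≈ 5 points lower), age ~ N(78, 8²), 55%
female, and 13% extra missingness on item 7. EQ-5D-5L items are drawn from
known multinomial-logit models whose linear predictors depend on the
realised standardised composite score, age and sex; because the composite
is an additive function of the items, both the score-encoded and the
categorical mlogit response mappers are correctly specified, making
parameter-recovery tests well-posed. A `misspecified=True` variant draws
the EQ-5D items from the latent factor directly so that no fitted mapper is
exactly correct. Utilities come from the crosswalk, so the ceiling arises
mechanically from the full-health state. The intercept shift that sets the
full-health fraction is calibrated once per dataset (deterministically,
by root-finding on the realised predictors of the self-rated scenario) to
the configured `ceiling_target` (default 0.20); proxies, scoring lower
under the same response process, land below it. Default slopes were chosen
so the Spearman correlation between composite score and utility is ≈ 0.5
and the self-rated utility distribution has mean ≈ 0.78, SD ≈ 0.22 —
the regime typical of dementia cohorts.

All draws come from a single `default_rng(seed)` stream in documented order,
so datasets are byte-reproducible. What the generator does *not* emulate:
item-level residual dependence between specific QoL-AD and EQ-5D items
beyond the shared score, country/language effects, cognitive-staging
covariates, informative dropout, or non-monotone rater disagreement. Tests
passing on these data therefore demonstrate algorithmic correctness and
self-consistency, not predictive performance on any real cohort.

Problem sizes used in the checks: recovery tests run at n ≈ 5,000
observations, the model-ranking self-consistency check at 450 subjects × 3
visits, Monte-Carlo oracles at 10⁶ draws — sizes at which sampling error is
small relative to the 3-standard-error acceptance bands while the full
suite stays comfortably runnable on one CPU.

## Known limitations

- CLAD reports no standard errors and can cycle (capped, flagged).
- The shipped crosswalk is a synthetic stand-in (above); results on it are
  methodologically faithful but not valued on the published tariff.
- No uncertainty intervals around predicted utilities are produced.
- The independence assumption across EQ-5D dimensions in the expected-
  utility conversion ignores residual correlation between dimensions.
- Missing QoL-AD items are never imputed; rows are excluded (estimation) or
  flagged (application).
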