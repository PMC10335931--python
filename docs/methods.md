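# Methods

This note records the statistical procedure infantfm implements, the
choices made where the procedure leaves room, and what the synthetic
benchmarks do and do not establish.

## Data model

One observation is one infant at one visit (1, 3, or 6 months): sex,
gestational age at birth (weeks, ≥ 37 — term infants only), age in days,
weight (kg), length (cm), head/mid-upper-arm/waist/thigh/calf
circumferences (cm), biceps/triceps/subscapular/waist/thigh/calf
skinfolds (mm), and — when available — reference fat mass (kg) from
air-displacement plethysmography. BMI (kg/m²) is always derived from
weight and length; an input BMI column is ignored (with a logged warning
when it disagrees beyond 0.05 kg/m²). Duplicate anthropometric readings
resolve to their mean; a skinfold pair differing by more than 2 mm
requires a third reading, and the resolved value is then the mean of all
three (the symmetric choice; a median-of-three rule is available via the
`rule` argument). Records with fat mass below 5% of body weight are
excluded from development — values that low are below the minimum
reported for healthy term infants and indicate a measurement problem.
The boundary is strict: exactly 5.0% is retained.

## Step 1 — stability selection by vote counting

Sixteen candidates: sex (female = 0, male = 1), gestational age, weight,
length, BMI, the five circumferences, the six skinfolds. BMI joins the
directly measured candidates because the final published equations use
it even though it is a derived quantity.

Records are ranked by measured FM and cut into five contiguous rank bins
whose sizes differ by at most one (remainders go to the lowest-rank
bins; ties break by stable original order), so that every subsample
spans the outcome range. Each repetition draws round(0.8 · bin size)
records per bin (minimum one) without replacement, chooses its own L1
penalty, and fits the LASSO with predictors standardized internally to
mean 0 / SD 1 (population SD). Coefficients are returned on the original
scale, preserving exact zeros; the intercept is unpenalized. The
objective is ½·MSE + λ‖β‖₁, the scikit-learn coordinate-descent
parametrization.

Penalty choice per repetition (`lambda_rule`):

* `cv` (default): minimize 5-fold cross-validated MSE over a 30-point
  geometric grid from λ_max (the smallest penalty that zeroes every
  coefficient) down to 10⁻³·λ_max. Folds are contiguous, deterministic
  splits of the subsample; each training block is re-centered before the
  interceptless path fit. Data-driven penalties are what make the
  repetition-to-repetition variability informative for vote counting.
* `lambda_1se`: the largest penalty within one standard error of the CV
  optimum (the glmnet-style parsimonious rule).
* `fixed`: a user-supplied constant.

Default scope: 100 blocks × 12 repetitions = 1200 coefficients per
candidate. A variable is selected when |β| > 10⁻¹⁰ (distinguishing exact
zeros from back-transformation round-off) in at least 500 repetitions. A
failed repetition is recorded as all-zero coefficients and still counts
in the denominator. The whole stage is deterministic given its seed.

## Step 2 — cross-validated Theil-Sen training

"12-fold cross-validation with 70/30 train/test splits" cannot be a
partition (twelve disjoint 30% test sets exceed the sample); it is
implemented as twelve independent quintile-stratified random splits.
Within each fold, train and test are disjoint and jointly cover the
cohort.

The per-fold estimator is Theil-Sen regression:

* one covariate: slope = median of all pairwise slopes, intercept =
  median(y − slope·x), enumerated exactly whenever the number of pairs
  allows (scipy's estimator with the joint-median intercept rule);
* several covariates: the classical estimator has no unique
  generalization; we use the spatial median (geometric median, Weiszfeld
  iteration with the Vardi-Zhang correction) of exact least-squares
  solutions on random subsets of p+1 observations — the same
  construction as scikit-learn's `TheilSenRegressor`, against which the
  implementation is cross-checked in the tests. All subsets are
  enumerated when there are at most `max_subsets` (default 10 000),
  otherwise that many are drawn, seeded. Subset systems are solved in
  standardized coordinates (the least-squares point is unchanged; raw
  anthropometric columns are too ill-conditioned to detect genuinely
  singular subsets, such as an all-one-sex draw) and back-transformed
  before the spatial median. The breakdown fraction shrinks with
  dimension, roughly 1 − 0.5^(1/(p+1)).

The final model takes, per coefficient **and for the intercept**, the
median of the twelve partial models (even count: mean of the 6th and 7th
order statistics). The aggregation is symmetric in fold order. A fold
whose fit fails aborts the run — with twelve folds, silently dropping
one would bias the median.

**Known behavior:** componentwise medians discard the correlation
between a fold's intercept error and its coefficient errors. With many
collinear selected variables at n ≈ 100 the partial models scatter along
error-compensating directions, and the aggregated model can carry a
systematic prediction offset of a few tenths of a kg even though each
partial model is nearly unbiased. This is a property of the published
aggregation rule, reproduced deliberately; the Bland-Altman stage exists
precisely to quantify it. Squared-correlation measures (r², out-of-fold
R²) are unaffected by such offsets.

The reported out-of-fold R² is the squared Pearson correlation of the
*final* model's predictions on each fold's held-out records, pooled.
Since the final model aggregates all folds, this is lightly optimistic,
but it is the quantity that pairs with the reported r of the final
equation. The partial models' own held-out predictions are kept in
`CVResult.fold_test_predictions` for fold-level diagnostics.

## Step 3 — agreement validation

Differences are oriented predicted − measured. Bland-Altman: bias =
mean difference, limits of agreement = bias ± 1.96·SD (sample SD, n−1),
bias CI = bias ± t₀.₉₇₅,ₙ₋₁·SD/√n, each limit's CI = limit ±
t₀.₉₇₅,ₙ₋₁·SD·√(3/n) (the classical approximation); the share of
differences strictly outside each limit is reported.

Deming regression of predicted on measured uses the closed-form
errors-in-variables slope with an assumed error-variance ratio
δ = var(error in y)/var(error in x), default 1 (orthogonal regression;
the original analysis does not state its ratio). As δ → ∞ the fit
converges to OLS of y on x (verified numerically in the tests).
Confidence intervals and the one-sample tests of slope = 1 and
intercept = 0 use leave-one-out jackknife standard errors with a t
reference on n − 2 degrees of freedom; "equivalence" requires both CIs
to cover their targets and both p-values to exceed 0.05.

R² is reported as the squared Pearson correlation between predicted and
measured (the convention that pairs with the reported r values); a
residual-sum-of-squares R² would differ whenever the predictions carry
an offset. The mean comparison applies Shapiro-Wilk (α = 0.05) to each
sample; if both pass, a two-sample Student's t-test, otherwise the
two-sided Mann-Whitney U. Negative FM predictions are never truncated —
truncation would silently bias every agreement statistic — but batch
scoring flags them, along with predicted %FM outside [5, 40], as
quality-control notes.

No multiplicity adjustment is applied across the three visit ages; they
are three separate analyses.

## Synthetic cohort generator

The generator emulates the study conditions so the pipeline can be
tested and benchmarked end to end:

* Per-visit covariate means and SDs equal the published descriptive
  table (weight, length, BMI, circumferences, skinfolds, gestational age
  39.00 (1.06) weeks, age in days); default sample sizes are the study's
  133/105/101.
* Covariates are drawn from a truncated multivariate normal. The study
  reports no covariance, so a block-exchangeable default is used: size
  measures (weight, length, circumferences) correlate 0.6 among
  themselves, skinfolds 0.5, size-skinfold pairs 0.3, gestational age
  0.3 with size and 0 with skinfolds — chosen once to mimic typical
  anthropometric collinearity so that selection is non-trivially
  challenged. Fully overridable. Truncation: mean ± 4 SD and positivity
  (negligible mass), gestational age to [37, 42] weeks (which shifts its
  realized mean up by ≈ 0.07 weeks — accepted, and accounted for in the
  tests). Rows violating bounds are rejected and redrawn.
* Weight and length are drawn; BMI is computed from them, never drawn,
  so the BMI identity holds exactly in every record. Sex is a balanced
  Bernoulli draw.
* Measured FM = true model (default: the visit's published equation)
  evaluated on the drawn covariates, plus N(0, σ) noise with σ solved
  from var(signal)/(var(signal) + σ²) = R²_target, the published
  per-visit R² (0.54/0.69/0.63) by default. var(signal) is estimated on
  a large draw with a fixed internal probe seed, so calibration is a
  deterministic constant of the configuration. FM is floored at 1% and
  capped at 99% of body weight.
* A 2% Bernoulli subset is rescaled to %FM uniform in [2, 5) so the
  exclusion filter always has work to do.

One master seed spawns per-stage child seeds in a fixed order
(generate, select, train, validate), so any stage can be re-run in
isolation; identical configuration and seed reproduce every artifact
byte for byte.

**What passing the synthetic benchmarks shows — and does not.** The
generator is Gaussian, linear, and homoscedastic by construction. Real
infant anthropometry has skewed skinfold distributions, measurement
error correlated between sites and observers, age-dependent variance,
and a reference method with its own error structure. The benchmarks
therefore establish that the *pipeline* is implemented correctly (it
recovers known truths at the study's n, noise, and collinearity), not
that the published equations are valid in any new population — that
requires validation against a reference method in that population.

## Benchmark problem sizes

The test suite exercises: noiseless coefficient recovery (exact to
≥ 6 decimals) through both OLS and the full Theil-Sen training stage;
median out-of-fold R² over 20 seeded study-size cohorts per visit,
required within ±0.08 of the calibration target; support recovery under
a strong sparse signal (3 true variables, n = 200, R² = 0.9) in at
least 16 of 20 full 1200-repetition selection runs; the univariate
Theil-Sen estimator against a brute-force all-pairs oracle on 100 random
fixtures (1e−6); closed-form degenerate cases of Bland-Altman and
Deming; and byte-identical artifacts across repeated pipeline runs. The
full suite runs in a few minutes on one CPU.

## Known limitations

* The multivariate Theil-Sen estimator is subset-based; at p ≳ 10 with
  n ≈ 100 its partial models are noisy, and the median-aggregated model
  can carry the prediction offset discussed above.
* The vote threshold (500/1200) has no error-control interpretation; it
  is the procedure's published constant.
* The per-fold penalty search returns grid minima; with very small
  subsamples the CV curve can be flat, making the selected penalty — and
  hence individual votes — sensitive to the draw. That variability is
  intentional: it is what the vote count aggregates over.
* Quintile stratification uses the measured outcome; the trained model
  therefore sees an outcome-balanced sample, not a simple random one.
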