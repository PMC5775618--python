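# Methods

## Distributions

BCCG and BCPE are implemented in the median-based parameterization used
throughout the growth-reference literature: `μ > 0` is the median, `σ > 0`
approximately the coefficient of variation, `ν` the Box-Cox skewness power,
and (BCPE only) `τ > 0` the kurtosis power of a power-exponential kernel.
The kernel is standardized to unit variance, `c² = 2^(−2/τ) Γ(1/τ)/Γ(3/τ)`,
so that `σ` keeps its CV interpretation for every `τ` and `τ = 2` collapses
to the standard normal kernel (BCPE ≡ BCCG, asserted to 1e−9 in tests).

Two numerical choices matter:

* **Truncation constant omitted.**  Formally the law is defined for
  `Y > 0`, which requires dividing by `Φ(1/(σ|ν|))`.  For the σ range of
  blood pressure (0.05–0.2) the neglected mass is below 1e−10, so the
  constant is dropped, as is standard.  Consequently pdf quadrature mass is
  1 within 1e−6 (tested) rather than exactly 1.
* **ν → 0 limit.**  `|ν| < 1e−6` switches to the exact log-normal branch;
  the Box-Cox branch uses `expm1`/`log1p` so the two agree at the switch
  point to machine precision.

Quantiles outside the Box-Cox domain (`1 + νσz ≤ 0`) raise a domain error
rather than silently truncating; with the σ values seen in practice this
needs α beyond roughly 1e−11.  Sampling is by quantile transform of
uniforms with the uniform clipped to [1e−9, 1−1e−9], which bounds draws at
about six kernel SDs and keeps the transform defined for all parameter
combinations.

## Fitting

Each distribution parameter has an additive predictor: log link for μ, σ,
τ, identity for ν (positivity by construction; the log link for μ is safe
because BP ≫ 0).  Smooth terms are cubic B-splines with 12 interior knots
at covariate quantiles and a second-order difference penalty, reparameterized
into an unpenalized linear column plus penalized deviation columns with
identity penalty, so penalty → ∞ shrinks a smooth to a straight line
(effective df 1).  The λ ↔ edf mapping uses the ridge trace formula on the
deviation columns' singular values, scaled by a scalar curvature weight
(1/σ̂² for μ under its log link); model df is the sum of unpenalized column
counts and the calibrated edf targets.

**Covariate scales.**  Age enters in years; height enters as log(height).
A linear log-height term is an allometric power law `μ ∝ height^b`, which
describes published pediatric BP medians closely; on the raw scale the
mild concavity of the height effect is real but too subtle for SBC to
justify a smooth at realistic n, leaving a systematic misfit.  Raw-scale
modelling remains available via `Control(log_height=False)`.

**Optimization** is cyclic: maximize the penalized log-likelihood over the
μ block (holding σ, ν, τ), then σ, ν, and for BCPE a bounded scalar search
on log τ; iterate until the objective changes by < 1e−6 (max 200 cycles).
Blocks are solved by L-BFGS with analytic score functions; any observation
with non-finite log density contributes a −1e10 barrier and is excluded
from the gradient, and hitting that barrier is flagged on the result.
Initialization: μ coefficients from a ridge regression of log y, σ from the
residual scale, ν = 1, τ = 2.  There is no randomness anywhere in the fit,
so refits are identical to the last bit.

**Selection.**  Smoothing strength per smooth term is chosen on the
effective-df grid {1, 2, 3, 5, 8} by SBC, one term at a time in formula
order (a coordinate search; the grid is small enough that a joint search
changes nothing in practice), warm-starting each fit.  Candidate model
specs (default: μ = smooth(age) + smooth(height); σ and ν each intercept
or linear in age; τ intercept-only) are compared by SBC with ties broken
toward fewer df, then candidate order.  The defaults mirror a survey
analysis that models age and height simultaneously and lets location,
scale and shape vary; they are fully configurable.

## Cohort pipeline

Exclusions run in a fixed order — age < 3, age ≥ 18 (completed years 3–17
analyzed), missing/outlying fields, IOTF overweight, IOTF obese — and each
record is counted under the first rule it violates, so the report always
conserves: consented = analysis + Σ exclusions.  "Outlying" is defined as
physiologically impossible (height outside 80–210 cm, weight 8–150 kg, SBP
40–250, DBP 20–150 mmHg), a declared default since surveys rarely publish
their operational rule.  IOTF classification interpolates the bundled
half-year cut-off table (Cole et al., 2000 convention: curves through adult
BMI 25/30 at age 18) linearly in age, with ≥ cut-off counting as the
heavier class.  The analysis BP is the mean of readings 2 and 3; reading 1
is summarized but never analyzed.  Baseline summaries use completed-years
age bands (3–6, 7–10, 11–13, 14–17), so age 6.9 belongs to 3–6.

## Synthetic cohorts

The generator emulates the survey structure the pipeline assumes:

* **Sex, age:** Bernoulli(0.49 boys); age continuous uniform on [2, 19) so
  both age exclusions are exercised.
* **Height:** sex-specific piecewise-linear mean curves through band-median
  heights (about 111/130/142/162 cm for boys at band midpoints, girls
  similar with an earlier plateau) with Gaussian SD around 8–10 cm,
  anchored at plausible ages 2 and 19 values.
* **BMI/weight:** a three-component mixture calibrated to IOTF prevalence —
  overweight (7.3%) uniform between the 25- and 30-cut-offs, obese (1.2%)
  just above the 30-cut-off, the rest log-normal around a normal-weight
  median curve clipped below the 25-cut-off.  Margins of ≥ 0.15 kg/m²
  around each cut-off keep the intended class stable under the 0.1-unit
  rounding of height and weight, so realized prevalence is binomially
  exact.  Weight is derived from BMI and height, making the BMI identity
  exact by construction.
* **Blood pressure:** each child's true SBP/DBP is drawn from the truth
  surfaces at (age, height); the three recorded readings add elevations
  δ1 = 2.2, δ2 = 1.0, δ3 = 0 mmHg plus i.i.d. Gaussian within-child noise
  (SD 3 mmHg, the same for all readings — the simplest model consistent
  with the declining reading means surveys report; within-child reading
  correlation is a declared assumption, not an inference).  The defaults
  put the mean(1st&2nd) − mean(2nd&3rd) gap at δ1/2 = 1.1 mmHg, mid-band
  for published surveys.  Readings are not rounded to integer mmHg, so
  that with the artifact layer off the analysis BP follows the true law
  exactly.
* **Missingness:** 0.63% of children get one randomly chosen field blanked.

**Truth surfaces** (`default_truth`) are smooth parametric fits to the
bundled published threshold table: log-median = cubic(age) + b·log(height)
per sex and measure (least-squares over the 75 printed P50 cells; residuals
≤ 0.73 mmHg, inside the table's integer rounding), σ linear in age through
the printed S column, ν constant at the value the BCCG row-consistency
relation recovers from the printed rows (≈0.27 for SBP, ≈1 for girls' DBP).
The boys' DBP surface is BCPE with τ = 1.5.  Its σ is calibrated to the
girls' DBP S column rather than the printed boys' column: the printed boys'
DBP S (≈0.04–0.07) is not variance-consistent with the printed P50→P90
spreads under any unit-variance Box-Cox law (the implied standardized P90
would need z ≈ 2.0, unreachable for any τ), whereas the observed age-band
SDs (≈8 mmHg) imply CV ≈ 0.12, matching the girls' column.

What the generator does **not** emulate: school-cluster sampling
correlation (the two-stage survey design), longitudinal growth, device
rounding, and any dependence between SBP and DBP beyond their shared
covariates.  Passing recovery tests therefore demonstrate correctness of
the estimation machinery under the stated data-generating process, not
robustness to design effects present in real surveys.

## Tables and validation

Height grids are per-sex, per-integer-age empirical percentiles of the
analysis (non-overweight) sample, linear interpolation of order statistics
("type 7"), rounded half-up to integer cm; cells with fewer than 20 records
are flagged.  Threshold tables evaluate the fitted models at exact integer
ages (mid-year evaluation available by option), round P50/P90/P95 half-up
to integer mmHg and print σ to 4 decimals.  Emission always runs structural
checks (pre-rounding P50 < P90 < P95, median-height monotonicity in age,
grid monotonicity) and records them beside the table.

For BCCG rows, (P50, S, P90) determine ν through
`P90 = P50·(1 + ν·S·z90)^(1/ν)` — the left side is strictly decreasing in
ν, so a bracketed root search on [−5, 5] finds the unique root — and hence
an implied P95.  Printed tables can thus be audited row by row; integer
rounding of the printed inputs bounds the achievable agreement at about
1 mmHg.  BCPE rows carry two shape unknowns and are skipped as
underdetermined.

## Validation experiments

`experiments.centile_recovery` simulates a survey (≈7000 analysis records
per sex), runs the full pipeline, and reports the maximum absolute error of
fitted P50/P90/P95 against the true centiles over integer ages 4–16 and the
per-age 10th–90th simulated height percentiles.  Two protocols exist: with
the reading-artifact layer off, the analysis BP follows the true law
exactly and the error isolates the estimator (maximum ≈ 0.3–1.9 mmHg across
seeds; the upper end occurs when SBC's choice between constant and
age-linear σ — a decision for which the deviance gain sits almost exactly
at the SBC penalty at this n — lands on the parsimonious side).  With the
artifacts on (survey conditions), the analysis BP is true BP + δ2/2 plus
noise, adding a systematic ≈ +0.5 mmHg at the median and ≈ +0.9 at P95
(the fitted σ absorbs the within-child noise variance), and the same
statistic ranges ≈ 1.3–1.7 mmHg.  Both numbers are reported by
`scripts/acceptance.py`.  `experiments.sbc_selection_rate` verifies that
SBC prefers a covariate-bearing location model essentially always when the
true median rises ≈ 20 mmHg across the age range (50 replicates, ≈ 2000
records each).

## Known limitations

* Effective df of smooth terms is a design-based calibration target, not
  the weighted trace of the converged fit; SBC therefore uses a slightly
  optimistic df for heavily weighted parameters.  With the small edf grid
  this changes selections only at decision boundaries.
* The cyclic optimizer has no second-order acceleration across blocks;
  convergence is linear but fast in practice (tens of cycles).
* Extrapolation beyond the training hull extends smooths linearly (flat in
  the deviation part) and is flagged, not refused.
* The row-consistency audit cannot check BCPE rows, and σ deconvolution of
  measurement noise is deliberately out of scope: tables describe observed
  analysis BP, as survey references do.
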