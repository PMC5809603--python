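# Methods

## The models

Crop yield responses to a single nutrient are modelled on small dose–response
tables: an ordered series of application rates X (kg/hm²) with the mean grain
yield Y (kg/hm²) observed at each rate.

**Quadratic polynomial model (QPFM).** The classical empirical curve

    Y = b0 + b1 X + b2 X²

assumes the marginal yield dY/dX = b1 + 2 b2 X declines *linearly* with rate
and that the response is symmetric about its maximum. Field data frequently
violate both assumptions, which shows up as "non-typical" fits — wrong
coefficient signs, or optima outside the tested range.

**Non-structural exponential model (NSFM).** Writing the soil's indigenous
nutrient supply as a fertilizer-equivalent amount s0 (kg/hm²), additive with
the applied rate, the marginal yield is modelled as an exponentially damped
version of the linear decline,

    dY/dX = A [1 − c (s0 + X)] e^(−cX),

whose antiderivative with zero integration constant (yield must vanish when
soil and fertilizer supply nothing) is

    Y = A (s0 + X) e^(−cX).

Parameters: A > 0 converts soil-equivalent nutrient into yield (kg/kg);
c > 0 (hm²/kg) sets the diminishing-returns decay; s0 is the soil supply
equivalent (kg/hm²; a negative estimate is possible on a poorly identified
fit and is flagged, not rejected). The curve has a single interior maximum
at X_max = 1/c − s0 and is asymmetric around it: yield loss from
over-fertilization is damped, matching the buffering observed with modern
fertilizer-tolerant varieties. Truncating e^(−cX) after its linear term maps
the model onto the quadratic with (b0, b1, b2) = (A s0, A(1 − c s0), −A c),
so the quadratic is the small-(cX) special case
(`taylor_qpfm_of_nsfm`).

## Estimation

The quadratic model is ordinary least squares on the regressors (1, X, X²),
solved by orthogonal decomposition.

The exponential model is nonlinear in (A, c, s0) but *separable*: for fixed
c, Y = (p + q X) e^(−cX) is linear in (p, q) = (A s0, A). `fit_nsfm`
therefore profiles the SSE over c (variable projection):

1. a dense log-spaced grid of c values, default 400 points on
   [1e-5, 5e-2] hm²/kg — covering the 1.9e-3..7.4e-3 range of field
   estimates with more than two decades of margin on either side; the grid
   is widened if needed so the quadratic-seeded value c0 = −b2/b1 is inside;
2. bounded scalar minimisation inside the bracketing grid cell
   (xatol = 1e-12).

This is deterministic, requires no starting values, and is global over the
searched interval; a profile minimum pinned at an interval end is flagged
(`c_at_bound`), and a fit with A ≤ 0 is rejected. The same engine fits the
marginal model via dY/dX = (u − v X) e^(−cX), u = A(1 − c s0), v = A c.

**Marginal series.** Between adjacent rates the marginal yield is the
difference quotient (Y[i+1] − Y[i])/(X[i+1] − X[i]), assigned to the
**upper** endpoint X[i+1]. The reference marginal analyses never state their
assignment convention, but only the upper endpoint reproduces their fitted
intercepts (a midpoint/lower assignment shifts the OLS intercept by
b·ΔX/2 / b·ΔX on an equally spaced design); this is asserted by test.

**Fit statistics.** For n points and p parameters: R² = 1 − SSE/SST,
S = sqrt(SSE/(n−p)), and F = (R²/(1−R²))·(n−p)/(p−1) on (p−1, n−p) degrees
of freedom, with significance from the F distribution's 0.05/0.01 upper
quantiles. This F definition is not stated in the reference tables but is
the unique one consistent with essentially every printed (F, R², n) triple
there (e.g. R² = 0.890, n = 7, p = 2 → F = 40.3 against a printed 40.28).

## Recommended rates

* Agronomic maximum: X_max = 1/c − s0 (exponential) or −b1/(2 b2)
  (quadratic). Negative values — fertile soils already past the optimum —
  are reported as-is with a `negative_rate` flag.
* Economic optimum: the rate where marginal yield equals the price ratio
  β = Px/Py (kg product per kg nutrient). For the exponential model
  X_eco = 1/(c + β/Y_eco) − s0 with Y_eco unknown a priori; it is resolved
  by fixed-point iteration from Y_max with tolerance 0.01 kg/hm² (far below
  agronomic relevance) and a 50-iteration cap — in practice 3–6 iterations
  suffice. At convergence the marginal yield equals β to first order in the
  tolerance; tests verify agreement with a dense grid search of
  Y(X) − βX to within the grid step. For the quadratic model the optimum is
  closed-form, (β − b1)/(2 b2), clipped to zero with a flag when negative.
* Typicality of a quadratic fit: b1 > 0, b2 < 0, the interior maximum
  within the tested rate range, and the recommended rates within the same
  range. The third condition's "range" is read as the span of tested
  *rates* (the fourth speaks of the design's scope, and the two conditions
  are conjoined anyway); yield-range and rate-range readings coincide on
  every bundled trial.

## Bundled reference data

Two trial sets ship as plain CSV:

* `rice_table1` — three 8-level trials (N, P2O5, K2O; Fujian, 2015–16) with
  replicate SDs;
* `wheat_table4` — nine historical winter-wheat trials (northern China,
  1980s) with 5–8 rates.

Alongside them, `published_fits()` exposes the reported per-trial
coefficients and statistics for 18 rice and 9 wheat trials, so comparisons
that only need coefficients (rate correlations, ratio summaries) run
without raw yields.

Three transcription decisions were needed to make the published coefficient
tables reproducible from the published raw data; in each case the stored
value is the one that round-trips, and the printed value is kept in trial
metadata:

* wheat trial W9's yield at 450 kg/hm² is stored as 1455 (printed 14550, a
  decimal slip amid yields of 480–2355; the reported intercept A·s0 ≈ 449
  confirms the correction);
* trials W5–W7's printed rates (0, 34, 68, 101, 135) are stored as the even
  design (0, 33.75, 67.5, 101.25, 135), and W8's (0, 38, 75, 113, 150, 188)
  as (0, 37.5, …, 187.5): with the rounded rates the published quadratic
  coefficients are off by up to 1.1%, with the even designs every
  coefficient reproduces to ≤ 0.23%;
* trials W4 (urea) and W9 (calcium superphosphate) are dosed in fertilizer
  *product* mass, but their published coefficients were fitted on
  nutrient-converted rates (46% N and 12% P2O5, the product grades).
  `to_nutrient_basis()` performs that conversion; fixtures keep the product
  rates as printed.

### Known inconsistencies in the reference tables

These are reported, not patched, because no uniquely determined correction
exists:

* **Rice trial R14's quadratic coefficients.** With the printed
  b1 = 8.1339, b2 = −0.043 its quadratic optimum (94.6 kg/hm²) sits far off
  the otherwise tight exponential-vs-quadratic diagonal (rate ratio 0.64
  against a 0.85–0.95 cluster). As a consequence the Pearson correlation of
  maximum rates over the 16 starred trials computes to 0.967 from the
  printed coefficients, against a reported 0.9868; dropping R14 gives
  0.989, and any b2 near −0.062 both restores the correlation to ≈0.99 and
  reproduces the reported K-group rate ratio of 89.0% (the printed
  coefficients give 84.4%). The package keeps the printed values and
  reports the computed correlation.
* **Wheat maximum-rate correlation.** From the printed wheat coefficients
  the correlation computes to 0.989 against a reported 0.979; no subset or
  unit convention examined recovers the reported value.
* **R18's quadratic F (15.5)** is consistent with its printed R² only under
  n = 5, contradicting the 4 rate levels recorded for that trial (n = 4
  implies F ≈ 7.6); it is excluded from the F-consistency sweep.
* **R7's exponential S (30.3)** does not satisfy S = sqrt(SSE/(n−p)) — the
  refit, which reproduces A, c, s0, F and R², gives 95.9.
* The exponential *marginal* fits' printed S values use denominator n−2
  (the linear model's p), not n−3; the package computes S with n−p and the
  tests check the published values under the n−2 convention.

## Synthetic trials

`simulate_trial` draws plot yields N(A(s0+X)e^(−cX), noise_sd²) at each
design rate with `n_reps` replicates and stores their mean and sample SD —
the same summary form as the bundled field trials. Defaults: noise_sd =
150 kg/hm² (mid-range of the 33–379 kg/hm² per-treatment SDs in the
three-replicate rice trials), n_reps = 3, 8-level designs. Noise is
homoscedastic Gaussian with no block, spatial or heteroscedastic structure,
so recovery experiments validate the estimator under the assumed model, not
robustness to field-layout effects. Seeding: each replicate trial uses
`SeedSequence([master_seed, replicate_index])`, making runs reproducible
and trivially parallelizable.

`recovery_experiment` repeats simulate-and-refit and reports bias and RMSE
for A, c, s0 and X_max. Tests use 40 replicates per condition — enough to
resolve the monotone effects asserted (RMSE shrinking with noise, denser
designs estimating X_max better) while keeping the suite fast.

## Numerical notes and limitations

* The profile SSE over c can be extremely flat when c·X_max is small (the
  quadratic limit); parameters then trade off along a ridge while fitted
  values barely move. The grid+refinement search still returns the profile
  minimum deterministically, but on such data (A, c, s0) should be read as
  a curve summary, not as separately well-identified quantities.
* Monotone-increasing trials fit without error; X_max then extrapolates
  beyond the tested range and is caught by the typicality/range checks
  downstream, not by the fitter.
* No standard errors or confidence intervals are produced for the
  exponential parameters; the recovery experiment is the intended tool for
  uncertainty assessment.
* Replicate-level plot data, weighted fits, and multi-nutrient (binary/
  tertiary) response surfaces are out of scope.
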