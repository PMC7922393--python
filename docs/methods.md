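# Methods

`heatqm` implements a two-part analysis: (1) quantile-mapping (QM) bias
correction of climate-model daily minimum temperature against station
observations, and (2) projection of temperature-attributable emergency-
department (ED) visits by combining the corrected future temperatures with
a quasi-Poisson exposure-response model, with Monte-Carlo uncertainty and
multi-model ensemble pooling. Because the real inputs (a regional-climate
downscaling ensemble and protected hospital records) are not shippable, a
first-class synthetic-data module generates series with the statistical
structure the methods assume; everything downstream is agnostic to the
source.

## Quantile mapping

Let `F_oh`, `F_mh`, `F_mp` be the CDFs of observed-historical, model-
historical and model-projected temperature. A transfer function `g` maps a
model value to a bias-corrected value; all methods except QDM fit `g` from
the historical pair and use the model's *historical* distribution to locate
a value's quantile level (the standard QM convention).

* **Normal mapping** — `g(x) = mu_o + (sigma_o/sigma_m)(x - mu_m)`, the
  closed form of `F_oh^{-1}(F_mh(x))` under Gaussian assumptions.
* **Empirical QM** — quantile tables of both series on a regular level grid
  `tau = 0, 0.01, ..., 1` (linear-interpolation order-statistic estimator;
  level 0/1 map to sample min/max); `g` interpolates linearly between table
  rows.
* **Robust QM** — the empirical quantile-quantile relation smoothed by
  local linear least squares: at each level, a line through the 10 nearest
  q-q pairs (by model-quantile value, ties to the lower level) predicts the
  corrected value; the table is averaged over 10 bootstrap replicates and
  then made non-decreasing by a running maximum. The bootstrap resamples
  the q-q *table rows*, not the raw days: resampling raw days re-estimates
  every quantile per replicate and leaves ~0.015 degC of mean noise in a
  12-year calibration, which would destroy the mean-closure property the
  method is supposed to have; row resampling keeps the bootstrap average
  centered on the full-sample mapping while still smoothing it.
* **Linear QM** — `g(x) = a + b x` with `(a, b)` by OLS of the observed on
  the model quantile function at full resolution (all paired order
  statistics; midpoint-level quantiles of the shorter series when lengths
  differ). Fitting through the complete order statistics puts the line
  through the sample means, so the corrected calibration series is mean-
  unbiased exactly; a coarse grid would leak endpoint noise into `a`, `b`.
* **QDM** — for each projection day with value `x`: its level
  `tau = F_mp(x)` is found in the *projection-period* distribution, and the
  output is `F_oh^{-1}(tau) + Delta` with `Delta = x - F_mh^{-1}(tau)`, so
  model-projected absolute changes in quantiles pass through the
  correction exactly (the delta identity holds by construction). QDM's
  default level grid is full-resolution (one level per order statistic),
  the convention of standard QDM implementations; an explicit grid can be
  passed to share levels with the table methods.

Fitting is season-stratified (DJF/MAM/JJA/SON by calendar month) by
default, which removes seasonality from the calibration; the corrected
target is reassembled in date order.

**Extrapolation.** Table methods use a constant-offset rule outside the
calibration range: the correction at the nearest table boundary is applied
unchanged, keeping behavior bounded on unprecedented future extremes.
Normal and linear methods extrapolate by their functional form. Missing
values are excluded from fitting and propagate through application.

**Fit statistics.** MBE = mean(obs − model), MAE, RMSE, and
NSD = sd(model)/sd(obs) (sample SDs, n−1), computed on aligned days and
optionally averaged across ensemble members. Ensemble spread is the
across-member SD of a within-member statistic — by default the warm-season
(May–September) period mean of daily values; a day-by-day cross-member SD
averaged over days is available as an alternative reading.

## Health model

Daily warm-season ED counts are modeled as

    log mu_t = alpha_0 + f(x_t) + h(t) + DOW + holiday [+ dew-point spline]

where `x_t` is the trailing 3-day moving average of daily minimum
temperature (computed on the full-year series *before* the May–September
restriction, so early-May exposures use late-April days), `f` is a natural
cubic spline with 3 df (knots at exposure terciles, boundary knots at the
data range), and `h(t)` is a natural cubic spline of time with interior
knots at the first day of each analyzed calendar month. Sensitivity
settings expose `f` with 2 or 4 df and `h` with 4/5/7 knots per warm season
(equally spaced within each season). The spline basis is the classical
restricted-cubic construction (cubic B-splines projected onto the
second-derivative-zero-at-boundary subspace) implemented in-package and
verified against an independent reference implementation; beyond the
boundary knots it continues linearly, which governs how the fitted curve
extrapolates to hotter future exposures (extrapolation fractions are
logged).

Estimation is quasi-Poisson: coefficients are the Poisson MLE (IRLS via a
standard GLM routine) and the covariance is the Poisson covariance scaled
by the Pearson chi-square dispersion — an exact algebraic identity that is
tested. The exposure-response is reported as
`theta(x) = f(x) - f(x0)` with pointwise delta-method variance from the
exposure-coefficient covariance block. The reference `x0` is the minimum
observed exposure when `theta` is strictly increasing on a 200-point grid
over the observed range; otherwise the grid argmin of risk (the usual
choice for U-shaped associations).

## Attributable numbers and projection

For historical day `t` with count `n_t`:
`AN_H(t) = n_t (1 - e^{-theta(x_t)})`. For projection day `t` with
bias-corrected exposure `xhat_t` (3-day moving average taken *after*
correction): `AN_P(t) = (n_t - AN_H(t)) (e^{theta(xhat_t)} - 1)`, where
`n_t - AN_H(t)` is the paired historical baseline. The two forms agree
identically when the same `theta` applies. Each projection day is paired
with the historical day of the same month/day (Feb 29 → Feb 28), cycling
the 12 historical years across the projection years; a month-mean baseline
is available as an alternative. Annual excess = mean over projection years
of the May–September sum of `AN_P`; decadal figures average the ten annual
sums.

**Uncertainty.** Exposure-spline coefficient vectors are drawn from a
multivariate Normal (point estimates, dispersion-scaled covariance; 5000
draws by default — the analysis scripts use 1000 at desk scale), and
`AN_H` and `AN_P` are recomputed jointly per draw. The same draws are
reused for every ensemble member so between-member differences reflect
exposure alone. Summaries are the median and the 2.5th/97.5th percentiles
(linear interpolation of order statistics). Two ensemble combinations:
*average* (across-member mean within each draw — ignores between-model
spread and gives the narrower interval) and *pooled* (concatenate all
members' draws — carries between-model spread into the interval).

## Synthetic data

* **Observations** — annual harmonic mean cycle
  `15 + 9 cos(2 pi (doy - 199)/365.25)` degC (winter minima ~6, summer
  minima ~24, a humid-subtropical profile) plus AR(1) residuals
  (phi = 0.7, innovation sd 2.5, stationary sd ~3.5), initialized from the
  stationary law. QM only assumes exchangeable seasonal distributions, so
  this minimal structure suffices.
* **Model members** — an independent realization of the same weather
  process, then `mean + additive_bias + scale_bias * (value - mean)`, an
  extra `tail_bias` above the member's own 0.9 hindcast quantile (the
  quantile-dependent bias QM exists to fix), and a linear warming trend
  (degC/decade) in the projection period. The study ensemble uses additive
  biases −3.4..+0.9 degC and scales 0.88..1.10, the magnitudes reported
  for real regional-climate minimum-temperature hindcasts, with a shared
  0.5 degC/decade trend.
* **ED counts** — negative-binomial (variance = dispersion × mean;
  dispersion 1.3, Poisson at 1) around a log-linear predictor with a known
  exposure-response (default: linear, 0.01 log-RR per degC), a seasonal
  harmonic (amplitude 0.05), day-of-week effects, and an explicit holiday
  date list. The baseline is calibrated so the expected warm-season mean
  is 2286 visits/day, the scale of a large metropolitan ED system. A
  helper solves the baseline exactly rather than tuning it.

What the generator does *not* emulate: spatial fields, humidity/dew-point
coupling, hospital-level reporting structure, outbreaks or reporting
artifacts, and any real climate dynamics. Passing tests therefore
demonstrate the estimators' internal correctness and calibration under the
assumed data-generating structure, not performance on real Atlanta data.

## Numerical choices

* Quantile estimator: linear interpolation of order statistics everywhere,
  so tables are reproducible.
* Robust QM tie-break: nearest neighbors by model-quantile distance with
  stable ordering toward the lower level; degenerate (zero-variance)
  neighborhoods fall back to the neighborhood mean.
* Seed handling: every generator and the bootstrap/Monte-Carlo steps take
  explicit integer seeds; the pipeline derives per-stage/per-member
  sub-seeds (< 2^31) from one global seed via a seed sequence, so adding a
  member never perturbs another member's stream.
* Degenerate inputs error early: zero model SD (normal mapping), constant
  quantiles (linear), degenerate projection distribution (QDM), zero
  observed variance (NSD), rank-deficient designs (with the offending
  columns reported), non-PSD coefficient covariance.
* Monte-Carlo draws are evaluated in blocks of 250 to bound memory on
  50-year projections.

## Problem sizes

The shipped study uses a 12-year calibration (4383 days), a 10-member
ensemble, 50 projection years summarized over the 2050s and 2090s, and
1000 Monte-Carlo draws in the analysis scripts; the parameter-recovery
check runs 50 generating seeds. These sizes give Monte-Carlo error well
below the effects being measured while keeping any single script in the
tens of seconds on one CPU.

## Known limitations

* The robust-QM bootstrap smooths over table rows; with very coarse grids
  (< ~20 levels) the neighborhood of 10 points spans most of the range and
  the method degenerates toward linear QM.
* The constant-offset extrapolation rule assumes the boundary correction
  persists beyond the calibration range; strong quantile-dependence of
  bias in unobserved tails is not correctable by construction.
* Exposure-response extrapolation beyond the observed range is linear (the
  natural-spline tails); projections dominated by out-of-range exposures
  inherit that assumption.
* Counts are modeled as a single aggregated city series; hospital-specific
  effects and dew-point confounding are available as covariate hooks but
  are off by default and unexplored.
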