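# Methods

`itscast` implements a two-stage interrupted time series (ITS) analysis for
daily count outcomes. Stage 1 trains and compares forecasters on pre-event
data only; stage 2 extrapolates the winning model through an event window to
obtain the counterfactual ("expected") trajectory and turns the gap between
observed and expected counts into an excess-event estimate with empirical
bootstrap intervals. This note records the models, the defaults, the
numerical choices, and what the synthetic studies do and do not demonstrate.

## Data model and timeline

The unit of analysis is a `DailyOutcomeSeries`: strictly consecutive
calendar days, a non-negative integer count per day, and real-valued
covariate columns (daily maximum/minimum temperature, dew point,
precipitation, and PM2.5 split into an event-related and a non-event-related
component). The timeline is split into a training segment, a held-out
testing segment, an optional buffer (days after testing but before the event
starts, excluded from all fitting and reported separately), and the
post-event reporting horizon. All windows are closed date intervals; an
event window can be given explicitly or detected as the first run of at
least `min_run` consecutive days on which a pollutant column strictly
exceeds a threshold (ties at the threshold do not count).

## Forecaster families

All three families share one estimator contract: `fit(y, X)` on the training
days, `predict(X)` over a horizon that immediately follows, real-valued
forecasts (floored at zero only in formatted reports, never inside residual
or bootstrap arithmetic).

**Seasonal ARIMA.** SARIMAX(p,d,q)(P,D,Q)[7] by maximum likelihood
(statsmodels), with weekly seasonal period 7 (the natural choice for daily
data) and yearly seasonality delegated to deterministic Fourier regressors
(order 3, period 365.25 d) rather than a 365-day seasonal polynomial.
Non-stationary or non-invertible fits raise a typed error that
hyperparameter search scores as an infinite validation loss. Bootstrap
refits are warm-started from the point fit's parameters with a reduced
iteration cap (30); near the optimum this changes estimates negligibly and
makes B refits affordable.

**NNAR ensemble.** A single-hidden-layer feed-forward autoregression:
inputs are lags 1..p of the outcome, seasonal lags 7, 14, ... up to P·7, and
optional feature columns; the hidden layer uses the logistic sigmoid, the
output is linear. `n_networks` members are trained (sklearn `MLPRegressor`,
L-BFGS, L2 penalty = the decay parameter) from initializations derived from
one seed via a `SeedSequence`, so fits are bit-reproducible. Inputs and
target are standardized before training and predictions de-standardized.
Forecasts are the ensemble mean and are produced recursively, feeding
predictions back as lagged inputs. A diverging member is re-initialized
once from a reserve seed before the fit fails.

**Hybrid (structural + boosted residuals).** The series is viewed as
Y_t = L_t + N_t. Stage 1 fits L by MAP: a piecewise-linear trend with 25
potential changepoints placed uniformly over the first `changepoint_range`
fraction of the training history (Laplace prior on slope changes, scale
`cp_prior` — an L1 penalty solved by FISTA with soft-thresholding, hence
deterministic), plus yearly and weekly Fourier seasonality under a Gaussian
prior of scale `seas_prior`, plus optional holiday indicators. Weekly
seasonality belongs in the structural stage for daily counts: leaving the
day-of-week cycle to the residual stage couples the excess estimate to the
day-of-week mix of the event window whenever the boosted stage is
regularized hard. The noise scale in the MAP objective is estimated once
from an unpenalized least-squares fit. Forecasts extrapolate the final
trend slope (no future changepoints). Stage 2 fits an XGBoost regressor to
the stage-1 residuals on the feature matrix (calendar signature, 0-7 day
lags of non-event PM2.5, same-day meteorology), with `mtry` interpreted as
candidate features per split and converted to a column-sampling fraction,
and early stopping monitored on the chronologically last 10% of the
training range. The final forecast is exactly stage 1 plus stage 2.

Features never leak: every feature at date t is a function of t and
covariate values at dates ≤ t, and the Fourier phase is anchored at the
first date of the full study series so train/test/horizon features are
phase-consistent.

## Tuning and model selection

Within each family, hyperparameters are tuned by expanding-window
cross-validation on the training segment only: a requested 2.9-year initial
window (resolved as round(2.9 × 365.25) = 1059 days; "12 months" as 365
days) followed by five sequential non-overlapping 12-month validation
windows, each later fold extending training by one validation length. When
the requested initial window plus the validation windows overshoots the
available span, the initial window shrinks so the last validation window
ends exactly at the training end (for a 2009-01-01..2016-11-07 span this
gives a 1043-day fold-1 window); an undershoot leaves a recorded unused
tail. Candidates come from a Latin-hypercube space-filling design over the
family's box (100/75/100 configurations by default; integers stratified;
the boosted-stage loss-reduction threshold sampled on the log scale), and
the winner minimizes mean validation RMSE with ties going to the earlier
candidate. The *family* is then chosen by RMSE on the held-out testing
segment (ties: higher R², then the fixed order ARIMA, NNAR, hybrid).
Metrics follow the standard definitions; MAPE and SMAPE are reported as
fractions, MAPE over non-zero observations only, and R² is the coefficient
of determination 1 − SSE/SST.

## Counterfactual and uncertainty

The selected configuration is refitted on the full pre-event span (training
+ testing + buffer) and predicts from the event start through the end of
the reporting period. Uncertainty comes from a moving block bootstrap
(MBB) on the in-sample residuals e_t = y_t − ŷ_t: the n−L+1 overlapping
length-L blocks are resampled (ceil(n/L) draws, concatenated, truncated to
n), added back to ŷ to form a pseudo-series (floored at 0, kept
real-valued; a documented switch rounds to integers), and the model is
refitted with frozen hyperparameters and asked to forecast the horizon. By
default each stored ensemble row also adds an MBB-resampled residual path
over the horizon, making the ensemble a bootstrap sample of *future
observations* under the no-event scenario rather than of the expected
trajectory alone. This is the package's deliberate design choice: the
excess estimand compares one realized observation with the counterfactual,
so an interval meant to cover the true event effect must absorb day-level
count noise; with the refit-only ensemble (`horizon_noise=False`) the
intervals describe only estimation uncertainty of the expected curve and
their excess transforms under-cover a known injected effect badly (~40-50%
instead of ~95% in the package's own calibration experiments). Empirical
intervals are percentile-based (2.5th/97.5th for 95%) with linear
interpolation between order statistics, hence bit-reproducible, and need
not be symmetric about the point forecast. A refit failure is retried once
with a fresh resample, then the row is dropped and counted.

The block length L defaults to 14 and can be selected by a stability scan:
for each candidate L (1..100) the residuals are block-resampled and the
width of the 95% interval of the resampled-series sum recorded; that width
is flat in L for independent residuals and grows with L until blocks cover
the correlation length. The selected L is the smallest whose width is
within 5% of the mean width of the next ten candidates (the mean makes the
rule robust to Monte-Carlo noise at the default 2000-resample scan); if no
candidate is stable the width-minimizing L is returned with a warning.

The excess report contains, per event day and in total: observed counts,
expected counts with the empirical interval, excess = observed − expected
with the interval flipped around the observed value, and the attributable
fraction excess/observed. Daily excess values sum exactly to the totals
row before any presentation rounding (counts to integers, percentages to
one decimal). Secondary windows (event start moved one day earlier, and
the week after the event) are available.

## Synthetic data generator

Real hospitalization records are restricted, so the generator emulates the
study's data shape with known ground truth: a log-linear mean with
intercept log 55 (≈55 daily events, the case-study scale), a slow trend
(2×10⁻⁵ per day on the log scale, ≈ +7.5% per decade), a weekday/weekend
cycle (Mon..Sun log effects +0.05 … −0.10, emulating the weekend dip in
unscheduled admissions), winter-peaking yearly seasonality (first- and
second-order Fourier amplitudes 0.15 and 0.03 on the cosine terms), weak
covariate effects applied to centered covariates (|γ·sd(x)| ≤ 0.1, so
forecasters face a realistic signal-to-noise ratio), and negative binomial
counts with size 50 (variance ≈ 2× the mean at this level; the Poisson
limit is available by setting the dispersion to None). Covariates are
seasonal sinusoids with AR(1) weather noise (tmin < tmax enforced daily),
zero-inflated winter-weighted precipitation, positive stationary non-event
PM2.5, and an event-related PM2.5 spike injected over the event window.
The injected event multiplies the mean by a rate ratio RR (default 1.15)
over a 12-day window in November of the final year, so the true total
excess Σ μ_t(RR−1) is known exactly.

Two ready-made scales exist: `small` (4 calendar years, 1461 days,
2015-2018, split 2017-11-07 / 2018-11-07 / event Nov 9-20 2018) and
`paper_like` (10 years, 2009-2018, with the case-study split dates). The
calibration experiments in the test suite use the small scale with 40
replicates, B = 100 bootstrap iterations and L = 14 — sizes chosen so the
whole suite stays desk-scale — and a deliberately stiff boosted stage
(learning rate 0.005, min node size 12, ≤60 trees) so that in-sample
residuals keep essentially the full noise variance; a flexible boosted
stage absorbs noise in-sample, shrinks the residual pool, and narrows the
bootstrap intervals below their nominal level. Under these conditions the
95% excess interval covers the true injected excess in ≈95% of replicates
and the mean estimate is within ~10% of truth; with RR = 1 the mean
estimated excess is statistically indistinguishable from zero.

What the generator does *not* emulate: reporting artifacts (holiday coding,
duplicate admissions), long-memory dependence or epidemic outbreaks in the
counts, measurement error in exposure, and spatial aggregation. Passing
calibration here shows the machinery is correct under the stated generating
model, not that any particular real-world analysis is unbiased.

## Numerical and degenerate-input choices

- Dates are calendar days; splits validate `train_end < test_end < event
  start` and reject out-of-range windows.
- The loader rejects duplicate dates (naming them), gaps (naming the gap),
  negative, non-integer or missing counts; it does not impute.
- FISTA runs to a 1e-10 max-coefficient shift or 2000 iterations; the
  Lipschitz constant comes from the exact largest eigenvalue of the
  penalized normal matrix.
- Metric computation requires n ≥ 2; an all-zero observation vector makes
  MAPE `None` rather than an error; R² of a zero-variance target is defined
  as 1 for a perfect fit and −inf otherwise.
- `empirical_ci` warns below B = 40 for a 95% interval. Ensemble rows must
  be finite; `level=1` returns min/max.
- Tuning treats any `ForecastFitError` as +inf; if every configuration of a
  family fails, the search raises rather than returning an arbitrary
  winner.

## Known limitations

- The structural stage is a MAP point estimate; stage-1 parameter
  uncertainty enters only through the bootstrap refits, not a posterior.
- ARIMA bootstrap refits use a capped warm-started optimizer; on pseudo-
  series far from the point fit the cap may stop slightly short of the
  optimum (the effect is well inside bootstrap noise in the calibration
  runs).
- In-sample residuals understate out-of-sample error for flexible
  configurations; the stability of the bootstrap intervals therefore
  depends on choosing configurations that do not overfit the training
  span. The tuning stage's expanding-window validation is the guard.
- Only the moving block bootstrap is implemented (no stationary or
  circular variants), and no model averaging across families.
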