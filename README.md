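# itscast

Two-stage interrupted time series (ITS) analysis for daily count outcomes:
estimate how many events (e.g. respiratory hospitalizations) an abrupt
exposure — a wildfire smoke episode, a policy change — caused, when no
control group exists.

**Stage 1** uses pre-event data only: three forecaster families are tuned by
expanding-window cross-validation and compared on a held-out testing
segment —

- seasonal **ARIMA** with weekly seasonal orders and yearly Fourier
  regressors: y_t = c + Σᵢ φᵢ y_{t−i} + Σⱼ θⱼ ε_{t−j} + ε_t;
- **NNAR**, an ensemble of single-hidden-layer feed-forward
  autoregressions y_t = α₀ + Σⱼ αⱼ g(β₀ⱼ + Σᵢ βᵢⱼ x_{t−i}) + ε_t with
  logistic g and forecasts averaged over many random initializations;
- a **hybrid** decomposition Y_t = L_t + N_t: a structural stage
  (piecewise-linear trend with L1-penalized changepoints + yearly and
  weekly Fourier seasonality) plus an XGBoost model of its residuals on
  calendar and covariate features.

**Stage 2** refits the winner on the full pre-event span and extrapolates
it through the event window as the counterfactual. Excess events are
observed − expected; uncertainty comes from a **moving block bootstrap**:
residual blocks of length L are resampled (preserving autocorrelation),
added back to the fitted values, the model is refitted on each
pseudo-series, and the 2.5th/97.5th percentiles of the resulting forecast
ensemble give 95% empirical confidence intervals (eCIs). The attributable
fraction is excess/observed.

## Worked example

Hospitalization records are typically restricted, so the package ships a
generator that emulates a county-level daily series (weekly + yearly
seasonality, slow trend, meteorology and PM2.5 covariates, overdispersed
counts) with a known injected event effect:

```python
import pandas as pd
from itscast import make_study_fixture, HybridForecaster
from itscast.pipeline import family_feature_builder, counterfactual_analysis

# 4 years of synthetic daily counts; a 12-day event (Nov 9-20, 2018)
# multiplies the expected count by RR = 1.15
series, split, truth = make_study_fixture("small", seed=1, rr=1.15)

model = HybridForecaster(n_trees_max=60, learning_rate=0.005,
                         min_n=12, depth=8, early_stop=10)
features = family_feature_builder("hybrid", series)
result = counterfactual_analysis(series, split, model, features,
                                 B=150, L=14, seed=1)
total = result.report.total
print(f"true excess      {truth.true_total_excess:.1f}")
print(f"estimated excess {total['excess']:.1f} "
      f"(95% eCI {total['excess_lo']:.1f} to {total['excess_hi']:.1f})")
print(f"attributable fraction {total['af_pct']:.1f}%")
```

Output:

```
true excess      109.8
estimated excess 141.3 (95% eCI 65.3 to 212.9)
attributable fraction 16.6%
```

i.e. observed counts exceed the counterfactual forecast by ~141 events
over the 12 event days, and the interval comfortably contains the true
injected excess of ~110. (Across 40 such replicates the interval
covers the truth ≈95% of the time; see `docs/methods.md`.)

A command-line pipeline wraps the same steps for CSV inputs:

```bash
itscast --config run.yaml simulate        # or point input_path at your CSV
itscast --config run.yaml tune            # space-filling search + expanding-window CV
itscast --config run.yaml evaluate        # per-family metrics, family selection
itscast --config run.yaml counterfactual  # excess report + bootstrap ensemble
```

The event window may be given as explicit dates or detected as the first
run of days on which a pollutant column exceeds a threshold (e.g. daily
mean PM2.5 > 35 µg/m³).

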