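"""Forecaster families: estimation sanity, recursion, reproducibility."""

import numpy as np
import pandas as pd
import pytest

from itscast import ArimaForecaster, ForecastFitError, HybridForecaster, NnarForecaster
from itscast.forecasters.structural import StructuralTrendSeasonal
from itscast.pipeline import family_feature_builder
from itscast.series import SplitSpec, split_series

from conftest import build_series


def _ar1_counts(phi, n, sigma, level, seed):
    rng = np.random.default_rng(seed)
    y = np.empty(n)
    y[0] = 0.0
    eps = rng.normal(0, sigma, n)
    for t in range(1, n):
        y[t] = phi * y[t - 1] + eps[t]
    return build_series(np.round(y + level).clip(0).astype(int))


class TestArima:
    def test_white_noise_has_near_zero_arma_coefficients(self):
        rng = np.random.default_rng(3)
        s = build_series(np.round(rng.normal(50, 5, 500)).clip(0).astype(int))
        est = ArimaForecaster(p=1, d=0, q=1, fourier_K=0).fit(s.y)
        params = dict(zip(est.result_.param_names, est.result_.params))
        assert abs(params["ar.L1"]) < 0.15
        assert abs(params["ma.L1"]) < 0.15

    def test_ar1_coefficient_recovery(self, ar1_series):
        est = ArimaForecaster(p=1, d=0, q=0, fourier_K=0).fit(ar1_series.y)
        params = dict(zip(est.result_.param_names, est.result_.params))
        assert 0.52 <= params["ar.L1"] <= 0.68

    def test_constant_series_with_differencing_forecasts_the_constant(self):
        s = build_series([25] * 120)
        est = ArimaForecaster(p=1, d=1, q=0, fourier_K=0).fit(s.y)
        horizon = pd.DataFrame(index=pd.date_range(s.end + pd.Timedelta(days=1),
                                                   periods=5))
        assert np.allclose(est.predict(horizon), 25.0, atol=1e-6)

    def test_forecast_follows_ar_recursion(self, ar1_series):
        """Multi-step forecasts equal the hand-rolled c + phi * previous recursion."""
        est = ArimaForecaster(p=1, d=0, q=0, fourier_K=0).fit(ar1_series.y)
        params = dict(zip(est.result_.param_names, est.result_.params))
        c, phi = params["intercept"], params["ar.L1"]
        horizon = pd.DataFrame(index=pd.date_range(
            ar1_series.end + pd.Timedelta(days=1), periods=4))
        got = est.predict(horizon)
        manual, prev = [], float(ar1_series.y.iloc[-1])
        for _ in range(4):
            prev = c + phi * prev
            manual.append(prev)
        np.testing.assert_allclose(got, manual, rtol=1e-8)

    def test_empty_horizon_gives_empty_forecast(self, ar1_series):
        est = ArimaForecaster(p=1, d=0, q=0, fourier_K=0).fit(ar1_series.y)
        assert est.predict(pd.DataFrame()).size == 0

    def test_too_short_training_raises_with_config(self):
        s = build_series([5] * 40)
        with pytest.raises(ForecastFitError) as ei:
            ArimaForecaster(p=3, d=0, q=3, P=3, Q=3).fit(s.y)
        assert ei.value.config["p"] == 3


class TestNnar:
    def test_zero_output_weights_predict_the_intercept(self, ar1_series):
        """With all hidden-to-output weights zero the network equation reduces
        to the output intercept alone."""
        est = NnarForecaster(p_lags=2, n_networks=2, hidden_units=4,
                             epochs=30, random_state=0)
        est.fit(ar1_series.slice(ar1_series.start, ar1_series.dates[199]).y)
        est.W2_ = np.zeros_like(est.W2_)
        est.b2_ = np.full_like(est.b2_, 1.25)
        horizon = pd.DataFrame(index=pd.date_range(
            ar1_series.dates[200], periods=3))
        destandardized = 1.25 * est.y_std_ + est.y_mean_
        np.testing.assert_allclose(est.predict(horizon), destandardized, rtol=1e-12)

    def test_sigmoid_activation_at_zero_input(self, ar1_series):
        """Zero input weights leave every hidden unit at g(0) = 0.5 exactly."""
        est = NnarForecaster(p_lags=1, n_networks=1, hidden_units=4,
                             epochs=30, random_state=0)
        est.fit(ar1_series.slice(ar1_series.start, ar1_series.dates[199]).y)
        est.W1_ = np.zeros_like(est.W1_)
        est.b1_ = np.zeros_like(est.b1_)
        est.W2_ = np.ones_like(est.W2_)
        est.b2_ = np.zeros_like(est.b2_)
        x = np.zeros((1, est.W1_.shape[1]))
        assert est._forward(x)[0] == pytest.approx(0.5 * 4, abs=1e-15)

    def test_one_step_rmse_close_to_true_model_on_linear_ar1(self):
        """On a linear AR(1) signal the ensemble's held-out one-step RMSE is
        within 15% of the known-true-model RMSE."""
        s = _ar1_counts(phi=0.7, n=2000, sigma=4.0, level=80, seed=11)
        cut = 1600
        train = s.slice(s.start, s.dates[cut - 1])
        est = NnarForecaster(p_lags=2, P_seasonal=1, hidden_units=8,
                             n_networks=10, decay=0.05, epochs=150,
                             random_state=1).fit(train.y)
        y = s.y.to_numpy(dtype=float)
        Xlag, rows = est._lag_matrix(y)
        tail = rows >= cut
        Xs = (Xlag[tail] - est.x_mean_) / est.x_std_
        preds = est._forward(Xs) * est.y_std_ + est.y_mean_
        obs = y[rows[tail]]
        mean_level = train.y.mean()
        oracle = mean_level + 0.7 * (y[rows[tail] - 1] - mean_level)
        rmse = np.sqrt(np.mean((obs - preds) ** 2))
        rmse_oracle = np.sqrt(np.mean((obs - oracle) ** 2))
        assert rmse <= 1.15 * rmse_oracle

    def test_recursive_two_step_equals_manual_chaining(self, ar1_series):
        train = ar1_series.slice(ar1_series.start, ar1_series.dates[299])
        est = NnarForecaster(p_lags=3, n_networks=3, hidden_units=6,
                             epochs=50, random_state=5).fit(train.y)
        horizon = pd.DataFrame(index=pd.date_range(
            train.end + pd.Timedelta(days=1), periods=2))
        got = est.predict(horizon)

        lags = est._lags
        hist = list(train.y.astype(float))
        manual = []
        for _ in range(2):
            row = np.array([hist[-j] for j in lags])
            rs = (row - est.x_mean_) / est.x_std_
            yhat = float(est._forward(rs[None, :])[0]) * est.y_std_ + est.y_mean_
            manual.append(yhat)
            hist.append(yhat)
        np.testing.assert_allclose(got, manual, rtol=1e-12)

    def test_seed_reproducibility_is_bit_exact(self, ar1_series):
        train = ar1_series.slice(ar1_series.start, ar1_series.dates[299])
        horizon = pd.DataFrame(index=pd.date_range(
            train.end + pd.Timedelta(days=1), periods=5))
        runs = []
        for _ in range(2):
            est = NnarForecaster(p_lags=2, n_networks=4, hidden_units=6,
                                 epochs=60, random_state=9).fit(train.y)
            runs.append(est.predict(horizon))
        np.testing.assert_array_equal(runs[0], runs[1])

    def test_ensemble_mean_varies_less_than_single_member(self, ar1_series):
        """Averaging property: across 10 seeds, the ensemble-mean prediction
        varies less than a single member's prediction."""
        train = ar1_series.slice(ar1_series.start, ar1_series.dates[399])
        y = train.y.to_numpy(dtype=float)
        ens_preds, member_preds = [], []
        for seed in range(10):
            est = NnarForecaster(p_lags=2, n_networks=6, hidden_units=6,
                                 epochs=60, random_state=seed).fit(train.y)
            Xlag, rows = est._lag_matrix(y)
            Xs = (Xlag[-50:] - est.x_mean_) / est.x_std_
            ens_preds.append(est._forward(Xs))
            member_preds.append(est._member_forward(Xs)[0])
        ens_var = np.var(np.array(ens_preds), axis=0).mean()
        member_var = np.var(np.array(member_preds), axis=0).mean()
        assert ens_var <= member_var


class TestHybrid:
    def test_structural_stage_recovers_pure_linear_trend(self):
        idx = pd.date_range("2015-01-01", periods=800)
        y = pd.Series(2.0 * np.arange(800.0), index=idx)
        st = StructuralTrendSeasonal(yearly_K=0, cp_prior=0.5).fit(y)
        recovered = st.predict(idx)
        mask = y > 100  # relative error on the interpolated ramp
        assert np.max(np.abs(recovered[mask] - y[mask]) / y[mask]) < 0.01

    def test_additivity_identity(self, small_study):
        """Final prediction equals stage-1 plus stage-2 everywhere, exactly."""
        series, spec, _ = small_study
        parts = split_series(series, spec)
        fb = family_feature_builder("hybrid", series)
        X_tr = fb.transform(parts.train.dates, series.covariates)
        X_te = fb.transform(parts.test.dates, series.covariates)
        est = HybridForecaster(n_trees_max=50).fit(parts.train.y, X_tr)
        total = est.predict(X_te)
        linear, nonlinear = est.predict_components(X_te)
        np.testing.assert_array_equal(total, linear + nonlinear)

    def test_zero_residuals_leave_boosted_stage_inert(self):
        """When the structural stage already fits perfectly the boosted stage
        predicts ~0 and the hybrid forecast equals the structural one."""
        idx = pd.date_range("2014-01-01", periods=900)
        t = np.arange(900.0)
        y = pd.Series(100.0 + 0.05 * t, index=idx)
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"x1": rng.normal(size=900), "x2": rng.normal(size=900)},
                         index=idx)
        est = HybridForecaster(yearly_K=0, cp_prior=0.5, n_trees_max=50,
                               early_stop=10).fit(y, X)
        linear, nonlinear = est.predict_components(
            X.iloc[:0].reindex(pd.date_range(idx[-1] + pd.Timedelta(days=1),
                                             periods=30)).fillna(0.0))
        assert np.max(np.abs(nonlinear)) < 0.5  # ~0 on a ~145 scale
        np.testing.assert_allclose(linear + nonlinear, linear, atol=0.5)

    def test_boosted_stage_captures_covariate_step(self):
        """Trend + yearly cycle + covariate step: the hybrid beats the
        structural stage alone out of sample."""
        rng = np.random.default_rng(8)
        n = 1200
        idx = pd.date_range("2013-01-01", periods=n)
        t = np.arange(float(n))
        x = rng.normal(size=n)
        signal = (60.0 + 0.01 * t + 8.0 * np.sin(2 * np.pi * t / 365.25)
                  + 10.0 * (x > 0.5) + rng.normal(0, 2.0, n))
        y = pd.Series(np.round(signal).clip(0), index=idx).astype(float)
        X = pd.DataFrame({"x_lag0": x}, index=idx)
        cut = 1000
        est = HybridForecaster(n_trees_max=200, random_state=0).fit(
            y.iloc[:cut], X.iloc[:cut])
        linear, nonlinear = est.predict_components(X.iloc[cut:])
        obs = y.iloc[cut:].to_numpy()
        rmse_hybrid = np.sqrt(np.mean((obs - (linear + nonlinear)) ** 2))
        rmse_stage1 = np.sqrt(np.mean((obs - linear) ** 2))
        assert rmse_hybrid < rmse_stage1

    def test_short_training_span_rejected(self):
        s = build_series([10] * 400)
        X = pd.DataFrame({"x": np.zeros(400)}, index=s.dates)
        with pytest.raises(ForecastFitError, match="2 years"):
            HybridForecaster().fit(s.y, X)

    def test_in_sample_rmse_finite_for_all_families(self, small_study):
        series, spec, _ = small_study
        parts = split_series(series, spec)
        for family, est in {
            "arima": ArimaForecaster(p=1, d=0, q=1),
            "nnar": NnarForecaster(n_networks=3, epochs=40, random_state=0),
            "hybrid": HybridForecaster(n_trees_max=50),
        }.items():
            fb = family_feature_builder(family, series)
            X = None if fb is None else fb.transform(parts.train.dates,
                                                     series.covariates)
            est.fit(parts.train.y, X)
            fv = est.fitted_values()
            obs = parts.train.y.loc[fv.index]
            rmse = np.sqrt(np.mean((obs - fv) ** 2))
            assert np.isfinite(rmse), family
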