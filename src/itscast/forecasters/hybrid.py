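"""Hybrid forecaster: structural decomposition + boosted residual model.

The hybrid view Y_t = L_t + N_t splits the series into a structural
component L (piecewise-linear trend + yearly and weekly Fourier seasonality
+ optional holidays, fitted by :class:`StructuralTrendSeasonal`) and a
nonlinear component N captured by a gradient-boosted tree ensemble fitted
to the stage-1 residuals e_t = Y_t - L_hat_t on the exogenous feature matrix
(calendar signature, covariate lags, ...).  The final forecast is exactly
Y_hat = L_hat + N_hat: an identity by construction, asserted by tests.

Because the hybrid predicts from dates and features alone (no feeding back
of its own forecasts), the multi-step forecast is a single batched call.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .base import BaseForecaster, ForecastFitError
from .structural import StructuralTrendSeasonal

__all__ = ["HybridForecaster"]


class HybridForecaster(BaseForecaster):
    """Two-stage trend-decomposition + boosted-residual forecaster.

    Stage-1 knobs (``changepoint_range``, ``cp_prior``, ``seas_prior``,
    ``yearly_K``, ``n_changepoints``) control the structural model; the rest
    configure the XGBoost residual stage.  ``mtry`` is the number of
    candidate features per split (converted internally to a column-sampling
    fraction); early stopping monitors the last ``valid_fraction`` of the
    training range, kept chronological to avoid leakage.
    """

    family = "hybrid"

    def __init__(
        self,
        changepoint_range: float = 0.8,
        cp_prior: float = 0.05,
        seas_prior: float = 1.0,
        yearly_K: int = 3,
        weekly_K: int = 3,
        n_changepoints: int = 25,
        holidays=None,
        mtry: int = 10,
        min_n: int = 2,
        depth: int = 8,
        learning_rate: float = 0.05,
        gamma: float = 0.0,
        early_stop: int = 20,
        n_trees_max: int = 300,
        valid_fraction: float = 0.1,
        random_state: int = 0,
    ):
        self.changepoint_range = changepoint_range
        self.cp_prior = cp_prior
        self.seas_prior = seas_prior
        self.yearly_K = yearly_K
        self.weekly_K = weekly_K
        self.n_changepoints = n_changepoints
        self.holidays = holidays
        self.mtry = mtry
        self.min_n = min_n
        self.depth = depth
        self.learning_rate = learning_rate
        self.gamma = gamma
        self.early_stop = early_stop
        self.n_trees_max = n_trees_max
        self.valid_fraction = valid_fraction
        self.random_state = random_state

    def _fit(self, y: pd.Series, X: Optional[pd.DataFrame]):
        from xgboost import XGBRegressor

        if len(y) < 2 * 365:
            raise ForecastFitError(
                "hybrid stage 1 needs >= 2 years of training days to identify "
                f"yearly seasonality; got {len(y)}",
                self.get_params(),
            )
        self.stage1_ = StructuralTrendSeasonal(
            changepoint_range=self.changepoint_range,
            cp_prior=self.cp_prior,
            seas_prior=self.seas_prior,
            yearly_K=self.yearly_K,
            weekly_K=self.weekly_K,
            n_changepoints=self.n_changepoints,
            holidays=self.holidays,
        ).fit(y)
        resid = y - self.stage1_.fitted_

        if X is None or not len(X.columns):
            raise ForecastFitError(
                "hybrid stage 2 needs a feature matrix", self.get_params()
            )
        Xv = X.to_numpy(dtype=float)
        n_valid = max(int(round(self.valid_fraction * len(y))), 1)
        if n_valid <= self.early_stop:
            raise ForecastFitError(
                f"early-stopping tail ({n_valid} days) shorter than "
                f"early_stop={self.early_stop} rounds",
                self.get_params(),
            )
        colsample = min(max(self.mtry / Xv.shape[1], 1.0 / Xv.shape[1]), 1.0)
        self.stage2_ = XGBRegressor(
            n_estimators=self.n_trees_max,
            max_depth=self.depth,
            min_child_weight=self.min_n,
            colsample_bynode=colsample,
            learning_rate=self.learning_rate,
            gamma=self.gamma,
            early_stopping_rounds=self.early_stop,
            objective="reg:squarederror",
            tree_method="hist",
            n_jobs=1,
            random_state=self.random_state,
        )
        r = resid.to_numpy(dtype=float)
        self.stage2_.fit(
            Xv[:-n_valid],
            r[:-n_valid],
            eval_set=[(Xv[-n_valid:], r[-n_valid:])],
            verbose=False,
        )
        self.fitted_values_ = pd.Series(
            self.stage1_.fitted_.to_numpy() + self.stage2_.predict(Xv),
            index=self.train_index_,
        )
        self.sigma2_ = float(np.mean((y - self.fitted_values_) ** 2))

    def predict_components(self, X: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """(structural, boosted-residual) forecast components for horizon X."""
        self._check_fitted()
        X = pd.DataFrame(X)[self.feature_names_in_]
        dates = pd.DatetimeIndex(X.index)
        linear = self.stage1_.predict(dates)
        nonlinear = self.stage2_.predict(X.to_numpy(dtype=float))
        return linear, np.asarray(nonlinear, dtype=float)

    def _predict(self, X: pd.DataFrame) -> np.ndarray:
        linear, nonlinear = self.predict_components(X)
        return linear + nonlinear
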