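"""Seasonal ARIMA with exogenous Fourier regressors.

The classical linear forecaster of the comparison: y_t is a linear function
of past observations, past forecast errors and a noise term, with a weekly
seasonal polynomial (period 7 for daily data) and yearly seasonality handed
to deterministic Fourier regressors rather than a 365-day seasonal
polynomial.  Estimation is maximum likelihood via statsmodels' state-space
SARIMAX.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from ..features import YEAR_DAYS, fourier_terms
from .base import BaseForecaster, ForecastFitError

__all__ = ["ArimaForecaster"]


class ArimaForecaster(BaseForecaster):
    """SARIMAX(p,d,q)(P,D,Q)[m] + yearly Fourier terms (+ optional exogenous X).

    Parameters mirror the usual Box-Jenkins orders; ``fourier_K`` sets the
    yearly Fourier order (0 disables).  A non-stationary or non-invertible
    maximum-likelihood fit raises :class:`ForecastFitError` carrying the
    configuration, which hyperparameter search treats as an infinite score.
    """

    family = "arima"

    def __init__(
        self,
        p: int = 1,
        d: int = 0,
        q: int = 1,
        P: int = 0,
        D: int = 0,
        Q: int = 0,
        seasonal_period: int = 7,
        fourier_K: int = 3,
    ):
        self.p = p
        self.d = d
        self.q = q
        self.P = P
        self.D = D
        self.Q = Q
        self.seasonal_period = seasonal_period
        self.fourier_K = fourier_K

    def _exog(self, dates: pd.DatetimeIndex, X: Optional[pd.DataFrame]) -> Optional[pd.DataFrame]:
        parts = []
        if self.fourier_K:
            parts.append(fourier_terms(dates, self.fourier_K, YEAR_DAYS, origin=self.origin_))
        if X is not None and len(X.columns):
            parts.append(X)
        if not parts:
            return None
        return pd.concat(parts, axis=1)

    def _fit(self, y: pd.Series, X: Optional[pd.DataFrame]):
        from statsmodels.tsa.statespace.sarimax import SARIMAX

        self.origin_ = self.train_index_[0]
        exog = self._exog(self.train_index_, X)
        n_par = self.p + self.q + self.P + self.Q + 2
        if len(y) <= 10 * n_par:
            raise ForecastFitError(
                f"training span {len(y)} too short for {n_par} ARMA parameters",
                self.get_params(),
            )
        try:
            model = SARIMAX(
                y.to_numpy(),
                exog=None if exog is None else exog.to_numpy(),
                order=(self.p, self.d, self.q),
                seasonal_order=(self.P, self.D, self.Q, self.seasonal_period),
                trend="c" if (self.d + self.D) == 0 else None,
                enforce_stationarity=True,
                enforce_invertibility=True,
            )
            # bootstrap refits start from the point fit's parameters (set
            # externally via warm_start_params); near the optimum a modest
            # iteration cap is enough and keeps B refits affordable
            start = getattr(self, "warm_start_params", None)
            maxiter = 200 if start is None else 30
            with np.errstate(all="ignore"):
                self.result_ = model.fit(disp=False, maxiter=maxiter, start_params=start)
        except (np.linalg.LinAlgError, ValueError) as exc:
            raise ForecastFitError(f"ARIMA fit failed: {exc}", self.get_params()) from exc
        if not np.isfinite(self.result_.params).all():
            raise ForecastFitError("ARIMA fit produced non-finite parameters", self.get_params())
        self.sigma2_ = float(self.result_.params[-1])
        fitted = self.result_.get_prediction().predicted_mean
        # the first max(d + D*m, 1) one-step predictions precede identifiable
        # state initialization under differencing; keep scored rows only
        skip = self.d + self.D * self.seasonal_period
        self.fitted_values_ = pd.Series(fitted, index=self.train_index_).iloc[skip:]

    def _predict(self, X: pd.DataFrame) -> np.ndarray:
        horizon = pd.DatetimeIndex(X.index)
        exog = self._exog(horizon, X if self.feature_names_in_ else None)
        fc = self.result_.get_forecast(
            steps=len(horizon), exog=None if exog is None else exog.to_numpy()
        )
        return np.asarray(fc.predicted_mean, dtype=float)
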