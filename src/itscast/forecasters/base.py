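"""Common fit/predict contract for the three forecaster families.

Forecasters are estimator classes in the scikit-learn idiom (``get_params``
/ ``set_params`` via :class:`~sklearn.base.BaseEstimator`, fitted attributes
with a trailing underscore, input validation on entry), but — being
forecasters — ``fit`` is y-first: ``fit(y, X)`` with ``y`` a daily-indexed
count series and ``X`` an aligned feature frame.  ``predict(X)`` takes the
feature rows of a horizon that immediately follows the training range and
returns real-valued (unrounded) forecasts; autoregressive families forecast
recursively, feeding their own predictions.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, clone

__all__ = ["BaseForecaster", "ForecastFitError", "clone"]


class ForecastFitError(RuntimeError):
    """A fit failed (non-convergence, non-invertible model, divergent loss).

    Carries the offending configuration so that tuning can score it as an
    infinite validation error instead of aborting the search.
    """

    def __init__(self, message: str, config: Optional[dict] = None):
        super().__init__(message)
        self.config = dict(config) if config else {}


class BaseForecaster(BaseEstimator):
    """Shared validation and bookkeeping for forecaster estimators."""

    family: str = "base"

    # -- hooks implemented by subclasses ------------------------------------
    def _fit(self, y: pd.Series, X: Optional[pd.DataFrame]):  # pragma: no cover
        raise NotImplementedError

    def _predict(self, X: pd.DataFrame) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    # -- public contract -----------------------------------------------------
    def fit(self, y, X: Optional[pd.DataFrame] = None):
        y = pd.Series(y, dtype=float) if not isinstance(y, pd.Series) else y.astype(float)
        idx = pd.DatetimeIndex(y.index)
        if len(idx) > 1:
            step = np.diff(idx.values).astype("timedelta64[D]").astype(int)
            if (step != 1).any():
                raise ValueError(f"{self.family}: training index is not consecutive days")
        if y.isna().any():
            raise ValueError(f"{self.family}: missing values in training outcome")
        if X is not None:
            X = pd.DataFrame(X)
            if not X.index.equals(idx):
                raise ValueError(f"{self.family}: feature rows not aligned to training dates")
        self.train_index_ = idx
        self.feature_names_in_ = list(X.columns) if X is not None else []
        self._fit(y, X)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Forecast one value per row of ``X`` (empty X -> empty forecast)."""
        self._check_fitted()
        X = pd.DataFrame(X)
        if len(X) == 0:
            return np.empty(0)
        if self.feature_names_in_:
            missing = [c for c in self.feature_names_in_ if c not in X.columns]
            if missing:
                raise ValueError(f"{self.family}: missing feature columns {missing}")
            X = X[self.feature_names_in_]
        idx = pd.DatetimeIndex(X.index)
        if idx[0] != self.train_index_[-1] + pd.Timedelta(days=1):
            raise ValueError(
                f"{self.family}: horizon must start the day after training "
                f"({(self.train_index_[-1] + pd.Timedelta(days=1)).date()}), got {idx[0].date()}"
            )
        return np.asarray(self._predict(X), dtype=float)

    def fitted_values(self) -> pd.Series:
        """In-sample (one-step-ahead where applicable) predictions on the
        training range, over the rows the model could score."""
        self._check_fitted()
        return self.fitted_values_

    def _check_fitted(self):
        if not hasattr(self, "train_index_"):
            raise RuntimeError(f"{self.family}: predict called before fit")
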