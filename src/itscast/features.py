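"""Deterministic model features: calendar signature, Fourier seasonality, lags.

Every feature value at date *t* is a function only of *t* and covariate
values at dates <= t, so feature construction can never leak information
from the forecast horizon into the fit.  The day index used for the Fourier
terms is anchored at a single *origin* date (by convention the first date of
the full study series, not of each segment) so that train, test and
post-event features stay phase-consistent.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "fourier_terms",
    "calendar_signature",
    "lagged",
    "FeatureBuilder",
]

YEAR_DAYS = 365.25


def _index(dates) -> pd.DatetimeIndex:
    return pd.DatetimeIndex(dates)


def fourier_terms(
    dates,
    K: int,
    period: float = YEAR_DAYS,
    origin=None,
) -> pd.DataFrame:
    """sin/cos pairs sin(2*pi*k*t/period), cos(2*pi*k*t/period) for k = 1..K.

    ``t`` is the 0-based day index measured from ``origin`` (default: the
    first date supplied).  Returns 2K columns named ``sin_k``/``cos_k``.
    """
    if K < 0:
        raise ValueError("K must be >= 0")
    if period <= 0:
        raise ValueError("period must be > 0")
    idx = _index(dates)
    origin = pd.Timestamp(origin) if origin is not None else idx[0]
    t = (idx - origin).days.to_numpy(dtype=float)
    cols = {}
    for k in range(1, K + 1):
        w = 2.0 * np.pi * k * t / period
        cols[f"sin_{k}"] = np.sin(w)
        cols[f"cos_{k}"] = np.cos(w)
    return pd.DataFrame(cols, index=idx)


def calendar_signature(dates, origin=None) -> pd.DataFrame:
    """Calendar feature set: linear index, day-of-week / month indicators,
    day-of-year, week-of-year.

    The linear index counts days from ``origin`` (default first date) so
    consecutive dates differ by exactly 1.
    """
    idx = _index(dates)
    origin = pd.Timestamp(origin) if origin is not None else idx[0]
    out = pd.DataFrame(index=idx)
    out["index_t"] = (idx - origin).days.to_numpy(dtype=float)
    dow = idx.dayofweek  # Monday=0
    for d in range(7):
        out[f"dow_{d}"] = (dow == d).astype(float)
    month = idx.month
    for m in range(1, 13):
        out[f"month_{m}"] = (month == m).astype(float)
    out["day_of_year"] = idx.dayofyear.astype(float)
    out["week_of_year"] = idx.isocalendar().week.to_numpy(dtype=float)
    return out


def lagged(column: pd.Series, lags: Sequence[int]) -> pd.DataFrame:
    """Lag columns: ``lag_j`` at date t holds the value at t-j.

    Rows whose lags precede the series origin hold NaN and are considered
    incomplete; model fitting drops (or natively handles) them.
    """
    if any(j < 0 for j in lags):
        raise ValueError("lags must be >= 0")
    name = column.name or "x"
    return pd.DataFrame(
        {f"{name}_lag{j}": column.shift(j) for j in lags}, index=column.index
    )


class FeatureBuilder:
    """Configurable, deterministic feature transformer for series segments.

    Records the study origin date at :meth:`fit` so that segment transforms
    share a single phase; :meth:`transform` may be called on any date range
    (train, test or forecast horizon) with the matching covariate rows.

    Parameters
    ----------
    fourier_K : Fourier order for yearly seasonality (0 disables).
    calendar : include the calendar signature group.
    covariate_lags : mapping covariate name -> iterable of lags; lag 0 means
        the contemporaneous value.
    holidays : optional explicit list of dates, emitted as a 0/1 indicator.
    """

    def __init__(
        self,
        fourier_K: int = 3,
        period: float = YEAR_DAYS,
        calendar: bool = True,
        covariate_lags: Optional[dict] = None,
        holidays: Optional[Iterable] = None,
    ):
        self.fourier_K = fourier_K
        self.period = period
        self.calendar = calendar
        self.covariate_lags = covariate_lags
        self.holidays = holidays

    def get_params(self, deep=True):
        return {
            "fourier_K": self.fourier_K,
            "period": self.period,
            "calendar": self.calendar,
            "covariate_lags": self.covariate_lags,
            "holidays": self.holidays,
        }

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, series) -> "FeatureBuilder":
        self.origin_ = series.start
        return self

    def transform(self, dates, covariates: Optional[pd.DataFrame] = None) -> pd.DataFrame:
        if not hasattr(self, "origin_"):
            raise RuntimeError("FeatureBuilder.transform called before fit")
        idx = _index(dates)
        parts = []
        if self.calendar:
            parts.append(calendar_signature(idx, origin=self.origin_))
        if self.fourier_K:
            parts.append(fourier_terms(idx, self.fourier_K, self.period, origin=self.origin_))
        if self.covariate_lags:
            if covariates is None:
                raise ValueError("covariate_lags configured but no covariates supplied")
            for name, lags in self.covariate_lags.items():
                if name not in covariates.columns:
                    raise KeyError(f"unknown covariate {name!r}")
                # lag over the full covariate history supplied, then subset,
                # so segment-initial rows stay complete when history exists
                parts.append(lagged(covariates[name], list(lags)).reindex(idx))
        if self.holidays is not None:
            hol = pd.DatetimeIndex(pd.to_datetime(list(self.holidays)))
            parts.append(pd.DataFrame({"holiday": idx.isin(hol).astype(float)}, index=idx))
        if not parts:
            return pd.DataFrame(index=idx)
        out = pd.concat(parts, axis=1)
        if out.columns.duplicated().any():
            raise ValueError("duplicate feature column names")
        return out

    def fit_transform(self, series, covariates=None):
        return self.fit(series).transform(series.dates, covariates)
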