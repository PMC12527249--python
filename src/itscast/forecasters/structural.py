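"""Structural additive stage: piecewise-linear trend + Fourier seasonality.

MAP estimation of

    y(t) = g(t) + s(t) + h(t) + eps_t

where g is a piecewise-linear trend whose slope changes at a fixed grid of
potential changepoints (Laplace prior on slope changes -> L1 penalty, scale
``cp_prior``), s is Fourier seasonality — yearly of order ``yearly_K`` plus
weekly (period 7) of order ``weekly_K``, both under a Gaussian prior ->
ridge penalty with scale ``seas_prior`` — and h is an optional 0/1 holiday
indicator effect.  The outcome is scaled to O(1) before fitting; the noise
scale entering the likelihood is estimated once from an unpenalized least
squares fit.  Optimization is a deterministic FISTA loop (proximal gradient
with soft-thresholding on the slope-change coefficients), so fits are
bit-reproducible.

Forecasts beyond the training range extrapolate the final trend slope (no
future changepoints) with the seasonal phase continued from the training
origin.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from ..features import YEAR_DAYS, fourier_terms

__all__ = ["StructuralTrendSeasonal"]


def _soft_threshold(v: np.ndarray, thr: np.ndarray) -> np.ndarray:
    return np.sign(v) * np.maximum(np.abs(v) - thr, 0.0)


class StructuralTrendSeasonal:
    """Deterministic MAP fit of the trend/seasonal/holiday decomposition.

    Parameters
    ----------
    changepoint_range : fraction of the training history over which the
        potential changepoints are placed uniformly.
    cp_prior : Laplace prior scale on slope changes; smaller = stiffer trend.
    seas_prior : Gaussian prior scale on Fourier coefficients; larger =
        more flexible seasonality.
    yearly_K : Fourier order of the yearly component.
    n_changepoints : size of the potential-changepoint grid.
    holidays : optional explicit holiday dates (0/1 indicator effect).
    """

    def __init__(
        self,
        changepoint_range: float = 0.8,
        cp_prior: float = 0.05,
        seas_prior: float = 1.0,
        yearly_K: int = 3,
        weekly_K: int = 3,
        n_changepoints: int = 25,
        holidays=None,
        max_iter: int = 2000,
        tol: float = 1e-10,
    ):
        self.changepoint_range = changepoint_range
        self.cp_prior = cp_prior
        self.seas_prior = seas_prior
        self.yearly_K = yearly_K
        self.weekly_K = weekly_K
        self.n_changepoints = n_changepoints
        self.holidays = holidays
        self.max_iter = max_iter
        self.tol = tol

    # -- design matrix -------------------------------------------------------
    def _design(self, dates: pd.DatetimeIndex) -> np.ndarray:
        t = (dates - self.origin_).days.to_numpy(dtype=float) / self.t_scale_
        cols = [np.ones_like(t), t]
        for s in self.changepoints_:
            cols.append(np.maximum(t - s, 0.0))
        F = fourier_terms(dates, self.yearly_K, YEAR_DAYS, origin=self.origin_)
        cols.extend(F[c].to_numpy() for c in F.columns)
        W = fourier_terms(dates, self.weekly_K, 7.0, origin=self.origin_)
        cols.extend(W[c].to_numpy() for c in W.columns)
        if self.holidays is not None:
            hol = pd.DatetimeIndex(pd.to_datetime(list(self.holidays)))
            cols.append(dates.isin(hol).astype(float))
        return np.column_stack(cols)

    def fit(self, y: pd.Series) -> "StructuralTrendSeasonal":
        dates = pd.DatetimeIndex(y.index)
        self.origin_ = dates[0]
        span = max((dates[-1] - dates[0]).days, 1)
        self.t_scale_ = float(span)
        ncp = int(self.n_changepoints)
        # uniform grid over the first changepoint_range fraction of history
        self.changepoints_ = (
            self.changepoint_range * np.arange(1, ncp + 1) / (ncp + 1.0)
        )
        yv = y.to_numpy(dtype=float)
        self.y_scale_ = float(max(np.abs(yv).max(), 1.0))
        ys = yv / self.y_scale_

        X = self._design(dates)
        n, p = X.shape
        ncols_trend = 2
        cp_slice = slice(ncols_trend, ncols_trend + ncp)
        n_seas = 2 * (self.yearly_K + self.weekly_K)
        seas_slice = slice(ncols_trend + ncp, ncols_trend + ncp + n_seas)

        # noise scale from an unpenalized ridge-stabilized solve
        beta0, *_ = np.linalg.lstsq(X + 0.0, ys, rcond=None)
        resid0 = ys - X @ beta0
        sigma2 = max(float(np.mean(resid0**2)), 1e-10)

        # penalties: Laplace prior on slope deltas, Gaussian on Fourier terms
        lam1 = np.zeros(p)
        lam1[cp_slice] = 1.0 / self.cp_prior
        lam2 = np.zeros(p)
        lam2[seas_slice] = 1.0 / (self.seas_prior**2)

        XtX = X.T @ X / sigma2
        Xty = X.T @ ys / sigma2
        L = float(np.linalg.eigvalsh(XtX + np.diag(lam2)).max())

        beta = beta0.copy()
        z = beta.copy()
        t_acc = 1.0
        for _ in range(self.max_iter):
            grad = XtX @ z - Xty + lam2 * z
            beta_new = _soft_threshold(z - grad / L, lam1 / L)
            t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_acc**2))
            z = beta_new + (t_acc - 1.0) / t_new * (beta_new - beta)
            shift = np.max(np.abs(beta_new - beta))
            beta, t_acc = beta_new, t_new
            if shift < self.tol:
                break
        self.coef_ = beta
        self.n_features_ = p
        self._cp_slice = cp_slice
        self._seas_slice = seas_slice
        self.fitted_ = pd.Series((X @ beta) * self.y_scale_, index=dates)
        return self

    def predict(self, dates) -> np.ndarray:
        dates = pd.DatetimeIndex(dates)
        X = self._design(dates)
        return (X @ self.coef_) * self.y_scale_

    @property
    def trend_slopes_(self) -> np.ndarray:
        """Per-segment slopes (scaled-t units): base slope plus cumulated deltas."""
        k = self.coef_[1]
        deltas = self.coef_[self._cp_slice]
        return k + np.concatenate([[0.0], np.cumsum(deltas)])
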