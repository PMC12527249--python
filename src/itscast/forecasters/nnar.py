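"""Neural-network autoregression (NNAR) ensemble.

A single-hidden-layer feed-forward network applied to lagged outcomes:

    y_t = a0 + sum_j a_j * g(b0j + sum_i b_ij x_{t-i}) + eps_t,
    g(x) = 1 / (1 + exp(-x))

with inputs y_{t-1..p}, seasonal lags y_{t-m..t-Pm} (m = 7 for daily data)
and optional exogenous feature columns.  ``n_networks`` members are trained
from different random initializations derived from one seed; forecasts are
the ensemble mean, produced recursively by feeding predictions back in as
lagged inputs.  Inputs and target are standardized before training and
predictions de-standardized, following the NNAR convention.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from sklearn.neural_network import MLPRegressor

from .base import BaseForecaster, ForecastFitError

__all__ = ["NnarForecaster"]


class NnarForecaster(BaseForecaster):
    """NNAR(p, P)[m] ensemble of logistic-sigmoid MLPs with linear output.

    Parameters
    ----------
    p_lags : number of consecutive lags 1..p of the outcome.
    P_seasonal : number of seasonal lag terms (lags m, 2m, ..., P*m).
    hidden_units : hidden-layer width s.
    n_networks : ensemble size; forecasts average over members.
    decay : L2 weight penalty per member.
    epochs : optimizer iteration cap per member.
    random_state : seed from which all member initializations derive.
    """

    family = "nnar"

    def __init__(
        self,
        p_lags: int = 1,
        P_seasonal: int = 1,
        hidden_units: int = 10,
        n_networks: int = 20,
        decay: float = 0.01,
        epochs: int = 100,
        seasonal_period: int = 7,
        random_state: int = 0,
    ):
        self.p_lags = p_lags
        self.P_seasonal = P_seasonal
        self.hidden_units = hidden_units
        self.n_networks = n_networks
        self.decay = decay
        self.epochs = epochs
        self.seasonal_period = seasonal_period
        self.random_state = random_state

    # -- lag bookkeeping -----------------------------------------------------
    @property
    def _lags(self) -> np.ndarray:
        m = self.seasonal_period
        lags = list(range(1, self.p_lags + 1))
        lags += [k * m for k in range(1, self.P_seasonal + 1) if k * m not in lags]
        return np.array(sorted(lags), dtype=int)

    def _lag_matrix(self, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lags = self._lags
        max_lag = int(lags.max())
        n = len(y)
        if n <= max_lag + 1:
            raise ForecastFitError(
                f"training span {n} too short for max lag {max_lag}", self.get_params()
            )
        rows = np.arange(max_lag, n)
        Xlag = np.column_stack([y[rows - j] for j in lags])
        return Xlag, rows

    def _fit(self, y: pd.Series, X: Optional[pd.DataFrame]):
        yv = y.to_numpy(dtype=float)
        if len(yv) <= int(self._lags.max()) + 30:
            raise ForecastFitError(
                f"training span {len(yv)} too short for NNAR({self.p_lags},{self.P_seasonal})",
                self.get_params(),
            )
        Xlag, rows = self._lag_matrix(yv)
        if X is not None and len(X.columns):
            Xfull = np.column_stack([Xlag, X.to_numpy(dtype=float)[rows]])
        else:
            Xfull = Xlag
        target = yv[rows]

        self.x_mean_ = Xfull.mean(axis=0)
        self.x_std_ = np.where(Xfull.std(axis=0) > 0, Xfull.std(axis=0), 1.0)
        self.y_mean_ = float(target.mean())
        self.y_std_ = float(target.std()) or 1.0
        Xs = (Xfull - self.x_mean_) / self.x_std_
        ts = (target - self.y_mean_) / self.y_std_

        ss = np.random.SeedSequence(self.random_state)
        member_seeds = ss.generate_state(2 * self.n_networks) % (2**31 - 1)
        W1, b1, W2, b2 = [], [], [], []
        for m in range(self.n_networks):
            net = self._train_member(Xs, ts, int(member_seeds[m]))
            if net is None:  # one retry from the reserve seed block
                net = self._train_member(Xs, ts, int(member_seeds[self.n_networks + m]))
            if net is None:
                raise ForecastFitError(
                    f"NNAR member {m} diverged twice", self.get_params()
                )
            W1.append(net.coefs_[0])
            b1.append(net.intercepts_[0])
            W2.append(net.coefs_[1][:, 0])
            b2.append(net.intercepts_[1][0])
        # stacked weights for a vectorized ensemble forward pass
        self.W1_ = np.stack(W1)   # (M, n_in, h)
        self.b1_ = np.stack(b1)   # (M, h)
        self.W2_ = np.stack(W2)   # (M, h)
        self.b2_ = np.array(b2)   # (M,)

        self.history_ = yv.copy()
        preds = self._forward(Xs)
        self.fitted_values_ = pd.Series(
            preds * self.y_std_ + self.y_mean_, index=self.train_index_[rows]
        )

    def _train_member(self, Xs, ts, seed) -> Optional[MLPRegressor]:
        net = MLPRegressor(
            hidden_layer_sizes=(self.hidden_units,),
            activation="logistic",
            solver="lbfgs",
            alpha=self.decay,
            max_iter=self.epochs,
            random_state=seed,
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                net.fit(Xs, ts)
            except (ValueError, np.linalg.LinAlgError):
                return None
        if not all(np.isfinite(c).all() for c in net.coefs_):
            return None
        return net

    def _forward(self, Xs: np.ndarray) -> np.ndarray:
        """Ensemble-mean prediction on standardized rows (vectorized)."""
        # (M, n, h) hidden activations
        z = np.einsum("nf,mfh->mnh", Xs, self.W1_) + self.b1_[:, None, :]
        g = 1.0 / (1.0 + np.exp(-z))
        out = np.einsum("mnh,mh->mn", g, self.W2_) + self.b2_[:, None]
        return out.mean(axis=0)

    def _member_forward(self, Xs: np.ndarray) -> np.ndarray:
        """Per-member predictions, shape (M, n); used by diagnostics/tests."""
        z = np.einsum("nf,mfh->mnh", Xs, self.W1_) + self.b1_[:, None, :]
        g = 1.0 / (1.0 + np.exp(-z))
        return np.einsum("mnh,mh->mn", g, self.W2_) + self.b2_[:, None]

    def _predict(self, X: pd.DataFrame) -> np.ndarray:
        lags = self._lags
        hist = list(self.history_)
        exog = X.to_numpy(dtype=float) if self.feature_names_in_ else None
        out = np.empty(len(X))
        for h in range(len(X)):
            row = np.array([hist[-j] for j in lags], dtype=float)
            if exog is not None:
                row = np.concatenate([row, exog[h]])
            rs = (row - self.x_mean_) / self.x_std_
            yhat = float(self._forward(rs[None, :])[0]) * self.y_std_ + self.y_mean_
            out[h] = yhat
            hist.append(yhat)
        return out
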