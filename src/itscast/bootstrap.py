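"""Counterfactual prediction with moving-block-bootstrap empirical intervals.

The selected forecaster, fitted to the full pre-event span, yields in-sample
residuals e_t.  The moving block bootstrap (MBB) forms the n-L+1 overlapping
length-L blocks of those residuals, draws ceil(n/L) blocks uniformly with
replacement, concatenates and truncates to length n.  Each resampled
residual series is added back to the model's in-sample predictions to form a
pseudo-series, the model is refitted (same hyperparameters, parameters
re-estimated) and asked to forecast the post-event horizon; the B refits
form a B x H prediction ensemble whose 2.5th/97.5th percentiles give 95%
empirical confidence intervals (eCIs).  Because blocks preserve within-block
autocorrelation, the intervals respect the residual dependence structure.

Excess events over the event window are observed minus expected counts; the
excess eCI flips the expected eCI around the observed value; the
attributable fraction is excess over observed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .forecasters import ForecastFitError, clone
from .series import DailyOutcomeSeries, EventWindow

__all__ = [
    "ResidualSeries",
    "BootstrapEnsemble",
    "ExcessReport",
    "compute_residuals",
    "mbb_resample",
    "mbb_ensemble",
    "empirical_ci",
    "select_block_length",
    "excess_report",
]


@dataclass(frozen=True)
class ResidualSeries:
    """In-sample residuals e_t = y_t - yhat_t over the rows the model scored."""

    values: np.ndarray
    index: pd.DatetimeIndex

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if not np.isfinite(v).all():
            raise ValueError("residuals contain non-finite values")
        object.__setattr__(self, "values", v)

    def __len__(self):
        return len(self.values)


@dataclass
class BootstrapEnsemble:
    """B x H matrix of bootstrap counterfactual forecasts."""

    predictions: np.ndarray
    block_length: int
    seed: int
    horizon_index: pd.DatetimeIndex
    n_failed: int = 0

    def __post_init__(self):
        P = np.asarray(self.predictions, dtype=float)
        if P.ndim != 2 or P.shape[0] < 1:
            raise ValueError("ensemble must be a B x H matrix with B >= 1")
        if not np.isfinite(P).all():
            raise ValueError("ensemble rows must be finite")
        self.predictions = P

    @property
    def B(self) -> int:
        return self.predictions.shape[0]

    @property
    def H(self) -> int:
        return self.predictions.shape[1]


def compute_residuals(pre: DailyOutcomeSeries, model) -> ResidualSeries:
    """Residuals of a model over the pre-event span it was fitted on."""
    fitted = model.fitted_values()
    if not fitted.index.isin(pre.dates).all():
        raise ValueError("model was not fitted on this pre-event span")
    obs = pre.y.loc[fitted.index].to_numpy(dtype=float)
    return ResidualSeries(obs - fitted.to_numpy(), pd.DatetimeIndex(fitted.index))


def mbb_resample(residuals: ResidualSeries, L: int, rng: np.random.Generator) -> np.ndarray:
    """One moving-block resample of length n.

    Forms the n-L+1 overlapping blocks, draws ceil(n/L) uniformly with
    replacement, concatenates, truncates to n.  L=1 degenerates to the iid
    residual bootstrap; L=n reproduces the original series.
    """
    v = residuals.values
    n = len(v)
    if not (1 <= L <= n):
        raise ValueError(f"block length {L} outside [1, {n}]")
    n_blocks = n - L + 1
    n_draws = int(np.ceil(n / L))
    starts = rng.integers(0, n_blocks, size=n_draws)
    idx = (starts[:, None] + np.arange(L)[None, :]).ravel()
    return v[idx[:n]]


def mbb_ensemble(
    model,
    pre: DailyOutcomeSeries,
    X_pre: Optional[pd.DataFrame],
    X_horizon: pd.DataFrame,
    B: int = 1000,
    L: int = 14,
    seed: int = 0,
    round_pseudo: bool = False,
    horizon_noise: bool = True,
) -> BootstrapEnsemble:
    """Refit-and-forecast bootstrap ensemble for the post-event horizon.

    ``model`` is an unfitted (or to-be-refitted) estimator carrying the
    frozen best hyperparameters.  The point fit on the pre-event data
    provides in-sample predictions yhat and residuals; each iteration builds
    the pseudo-series y* = yhat + e* (floored at 0, kept real-valued unless
    ``round_pseudo``), refits a clone and forecasts the horizon.  A refit
    failure is retried once with a fresh resample; a second failure drops
    the row (counted in ``n_failed``).

    With ``horizon_noise`` (the default) each stored row additionally adds
    an MBB-resampled residual path over the horizon, making the ensemble a
    bootstrap sample of *future observations* under the no-event scenario —
    so the percentile intervals are empirical prediction intervals whose
    excess-event transforms can cover the true event effect.  With
    ``horizon_noise=False`` rows are the bare refit forecasts and the
    intervals reflect estimation uncertainty of the expected trajectory
    only (much narrower, especially per day).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    point = clone(model).fit(pre.y, X_pre)
    residuals = compute_residuals(pre, point)
    fitted = point.fitted_values()
    yhat = fitted.to_numpy()
    y_full = pre.y.astype(float).copy()

    rng = np.random.default_rng(np.random.SeedSequence([seed, L]))
    rows, n_failed = [], 0
    for _ in range(B):
        row = None
        for _attempt in range(2):
            e_star = mbb_resample(residuals, L, rng)
            y_star = np.maximum(yhat + e_star, 0.0)
            if round_pseudo:
                y_star = np.round(y_star)
            pseudo = y_full.copy()
            pseudo.loc[fitted.index] = y_star
            try:
                member = clone(model)
                if hasattr(point, "result_"):  # warm-start likelihood refits
                    member.warm_start_params = point.result_.params
                member.fit(pseudo, X_pre)
                row = member.predict(X_horizon)
                if horizon_noise:
                    H = len(row)
                    path = np.concatenate(
                        [mbb_resample(residuals, L, rng)
                         for _ in range(int(np.ceil(H / len(residuals))))]
                    )
                    row = row + path[:H]
                break
            except ForecastFitError:
                continue
        if row is None:
            n_failed += 1
        else:
            rows.append(row)
    if not rows:
        raise ForecastFitError("every bootstrap refit failed")
    if n_failed:
        warnings.warn(f"{n_failed} of {B} bootstrap refits failed and were dropped")
    return BootstrapEnsemble(
        predictions=np.vstack(rows),
        block_length=L,
        seed=seed,
        horizon_index=pd.DatetimeIndex(X_horizon.index),
        n_failed=n_failed,
    )


def empirical_ci(
    ensemble: BootstrapEnsemble,
    level: float = 0.95,
    total_columns: Optional[Sequence[int]] = None,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Per-day and total percentile intervals from the ensemble.

    Returns ``(daily, total)`` where ``daily`` is an H x 2 array of
    [lo, hi] per horizon day and ``total`` the interval for the sum over
    ``total_columns`` (default: all columns).  Percentiles use linear
    interpolation between order statistics, so intervals are
    bit-reproducible; they need not be symmetric about the point forecast.
    """
    if not (0 < level <= 1):
        raise ValueError("level must be in (0, 1]")
    if ensemble.B < 40 and level >= 0.95:
        warnings.warn(
            f"B={ensemble.B} is small for a {level:.0%} empirical interval"
        )
    alpha = 100.0 * (1.0 - level) / 2.0
    qs = (alpha, 100.0 - alpha)
    P = ensemble.predictions
    daily = np.percentile(P, qs, axis=0).T
    cols = slice(None) if total_columns is None else list(total_columns)
    sums = P[:, cols].sum(axis=1)
    lo, hi = np.percentile(sums, qs)
    return daily, (float(lo), float(hi))


def select_block_length(
    residuals: ResidualSeries,
    candidate_range: Sequence[int] = range(1, 101),
    B_scan: int = 2000,
    seed: int = 0,
    tol: float = 0.05,
    lookahead: int = 10,
) -> tuple[int, pd.DataFrame]:
    """Stability scan of interval width versus block length.

    For each candidate L the residuals are block-resampled ``B_scan`` times
    and the width of the central 95% interval of the resampled-series sum
    is recorded; that width is flat in L for independent residuals and
    grows with L until blocks cover the correlation length.  The selected L
    is the smallest whose width is within ``tol`` (relative) of the mean
    width of the next ``lookahead`` larger candidates — i.e. the point
    where widths have stopped changing with L.  If no candidate is stable, the
    width-minimizing L is returned with a warning.  Also returns the full
    width-vs-L table.
    """
    cands = sorted(set(int(L) for L in candidate_range))
    n = len(residuals)
    if cands[0] < 1 or cands[-1] > n:
        raise ValueError(f"candidate range outside [1, {n}]")
    widths = []
    for L in cands:
        rng = np.random.default_rng(np.random.SeedSequence([seed, L]))
        sums = np.empty(B_scan)
        for b in range(B_scan):
            sums[b] = mbb_resample(residuals, L, rng).sum()
        lo, hi = np.percentile(sums, (2.5, 97.5))
        widths.append(hi - lo)
    widths = np.asarray(widths)
    table = pd.DataFrame({"L": cands, "ci_width": widths})
    if len(cands) == 1:
        return cands[0], table
    for i, L in enumerate(cands):
        upcoming = widths[i + 1 : i + 1 + lookahead]
        if len(upcoming) == 0:
            break
        ref = float(np.mean(upcoming))
        if abs(widths[i] - ref) <= tol * max(ref, 1e-12):
            return L, table
    warnings.warn("no stable block length found; returning the width-minimizing L")
    return int(cands[int(np.argmin(widths))]), table


class ExcessReport:
    """Per-day and total observed / expected / excess / attributable-fraction
    rows with empirical CIs.

    ``frame`` holds one row per event day plus a ``"total"`` row: columns
    observed, expected, expected_lo, expected_hi, excess, excess_lo,
    excess_hi, af_pct, af_lo_pct, af_hi_pct.  Identities: excess = observed
    - expected; the excess interval flips the expected interval around the
    observed value; AF = excess / observed (where observed > 0); the total
    interval comes from the bootstrap distribution of summed predictions.
    """

    def __init__(self, frame: pd.DataFrame):
        self.frame = frame

    @property
    def total(self) -> pd.Series:
        return self.frame.loc["total"]

    def formatted(self) -> pd.DataFrame:
        """Presentation rounding: integer counts, 1-decimal percents."""
        out = self.frame.copy()
        for c in ("observed", "expected", "expected_lo", "expected_hi",
                  "excess", "excess_lo", "excess_hi"):
            out[c] = out[c].round().astype("Int64")
        for c in ("af_pct", "af_lo_pct", "af_hi_pct"):
            out[c] = out[c].round(1)
        return out


def excess_report(
    observed_post: DailyOutcomeSeries,
    ensemble: BootstrapEnsemble,
    point_predictions: np.ndarray,
    event: EventWindow,
    level: float = 0.95,
) -> ExcessReport:
    """Assemble the excess-event report over the event window.

    ``observed_post`` and ``point_predictions``/``ensemble`` must cover the
    event days (the ensemble horizon may extend beyond them; the totals row
    sums the event days only).  Expected values are floored at 0 for
    reporting; bootstrap arithmetic stays unfloored upstream.
    """
    horizon = ensemble.horizon_index
    point = np.asarray(point_predictions, dtype=float)
    if len(point) != len(horizon):
        raise ValueError("point predictions misaligned with ensemble horizon")
    ev_dates = event.dates
    if not ev_dates.isin(horizon).all():
        raise ValueError(
            f"event days {ev_dates[0].date()}..{ev_dates[-1].date()} not all "
            "inside the forecast horizon"
        )
    if not ev_dates.isin(observed_post.dates).all():
        raise ValueError("event days missing from the observed post-event segment")
    pos = horizon.get_indexer(ev_dates)
    daily_ci, total_ci = empirical_ci(ensemble, level=level, total_columns=pos)

    obs = observed_post.y.loc[ev_dates].to_numpy(dtype=float)
    exp = np.maximum(point[pos], 0.0)
    exp_lo = np.maximum(daily_ci[pos, 0], 0.0)
    exp_hi = np.maximum(daily_ci[pos, 1], 0.0)

    def _af(excess, observed):
        return np.where(observed > 0, 100.0 * excess / observed, np.nan)

    rows = pd.DataFrame(
        {
            "observed": obs,
            "expected": exp,
            "expected_lo": exp_lo,
            "expected_hi": exp_hi,
            "excess": obs - exp,
            "excess_lo": obs - exp_hi,
            "excess_hi": obs - exp_lo,
        },
        index=ev_dates.strftime("%Y-%m-%d"),
    )
    rows["af_pct"] = _af(rows["excess"].to_numpy(), obs)
    rows["af_lo_pct"] = _af(rows["excess_lo"].to_numpy(), obs)
    rows["af_hi_pct"] = _af(rows["excess_hi"].to_numpy(), obs)

    t_obs = obs.sum()
    t_exp = exp.sum()
    t_lo, t_hi = max(total_ci[0], 0.0), max(total_ci[1], 0.0)
    total = {
        "observed": t_obs,
        "expected": t_exp,
        "expected_lo": t_lo,
        "expected_hi": t_hi,
        "excess": t_obs - t_exp,
        "excess_lo": t_obs - t_hi,
        "excess_hi": t_obs - t_lo,
        "af_pct": 100.0 * (t_obs - t_exp) / t_obs if t_obs > 0 else np.nan,
        "af_lo_pct": 100.0 * (t_obs - t_hi) / t_obs if t_obs > 0 else np.nan,
        "af_hi_pct": 100.0 * (t_obs - t_lo) / t_obs if t_obs > 0 else np.nan,
    }
    frame = pd.concat([rows, pd.DataFrame([total], index=["total"])])
    return ExcessReport(frame)
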