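"""Expanding-window cross-validation, space-filling search, metrics, selection.

Hyperparameters are tuned inside each forecaster family by expanding-window
cross-validation on the training segment only: fold 1 trains on an initial
window and validates on the following 12 months; each later fold extends the
training window by one validation length and validates on the next,
non-overlapping, 12 months.  Candidate configurations come from a
Latin-hypercube space-filling design over the family's search box, and the
winner minimizes mean validation RMSE across folds.  The *family* itself is
then chosen on the held-out test segment by RMSE.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .forecasters import ForecastFitError
from .forecasters.configs import SEARCH_SPACES, config_class

__all__ = [
    "CVPlan",
    "MetricReport",
    "make_expanding_cv",
    "sample_configs",
    "compute_metrics",
    "tune",
    "select_best_model",
    "FAMILY_ORDER",
]

FAMILY_ORDER = ("arima", "nnar", "hybrid")
DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class CVPlan:
    """Ordered expanding-window folds of (train_range, validation_range),
    each range a closed (start, end) date pair."""

    folds: tuple
    unused_tail_days: int = 0

    def __iter__(self):
        return iter(self.folds)

    def __len__(self):
        return len(self.folds)


def make_expanding_cv(
    train_start,
    train_end,
    initial_years: float = 2.9,
    validation_months: int = 12,
    n_folds: int = 5,
) -> CVPlan:
    """Build the expanding-window plan over [train_start, train_end].

    ``initial_years`` resolves to round(years * 365.25) days and
    ``validation_months`` to round(months * 365 / 12) days, avoiding
    month-length ambiguity.  Fold 1 is anchored at ``train_start``.  When the
    requested initial window plus the validation windows overshoots the
    available span, the initial window shrinks to fit (so the last validation
    window ends exactly at ``train_end``); when it undershoots, the unused
    tail is recorded on the plan.
    """
    start, end = pd.Timestamp(train_start), pd.Timestamp(train_end)
    available = (end - start).days + 1
    initial = int(round(initial_years * DAYS_PER_YEAR))
    valid = int(round(validation_months * 365.0 / 12.0))
    needed = initial + n_folds * valid
    if needed > available:
        initial = available - n_folds * valid
        if initial < valid:
            raise ValueError(
                f"insufficient training span: need >= {(n_folds + 1) * valid} days "
                f"({n_folds} folds x {valid}-day validation + an initial window of "
                f"at least {valid} days), have {available}"
            )
    folds = []
    day = pd.Timedelta(days=1)
    for k in range(n_folds):
        tr_end = start + pd.Timedelta(days=initial + k * valid - 1)
        va_start = tr_end + day
        va_end = va_start + pd.Timedelta(days=valid - 1)
        folds.append(((start, tr_end), (va_start, va_end)))
    unused = (end - folds[-1][1][1]).days
    return CVPlan(folds=tuple(folds), unused_tail_days=max(unused, 0))


def sample_configs(family: str, n: int, seed: int) -> list:
    """Latin-hypercube sample of ``n`` configurations from the family's box.

    Integer parameters are stratified over their value set; ``gamma`` (the
    boosted stage's loss-reduction threshold) is sampled on the log scale.
    Deterministic for a given seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    space = SEARCH_SPACES[family]
    names = list(space)
    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    u = sampler.random(n)
    cls = config_class(family)
    configs = []
    for row in u:
        kwargs = {}
        for j, name in enumerate(names):
            lo, hi, kind = space[name]
            if kind == "int":
                val = int(min(math.floor(lo + row[j] * (hi - lo + 1)), hi))
            elif kind == "logfloat":
                val = float(np.exp(np.log(lo) + row[j] * (np.log(hi) - np.log(lo))))
            else:
                val = float(lo + row[j] * (hi - lo))
            kwargs[name] = val
        configs.append(cls(**kwargs))
    return configs


@dataclass(frozen=True)
class MetricReport:
    """Goodness-of-fit summary: R^2 (coefficient of determination), MAE,
    RMSE, MAPE and SMAPE (both on the fraction scale)."""

    r2: float
    mae: float
    rmse: float
    mape: Optional[float]
    smape: float
    n: int


def compute_metrics(observed, predicted) -> MetricReport:
    """Metric suite over an (observed, predicted) pair of equal length >= 2.

    MAPE averages |e|/|y| over the days with y != 0 and is reported missing
    (None) when every observation is zero; SMAPE uses 2|e|/(|y|+|yhat|).
    """
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1 or len(y) < 2:
        raise ValueError("observed and predicted must be equal-length vectors (n >= 2)")
    e = y - yhat
    mae = float(np.mean(np.abs(e)))
    rmse = float(np.sqrt(np.mean(e**2)))
    nz = y != 0
    mape = float(np.mean(np.abs(e[nz]) / np.abs(y[nz]))) if nz.any() else None
    denom = np.abs(y) + np.abs(yhat)
    ratio = np.where(denom > 0, 2.0 * np.abs(e) / np.where(denom > 0, denom, 1.0), 0.0)
    smape = float(np.mean(ratio))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(e**2)) / sst if sst > 0 else (1.0 if rmse == 0 else -np.inf)
    return MetricReport(r2=r2, mae=mae, rmse=rmse, mape=mape, smape=smape, n=len(y))


def _fit_and_score(estimator, series, feature_builder, tr_range, va_range) -> float:
    tr = series.slice(*tr_range)
    va = series.slice(*va_range)
    X_tr = X_va = None
    if feature_builder is not None:
        X_tr = feature_builder.transform(tr.dates, series.covariates)
        X_va = feature_builder.transform(va.dates, series.covariates)
    estimator.fit(tr.y, X_tr)
    pred = estimator.predict(X_va if X_va is not None else pd.DataFrame(index=va.dates))
    return compute_metrics(va.y.to_numpy(), pred).rmse


def tune(
    family: str,
    train,
    cv: CVPlan,
    configs: Sequence,
    feature_builder=None,
    random_state: int = 0,
):
    """Score each configuration across the CV folds; return the winner.

    Returns ``(best_config, table)`` where ``table`` is a tidy DataFrame
    (family, config_id, fold, rmse) plus per-config mean rows (fold = -1).
    A failed fit scores as +inf for that fold; ties in mean RMSE go to the
    earlier configuration in the sampled list.
    """
    if not configs:
        raise ValueError("configs must be non-empty")
    records = []
    means = np.empty(len(configs))
    for ci, cfg in enumerate(configs):
        fold_scores = []
        for fi, (tr_range, va_range) in enumerate(cv):
            est = cfg.to_estimator(random_state=random_state)
            try:
                score = _fit_and_score(est, train, feature_builder, tr_range, va_range)
            except ForecastFitError:
                score = np.inf
            fold_scores.append(score)
            records.append(
                {"family": family, "config_id": ci, "fold": fi, "rmse": score}
            )
        means[ci] = np.mean(fold_scores)
        records.append(
            {"family": family, "config_id": ci, "fold": -1, "rmse": means[ci]}
        )
    if not np.isfinite(means).any():
        raise ForecastFitError(f"every {family} configuration failed to fit")
    best = int(np.argmin(means))  # argmin takes the first minimum: documented tie-break
    return configs[best], pd.DataFrame.from_records(records)


def select_best_model(test_reports: Mapping[str, MetricReport]) -> str:
    """Family with the lowest test RMSE; ties broken by higher R^2, then by
    the fixed order arima, nnar, hybrid."""
    if not test_reports:
        raise ValueError("need at least one family report")
    order = {f: i for i, f in enumerate(FAMILY_ORDER)}
    return min(
        test_reports,
        key=lambda f: (
            test_reports[f].rmse,
            -test_reports[f].r2,
            order.get(f, len(order)),
        ),
    )
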