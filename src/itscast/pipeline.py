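"""End-to-end study orchestration.

Stage 1: tune each forecaster family by expanding-window CV on the training
segment, evaluate the tuned families on the held-out test segment, and
select the family with the lowest test RMSE.  Stage 2: refit the selected
configuration on the full pre-event span, forecast the post-event horizon
as the counterfactual, and wrap it in moving-block-bootstrap empirical
intervals and an excess-event report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .bootstrap import (
    BootstrapEnsemble,
    ExcessReport,
    compute_residuals,
    excess_report,
    mbb_ensemble,
    select_block_length,
)
from .features import FeatureBuilder
from .series import DailyOutcomeSeries, EventWindow, SplitSpec, split_series
from .tuning import MetricReport, compute_metrics, select_best_model

__all__ = [
    "family_feature_builder",
    "evaluate_families",
    "counterfactual_analysis",
    "StudyResult",
]


def family_feature_builder(
    family: str,
    series: DailyOutcomeSeries,
    nonsmoke_col: str = "nonsmoke_pm25",
    meteorology: tuple = ("tmax", "tmin", "dewpoint", "precip"),
    holidays=None,
) -> Optional[FeatureBuilder]:
    """Default exogenous feature policy per family.

    ARIMA uses its internal yearly Fourier regressors only; NNAR adds the
    calendar signature; the hybrid's boosted stage additionally sees 0-7 day
    lags of nonsmoke PM2.5 and same-day meteorology.
    """
    if family == "arima":
        return None
    if family == "nnar":
        return FeatureBuilder(fourier_K=0, calendar=True, holidays=holidays).fit(series)
    if family == "hybrid":
        lags = {}
        if nonsmoke_col in series.covariates.columns:
            lags[nonsmoke_col] = range(0, 8)
        for m in meteorology:
            if m in series.covariates.columns:
                lags[m] = (0,)
        return FeatureBuilder(
            fourier_K=3, calendar=True, covariate_lags=lags or None, holidays=holidays
        ).fit(series)
    raise ValueError(f"unknown family {family!r}")


def evaluate_families(
    series: DailyOutcomeSeries,
    spec: SplitSpec,
    estimators: Mapping[str, object],
    builders: Optional[Mapping[str, Optional[FeatureBuilder]]] = None,
) -> tuple[dict, dict, str]:
    """Fit each family's estimator on the training segment, score train and
    test segments, and pick the best family by test RMSE.

    Returns ``(reports, fitted, selected)`` with ``reports[family] =
    {"train": MetricReport, "test": MetricReport}``.
    """
    parts = split_series(series, spec)
    reports, fitted = {}, {}
    for family, est in estimators.items():
        builder = (
            builders[family]
            if builders is not None
            else family_feature_builder(family, series)
        )
        X_tr = X_te = None
        if builder is not None:
            X_tr = builder.transform(parts.train.dates, series.covariates)
            X_te = builder.transform(parts.test.dates, series.covariates)
        est.fit(parts.train.y, X_tr)
        fv = est.fitted_values()
        train_rep = compute_metrics(
            parts.train.y.loc[fv.index].to_numpy(), fv.to_numpy()
        )
        pred = est.predict(
            X_te if X_te is not None else pd.DataFrame(index=parts.test.dates)
        )
        test_rep = compute_metrics(parts.test.y.to_numpy(), pred)
        reports[family] = {"train": train_rep, "test": test_rep}
        fitted[family] = est
    selected = select_best_model({f: r["test"] for f, r in reports.items()})
    return reports, fitted, selected


@dataclass
class StudyResult:
    """Counterfactual stage output: the excess report for the main event
    window plus optional secondary / post-event-week reports, the bootstrap
    ensemble, the block-length scan, and the point forecast."""

    report: ExcessReport
    ensemble: BootstrapEnsemble
    point_predictions: np.ndarray
    horizon_index: pd.DatetimeIndex
    block_length: int
    lscan: Optional[pd.DataFrame] = None
    secondary_report: Optional[ExcessReport] = None
    postweek_report: Optional[ExcessReport] = None


def counterfactual_analysis(
    series: DailyOutcomeSeries,
    spec: SplitSpec,
    estimator,
    builder: Optional[FeatureBuilder] = None,
    B: int = 1000,
    L="auto",
    seed: int = 0,
    level: float = 0.95,
    scan_B: int = 2000,
    include_secondary: bool = False,
    include_postweek: bool = False,
) -> StudyResult:
    """Stage-2 analysis with the frozen, selected configuration.

    The estimator is refitted on the *full pre-event span* (training +
    testing + any buffer days up to the day before the event) and predicts
    from the event start through ``spec.post_extra_end``.  ``L`` may be an
    integer block length or ``"auto"`` for the stability-scan selector.
    When ``include_secondary`` is set, a report for the event window starting
    one day earlier is added (requires that day inside the horizon, so the
    pre-event fit then ends two days before the event).
    """
    event = spec.event
    horizon_start = event.start - pd.Timedelta(days=1) if include_secondary else event.start
    pre = series.slice(series.start, horizon_start - pd.Timedelta(days=1))
    horizon = pd.date_range(horizon_start, spec.post_extra_end, freq="D")
    post = series.slice(horizon_start, spec.post_extra_end)

    X_pre = X_h = None
    if builder is not None:
        X_pre = builder.transform(pre.dates, series.covariates)
        X_h = builder.transform(horizon, series.covariates)
    else:
        X_h = pd.DataFrame(index=horizon)

    from .forecasters import clone

    point_model = clone(estimator).fit(pre.y, X_pre)
    point = point_model.predict(X_h)

    lscan = None
    if L == "auto":
        residuals = compute_residuals(pre, point_model)
        L, lscan = select_block_length(residuals, B_scan=scan_B, seed=seed + 1)
    L = int(L)

    ensemble = mbb_ensemble(
        estimator, pre, X_pre, X_h, B=B, L=L, seed=seed + 2
    )
    report = excess_report(post, ensemble, point, event, level=level)

    secondary = postweek = None
    if include_secondary:
        secondary = excess_report(
            post,
            ensemble,
            point,
            EventWindow(event.start - pd.Timedelta(days=1), event.end),
            level=level,
        )
    if include_postweek:
        week = EventWindow(
            event.end + pd.Timedelta(days=1), event.end + pd.Timedelta(days=7)
        )
        if week.end <= spec.post_extra_end:
            postweek = excess_report(post, ensemble, point, week, level=level)
    return StudyResult(
        report=report,
        ensemble=ensemble,
        point_predictions=np.asarray(point),
        horizon_index=horizon,
        block_length=L,
        lscan=lscan,
        secondary_report=secondary,
        postweek_report=postweek,
    )
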