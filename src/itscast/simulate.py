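"""Synthetic daily count series with known ground truth.

Emulates a ~decade-long county-level daily series of the kind the pipeline
analyzes: overdispersed hospitalization-like counts with weekly and yearly
seasonality, a slow multiplicative trend, weak meteorological covariate
effects, and an injected multi-day event that multiplies the expected count
by a known rate ratio RR — so every pipeline stage can be scored against
truth without restricted data.

The generating model is log-linear:

    log mu_t = intercept + slope * t + weekly[dow(t)]
               + sum_k (a_k sin(2 pi k t / 365.25) + b_k cos(2 pi k t / 365.25))
               + sum_j gamma_j (x_jt - mean(x_j))
    mu_t <- mu_t * RR          inside the event window
    y_t ~ NegBin(mean mu_t, size `dispersion`)     (Poisson in the limit)

Covariate effects apply to centered covariates so the intercept keeps its
interpretation as the log baseline mean.  True total excess is
sum_event mu_base_t * (RR - 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .series import DailyOutcomeSeries, EventWindow, SplitSpec

__all__ = [
    "SimulationTruth",
    "generate_covariates",
    "generate_series",
    "make_study_fixture",
]

YEAR_DAYS = 365.25

#: weekend dip in unscheduled admissions: Mon..Sun multiplicative log effects
DEFAULT_WEEKLY = (0.05, 0.03, 0.02, 0.01, 0.00, -0.08, -0.10)
#: yearly Fourier amplitudes (sin_k, cos_k); cos_1 > 0 peaks on Jan 1 (winter)
DEFAULT_YEARLY = ((0.03, 0.15), (0.01, 0.03))
#: weak covariate effects on the log scale (per unit of the centered covariate)
DEFAULT_GAMMA = {
    "tmax": -0.004,
    "dewpoint": 0.002,
    "precip": 0.002,
    "nonsmoke_pm25": 0.006,
}


@dataclass
class SimulationTruth:
    """Generating coefficients and, after generation, the realized means."""

    intercept: float = float(np.log(55.0))
    slope: float = 2e-5  # per day, log scale (~7.5% per decade)
    weekly: tuple = DEFAULT_WEEKLY
    yearly: tuple = DEFAULT_YEARLY
    gamma: dict = field(default_factory=lambda: dict(DEFAULT_GAMMA))
    dispersion: Optional[float] = 50.0  # NegBin size; None = Poisson limit
    event: Optional[EventWindow] = None
    rr: float = 1.0
    mu: Optional[pd.Series] = None          # event-inclusive means, set by generate_series
    mu_base: Optional[pd.Series] = None     # no-event means
    true_total_excess: Optional[float] = None

    def __post_init__(self):
        if self.rr <= 0:
            raise ValueError("rate ratio must be > 0")


def _yearly_cycle(t: np.ndarray, amp_sin: float, amp_cos: float, k: int = 1) -> np.ndarray:
    w = 2.0 * np.pi * k * t / YEAR_DAYS
    return amp_sin * np.sin(w) + amp_cos * np.cos(w)


def generate_covariates(
    n_days: int,
    seed: int,
    start="2009-01-01",
    smoke_event: Optional[EventWindow] = None,
    smoke_level: float = 75.0,
) -> pd.DataFrame:
    """Coastal-county-like daily covariates.

    tmax/tmin/dewpoint: yearly sinusoids plus AR(1) weather noise with
    tmin < tmax enforced daily; precip: zero-inflated positive draws,
    likelier in winter; nonsmoke PM2.5: positive stationary noise around a
    seasonal mean; smoke PM2.5: zero except during an optional injected
    spike window.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    idx = pd.date_range(start, periods=n_days, freq="D")
    t = np.arange(n_days, dtype=float)

    def ar1(sigma, rho=0.7):
        e = rng.normal(0.0, sigma, n_days)
        out = np.empty(n_days)
        out[0] = e[0] / np.sqrt(1 - rho**2)
        for i in range(1, n_days):
            out[i] = rho * out[i - 1] + e[i]
        return out

    # summer peak: -cos peaks mid-year
    season = -np.cos(2.0 * np.pi * t / YEAR_DAYS)
    tmax = 18.0 + 5.0 * season + ar1(1.2)
    spread = np.maximum(6.0 + rng.normal(0.0, 1.0, n_days), 1.0)
    tmin = tmax - spread
    dewpoint = tmin - 1.5 + rng.normal(0.0, 1.0, n_days)

    winter = 0.5 * (1.0 + np.cos(2.0 * np.pi * t / YEAR_DAYS))  # 1 on Jan 1
    wet = rng.random(n_days) < (0.05 + 0.30 * winter)
    precip = np.where(wet, rng.exponential(4.0, n_days), 0.0)

    pm_season = 8.0 + 2.0 * np.cos(2.0 * np.pi * t / YEAR_DAYS)
    nonsmoke = np.maximum(pm_season + ar1(1.5, rho=0.5), 0.5)

    smoke = np.zeros(n_days)
    cov = pd.DataFrame(
        {
            "tmax": tmax,
            "tmin": tmin,
            "dewpoint": dewpoint,
            "precip": precip,
            "nonsmoke_pm25": nonsmoke,
            "smoke_pm25": smoke,
        },
        index=idx,
    )
    if smoke_event is not None:
        ramp = rng.uniform(0.9, 1.3, smoke_event.n_days)
        cov.loc[smoke_event.start : smoke_event.end, "smoke_pm25"] = smoke_level * ramp
    return cov


def generate_series(
    truth: SimulationTruth, covariates: pd.DataFrame, seed: int
) -> DailyOutcomeSeries:
    """Draw the outcome series implied by ``truth`` over the covariate dates.

    Side effect: fills ``truth.mu``, ``truth.mu_base`` and
    ``truth.true_total_excess``.
    """
    idx = pd.DatetimeIndex(covariates.index)
    t = np.arange(len(idx), dtype=float)
    log_mu = truth.intercept + truth.slope * t
    log_mu += np.asarray(truth.weekly, dtype=float)[idx.dayofweek]
    for k, (a, b) in enumerate(truth.yearly, start=1):
        log_mu += _yearly_cycle(t, a, b, k)
    for name, g in truth.gamma.items():
        if name in covariates.columns:
            x = covariates[name].to_numpy(dtype=float)
            log_mu += g * (x - x.mean())
    if np.max(log_mu) > 30:
        raise OverflowError("generated mean overflows; check coefficients")
    mu_base = np.exp(log_mu)
    mu = mu_base.copy()
    if truth.event is not None and truth.rr != 1.0:
        in_event = idx.isin(truth.event.dates)
        mu[in_event] *= truth.rr

    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    if truth.dispersion is None or not np.isfinite(truth.dispersion):
        y = rng.poisson(mu)
    else:
        k = float(truth.dispersion)
        y = rng.negative_binomial(k, k / (k + mu))

    truth.mu = pd.Series(mu, index=idx)
    truth.mu_base = pd.Series(mu_base, index=idx)
    if truth.event is not None:
        in_event = idx.isin(truth.event.dates)
        truth.true_total_excess = float(np.sum(mu_base[in_event]) * (truth.rr - 1.0))
    else:
        truth.true_total_excess = 0.0

    frame = covariates.copy()
    frame.insert(0, "y", y)
    return DailyOutcomeSeries(frame)


def make_study_fixture(
    scale: str = "small",
    seed: int = 0,
    rr: float = 1.15,
    dispersion: Optional[float] = 50.0,
) -> tuple[DailyOutcomeSeries, SplitSpec, SimulationTruth]:
    """Ready-made study: series + timeline split + generating truth.

    ``small`` spans 4 calendar years (1461 days, 2015-2018) for fast tests;
    ``paper_like`` spans 10 years (2009-2018) with split dates matching the
    case-study timeline.  Both inject a 12-day event (Nov 9-20 of the final
    year) with rate ratio ``rr`` and a smoke-PM2.5 spike over the same days.
    """
    if scale == "small":
        start, n_days = "2015-01-01", 1461
        train_end, test_end = "2017-11-07", "2018-11-07"
    elif scale == "paper_like":
        start, n_days = "2009-01-01", 3652
        train_end, test_end = "2016-11-07", "2018-11-07"
    else:
        raise ValueError("scale must be 'small' or 'paper_like'")
    event = EventWindow("2018-11-09", "2018-11-20")
    spec = SplitSpec(
        train_end=train_end, test_end=test_end, event=event, post_extra_end="2018-12-31"
    )
    cov = generate_covariates(n_days, seed, start=start, smoke_event=event)
    truth = SimulationTruth(event=event, rr=rr, dispersion=dispersion)
    series = generate_series(truth, cov, seed)
    return series, spec, truth
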