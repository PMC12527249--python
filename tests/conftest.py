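import numpy as np
import pandas as pd
import pytest

from itscast import DailyOutcomeSeries, make_study_fixture


def build_series(values, start="2020-01-01", **covariates) -> DailyOutcomeSeries:
    """Small helper: daily series from a list of counts (+ covariate columns)."""
    idx = pd.date_range(start, periods=len(values), freq="D")
    frame = pd.DataFrame({"y": values}, index=idx)
    for name, col in covariates.items():
        frame[name] = col
    return DailyOutcomeSeries(frame)


@pytest.fixture(scope="session")
def small_study():
    """4-year synthetic study with a 12-day injected event (RR=1.15)."""
    return make_study_fixture("small", seed=7, rr=1.15)


@pytest.fixture(scope="session")
def ar1_series():
    """Positive AR(1)-around-a-level count series for forecaster tests."""
    rng = np.random.default_rng(42)
    n = 2000
    y = np.empty(n)
    y[0] = 0.0
    eps = rng.normal(0, 5.0, n)
    for t in range(1, n):
        y[t] = 0.6 * y[t - 1] + eps[t]
    counts = np.round(y + 60.0).clip(0)
    return build_series(counts.astype(int), start="2012-01-01")
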