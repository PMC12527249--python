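"""Daily count series, timeline splitting, and event-window detection.

The single source of truth for every pipeline stage is a
:class:`DailyOutcomeSeries`: strictly consecutive calendar days, a
non-negative integer outcome count per day (e.g. respiratory
hospitalizations), and named real-valued covariate columns (meteorology and
pollutant concentrations).  The causal timeline of a two-stage interrupted
time series analysis is expressed as a :class:`SplitSpec` — training and
testing segments fitted on pre-event data, an event window, and a post-event
reporting horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DailyOutcomeSeries",
    "EventWindow",
    "SplitSpec",
    "SplitResult",
    "SeriesValidationError",
    "load_daily_series",
    "split_series",
    "detect_event_window",
]

#: canonical covariate column names; loaders may remap arbitrary CSV headers onto these
DEFAULT_COVARIATES = (
    "tmax",
    "tmin",
    "dewpoint",
    "precip",
    "nonsmoke_pm25",
    "smoke_pm25",
)


class SeriesValidationError(ValueError):
    """Raised when input data violate the daily-series invariants."""


def _as_timestamp(d) -> pd.Timestamp:
    ts = pd.Timestamp(d)
    return ts.normalize()


@dataclass(frozen=True)
class EventWindow:
    """Closed interval of calendar days defining the exposure event."""

    start: pd.Timestamp
    end: pd.Timestamp

    def __post_init__(self):
        object.__setattr__(self, "start", _as_timestamp(self.start))
        object.__setattr__(self, "end", _as_timestamp(self.end))
        if self.start > self.end:
            raise SeriesValidationError(
                f"event window start {self.start.date()} after end {self.end.date()}"
            )

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days + 1

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, self.end, freq="D")


@dataclass(frozen=True)
class SplitSpec:
    """Timeline split: train ends, test ends, event window, post-event reporting end.

    Days strictly between ``test_end`` and ``event.start`` (e.g. the single
    day between a Nov 7 test end and a Nov 9 event start) belong to no
    fitting segment; they are carried as a *buffer* and reported separately.
    """

    train_end: pd.Timestamp
    test_end: pd.Timestamp
    event: EventWindow
    post_extra_end: pd.Timestamp

    def __post_init__(self):
        object.__setattr__(self, "train_end", _as_timestamp(self.train_end))
        object.__setattr__(self, "test_end", _as_timestamp(self.test_end))
        object.__setattr__(self, "post_extra_end", _as_timestamp(self.post_extra_end))
        if not (self.train_end < self.test_end < self.event.start):
            raise SeriesValidationError(
                "split requires train_end < test_end < event start; got "
                f"{self.train_end.date()}, {self.test_end.date()}, {self.event.start.date()}"
            )
        if self.post_extra_end < self.event.end:
            raise SeriesValidationError("post_extra_end precedes the event end")


@dataclass
class DailyOutcomeSeries:
    """Dated daily outcome counts plus covariates.

    Parameters
    ----------
    frame
        DataFrame indexed by a daily ``DatetimeIndex`` with an integer-valued
        ``y`` column and zero or more real-valued covariate columns.
    """

    frame: pd.DataFrame
    validate_counts: bool = field(default=True, repr=False)

    def __post_init__(self):
        if "y" not in self.frame.columns:
            raise SeriesValidationError("series frame must contain a 'y' column")
        idx = pd.DatetimeIndex(self.frame.index)
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique()
            raise SeriesValidationError(
                "duplicate dates: " + ", ".join(str(d.date()) for d in dups[:5])
            )
        if not idx.is_monotonic_increasing:
            self.frame = self.frame.sort_index()
            idx = pd.DatetimeIndex(self.frame.index)
        if len(idx) > 1:
            deltas = np.diff(idx.values).astype("timedelta64[D]").astype(int)
            bad = np.nonzero(deltas != 1)[0]
            if bad.size:
                i = bad[0]
                raise SeriesValidationError(
                    f"gap in dates between {idx[i].date()} and {idx[i + 1].date()}"
                )
        y = self.frame["y"]
        if y.isna().any():
            raise SeriesValidationError("missing outcome values inside the analysis span")
        if self.validate_counts:
            if (y < 0).any():
                raise SeriesValidationError("negative outcome counts")
            if not np.allclose(y, np.round(y)):
                raise SeriesValidationError("non-integer outcome counts")
            self.frame = self.frame.assign(y=y.round().astype(int))
        self.frame.index = idx
        self.frame.index.name = "date"

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.frame.index)

    @property
    def y(self) -> pd.Series:
        return self.frame["y"]

    @property
    def covariates(self) -> pd.DataFrame:
        return self.frame.drop(columns="y")

    @property
    def start(self) -> pd.Timestamp:
        return self.dates[0]

    @property
    def end(self) -> pd.Timestamp:
        return self.dates[-1]

    def slice(self, start, end) -> "DailyOutcomeSeries":
        """Closed-interval [start, end] sub-series."""
        start, end = _as_timestamp(start), _as_timestamp(end)
        sub = self.frame.loc[start:end]
        return DailyOutcomeSeries(sub.copy(), validate_counts=self.validate_counts)

    def to_csv(self, path, column_map: Optional[Mapping[str, str]] = None) -> None:
        """Write the CSV dialect :func:`load_daily_series` reads back."""
        out = self.frame.reset_index()
        if column_map:
            out = out.rename(columns=column_map)
        out.to_csv(path, index=False)


class SplitResult(NamedTuple):
    """Timeline segments. ``buffer`` may be empty; it is excluded from fitting."""

    train: DailyOutcomeSeries
    test: DailyOutcomeSeries
    buffer: Optional[DailyOutcomeSeries]
    post: DailyOutcomeSeries


def load_daily_series(
    path,
    column_map: Optional[Mapping[str, str]] = None,
    date_column: str = "date",
    outcome_column: str = "y",
) -> DailyOutcomeSeries:
    """Read a daily series CSV and validate it.

    ``column_map`` maps CSV headers to canonical names (``{"admits": "y",
    "TMAX": "tmax"}``); ``date_column``/``outcome_column`` name the date and
    count columns *after* mapping.
    """
    raw = pd.read_csv(path)
    if column_map:
        raw = raw.rename(columns=dict(column_map))
    if date_column not in raw.columns:
        raise SeriesValidationError(f"no date column {date_column!r} in {sorted(raw.columns)}")
    if outcome_column not in raw.columns:
        raise SeriesValidationError(f"no outcome column {outcome_column!r}")
    raw = raw.rename(columns={outcome_column: "y"})
    dates = pd.to_datetime(raw[date_column], format="ISO8601")
    frame = raw.drop(columns=[date_column]).set_index(pd.DatetimeIndex(dates))
    if not pd.api.types.is_numeric_dtype(frame["y"]):
        raise SeriesValidationError("outcome column is not numeric")
    return DailyOutcomeSeries(frame.sort_index())


def split_series(series: DailyOutcomeSeries, spec: SplitSpec) -> SplitResult:
    """Split a series into train / test / buffer / post segments.

    train is [series start, train_end]; test is (train_end, test_end]; post
    is [event.start, post_extra_end]; any days strictly between test_end and
    event.start form the buffer.  Re-concatenating all four reproduces the
    input rows over [start, post_extra_end].
    """
    if spec.train_end < series.start or spec.post_extra_end > series.end:
        raise SeriesValidationError(
            f"split dates outside series range {series.start.date()}..{series.end.date()}"
        )
    train = series.slice(series.start, spec.train_end)
    test = series.slice(spec.train_end + pd.Timedelta(days=1), spec.test_end)
    buffer = None
    if spec.event.start - spec.test_end > pd.Timedelta(days=1):
        buffer = series.slice(
            spec.test_end + pd.Timedelta(days=1),
            spec.event.start - pd.Timedelta(days=1),
        )
    post = series.slice(spec.event.start, spec.post_extra_end)
    return SplitResult(train, test, buffer, post)


def detect_event_window(
    series: DailyOutcomeSeries,
    column: str,
    threshold: float,
    min_run: int = 1,
) -> Optional[EventWindow]:
    """First maximal run of >= ``min_run`` consecutive days strictly above ``threshold``.

    Exceedance is strict (a value exactly at the threshold does not count).
    Returns ``None`` when no qualifying run exists.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    if column not in series.frame.columns:
        raise KeyError(f"unknown column {column!r}")
    above = (series.frame[column].to_numpy() > threshold).astype(int)
    dates = series.dates
    run_start = None
    for i, flag in enumerate(above):
        if flag and run_start is None:
            run_start = i
        elif not flag and run_start is not None:
            if i - run_start >= min_run:
                return EventWindow(dates[run_start], dates[i - 1])
            run_start = None
    if run_start is not None and len(above) - run_start >= min_run:
        return EventWindow(dates[run_start], dates[-1])
    return None
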