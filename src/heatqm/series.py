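"""Daily time series: a pandas Series with a strictly increasing daily DatetimeIndex.

All modules in this package exchange daily data (temperature in deg C, ED
counts) as ``pandas.Series`` objects whose index is a daily ``DatetimeIndex``
with no duplicate dates.  Missing values are NaN; every consuming operation
states its own missing-value policy (fitting drops NaN, elementwise
application propagates it).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: calendar-season label for each month (meteorological seasons)
SEASON_OF_MONTH = {
    12: "DJF", 1: "DJF", 2: "DJF",
    3: "MAM", 4: "MAM", 5: "MAM",
    6: "JJA", 7: "JJA", 8: "JJA",
    9: "SON", 10: "SON", 11: "SON",
}

SEASONS = ("DJF", "MAM", "JJA", "SON")

#: warm-season months used for the health analysis (May-September)
WARM_MONTHS = (5, 6, 7, 8, 9)


def daily_series(dates, values, name: str | None = None) -> pd.Series:
    """Build and validate a daily series.

    Raises ``ValueError`` on unequal lengths, duplicate dates, or a
    non-increasing date sequence.  Gaps are permitted (e.g. a warm-season
    subset); the step between consecutive dates must be >= 1 day.
    """
    idx = pd.DatetimeIndex(dates)
    values = np.asarray(values, dtype=float)
    if len(idx) != len(values):
        raise ValueError(f"dates ({len(idx)}) and values ({len(values)}) differ in length")
    if idx.has_duplicates:
        raise ValueError("duplicate dates in daily series")
    if len(idx) > 1 and not idx.is_monotonic_increasing:
        raise ValueError("dates must be strictly increasing")
    return pd.Series(values, index=idx, name=name)


def validate_daily(series: pd.Series) -> pd.Series:
    """Validate an existing series against the daily-series invariants."""
    return daily_series(series.index, series.to_numpy(), name=series.name)


def season_labels(index: pd.DatetimeIndex) -> np.ndarray:
    """Meteorological season (DJF/MAM/JJA/SON) of each date."""
    return np.array([SEASON_OF_MONTH[m] for m in index.month])


def align(a: pd.Series, b: pd.Series) -> tuple[pd.Series, pd.Series]:
    """Require two series to share identical dates; return them as passed.

    Raises ``ValueError`` when the indexes differ, rather than silently
    intersecting, because every pairwise statistic here assumes day-for-day
    correspondence.
    """
    if not a.index.equals(b.index):
        raise ValueError("series are not aligned on identical dates")
    return a, b


def read_csv(path) -> pd.Series:
    """Read a ``date,value`` CSV (ISO-8601 dates) into a daily series."""
    df = pd.read_csv(path, parse_dates=["date"])
    return daily_series(df["date"], df["value"])


def write_csv(series: pd.Series, path) -> None:
    """Write a daily series as a ``date,value`` CSV with ISO-8601 dates."""
    out = pd.DataFrame({
        "date": series.index.strftime("%Y-%m-%d"),
        "value": series.to_numpy(),
    })
    out.to_csv(path, index=False)


def warm_season(series: pd.Series) -> pd.Series:
    """Subset to May-September days."""
    return series[series.index.month.isin(WARM_MONTHS)]
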