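"""Calendar-month date arithmetic.

All survey dates are held at month resolution with the day fixed at 15 (the
instrument collects year/month at best); the only day-level dates are the
war start, the data-collection window and per-respondent completion dates.
Durations are day counts divided by 365.25.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365.25
MID_DAY = 15


def ym_to_date(year, month, day: int = MID_DAY) -> dt.date:
    return dt.date(int(year), int(month), int(day))


def shift_months(dates, months, day: int | None = None) -> pd.Series:
    """Shift datetime-like values by whole calendar months (vectorised).

    The day of month is preserved unless ``day`` is given; days are clamped
    to 28 so the result is always a valid date.
    """
    idx = pd.DatetimeIndex(pd.Series(dates))
    months = np.asarray(months, dtype="int64")
    tot = idx.year.values * 12 + (idx.month.values - 1) + months
    y, m = tot // 12, tot % 12 + 1
    d = np.full(len(idx), day, dtype="int64") if day is not None else np.minimum(idx.day.values, 28)
    out = pd.to_datetime({"year": y, "month": m, "day": d})
    return pd.Series(out.values, index=pd.Series(dates).index if isinstance(dates, pd.Series) else None)


def years_between(start, end) -> np.ndarray:
    """Elapsed years (day count / 365.25) between two datetime-like arrays."""
    start = pd.DatetimeIndex(pd.Series(start)).values.astype("datetime64[D]")
    end = pd.DatetimeIndex(pd.Series(end)).values.astype("datetime64[D]")
    return (end - start).astype("int64") / DAYS_PER_YEAR


def as_day_array(dates) -> np.ndarray:
    """Convert datetime-likes to an int64 array of days since the Unix epoch."""
    return pd.DatetimeIndex(pd.Series(dates)).values.astype("datetime64[D]").astype("int64")


def date_to_day(d: dt.date) -> int:
    return (np.datetime64(d, "D") - np.datetime64(0, "D")).astype("int64").item()


def day_to_date(day: int) -> dt.date:
    return (np.datetime64(0, "D") + np.timedelta64(int(day), "D")).item()
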