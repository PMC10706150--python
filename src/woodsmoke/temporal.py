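"""Temporal aggregation: 2-min records → hourly means → daily averages.

Conventions match reference-network practice at the sites emulated here:

* all timestamps are local *standard* time (reference networks ignore
  daylight saving); tz-aware inputs are rejected rather than converted;
* a raw record belongs to the hour containing the midpoint of its
  reported interval, so a record spanning 23:58:59-00:00:59 counts in
  the 23:00 hour;
* a daily average is only reported when at least ``min_hours`` (default
  23 of 24) hourly values are present — stricter than the common 18-hour
  rule, because woodsmoke evenings make partial days unrepresentative;
* negative hourly values from reference instruments are legitimate noise
  around zero and are retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Sequence

import pandas as pd

from .errors import InvalidInputError, TimestampError

__all__ = [
    "ExclusionWindow",
    "records_to_hourly",
    "hourly_to_daily",
    "apply_exclusions",
    "DEFAULT_MIN_HOURS",
    "DEFAULT_EXCLUSION_WINDOWS",
]

DEFAULT_MIN_HOURS = 23


@dataclass(frozen=True)
class ExclusionWindow:
    """A labelled, date-inclusive window of days to exclude from analysis."""

    label: str
    start_date: date
    end_date: date

    def __post_init__(self) -> None:
        if self.start_date > self.end_date:
            raise InvalidInputError(
                f"exclusion window {self.label!r} has start after end"
            )


#: Windows excluded from the NSW collocation comparisons by default:
#: the Black Summer bushfire episode and a span of questionable
#: reference data.  Date-inclusive; user-editable in the pipeline config.
DEFAULT_EXCLUSION_WINDOWS = (
    ExclusionWindow("black_summer_bushfires", date(2019, 11, 1), date(2020, 1, 31)),
    ExclusionWindow("reference_data_problems", date(2022, 1, 1), date(2022, 5, 31)),
)


def _check_naive(ts: pd.Series | pd.DatetimeIndex, what: str) -> None:
    tz = getattr(ts.dtype, "tz", None)
    if tz is not None:
        raise TimestampError(
            f"{what} timestamps carry a timezone/daylight-saving offset ({tz}); "
            "supply naive local standard time instead"
        )


def records_to_hourly(
    records: pd.DataFrame,
    value_cols: Sequence[str],
    start_col: str = "timestamp_start",
    end_col: str = "timestamp_end",
) -> pd.DataFrame:
    """Average raw interval records into hourly means by interval midpoint.

    Parameters
    ----------
    records:
        Frame with naive local-standard-time interval columns and one or
        more numeric value columns.
    value_cols:
        Columns to average.  NaNs are ignored per column.

    Returns
    -------
    Frame with ``hour`` (start of each hour that received at least one
    record), the per-column hourly means, and ``n_<col>`` counts of
    contributing records.  Hours with no records are simply absent.

    Raises
    ------
    TimestampError
        If start times are unsorted or duplicated (listing the
        offenders), or timestamps are tz-aware.
    """
    starts = pd.to_datetime(records[start_col])
    ends = pd.to_datetime(records[end_col])
    _check_naive(starts, "record")
    _check_naive(ends, "record")
    if len(records) == 0:
        return pd.DataFrame(
            columns=["hour", *value_cols, *(f"n_{c}" for c in value_cols)]
        )
    if not starts.is_monotonic_increasing:
        bad = starts[starts.diff() < pd.Timedelta(0)]
        raise TimestampError(f"record start times are not sorted; offenders: {bad.tolist()[:5]}")
    dupes = starts[starts.duplicated()]
    if len(dupes):
        raise TimestampError(
            f"duplicate record start times: {dupes.unique().tolist()[:5]}"
        )

    midpoint = starts + (ends - starts) / 2
    hour = midpoint.dt.floor("h")
    grouped = records[list(value_cols)].groupby(hour)
    means = grouped.mean()
    counts = grouped.count().rename(columns=lambda c: f"n_{c}")
    out = pd.concat([means, counts], axis=1).reset_index()
    return out.rename(columns={out.columns[0]: "hour"})


def hourly_to_daily(
    hourly: pd.DataFrame,
    min_hours: int = DEFAULT_MIN_HOURS,
    value_col: str = "pm25",
    hour_col: str = "hour",
) -> pd.DataFrame:
    """Daily means from hourly values under a completeness rule.

    A calendar day is ``complete`` when at least ``min_hours`` non-missing
    hourly values fall on it; incomplete days keep their hour count but
    carry NaN for the daily mean.  ``min_hours=0`` reduces to a plain
    calendar-day mean.
    """
    if not 0 <= min_hours <= 24:
        raise InvalidInputError(f"min_hours must lie in [0, 24], got {min_hours}")
    hours = pd.to_datetime(hourly[hour_col])
    _check_naive(hours, "hourly")
    values = hourly[value_col]
    day = hours.dt.normalize()
    grouped = values.groupby(day)
    n_hours = grouped.count()
    means = grouped.mean()
    complete = n_hours >= min_hours
    out = pd.DataFrame(
        {
            "date": n_hours.index,
            "pm25": means.where(complete),
            "n_hours": n_hours.to_numpy(),
            "complete": complete.to_numpy(),
        }
    ).reset_index(drop=True)
    return out


def apply_exclusions(
    daily: pd.DataFrame,
    windows: Sequence[ExclusionWindow],
    date_col: str = "date",
) -> pd.DataFrame:
    """Mark days falling inside any exclusion window (date-inclusive).

    Adds ``excluded`` (bool) and ``exclusion_label`` (first matching
    window's label, for audit) columns; an empty window list yields the
    identity with ``excluded`` all False.  Windows may overlap.
    """
    out = daily.copy()
    dates = pd.to_datetime(out[date_col]).dt.date
    excluded = pd.Series(False, index=out.index)
    labels = pd.Series([None] * len(out), index=out.index, dtype=object)
    for w in windows:
        inside = (dates >= w.start_date) & (dates <= w.end_date)
        labels = labels.mask(inside & ~excluded, w.label)
        excluded |= inside
    out["excluded"] = excluded.to_numpy()
    out["exclusion_label"] = labels.to_numpy()
    return out
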