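"""Dual-laser quality control: fusing the A and B channels of one unit.

Each unit carries two identical laser counters sampling the same air, so
hardware faults (a speck of dirt, a failing fan) show up as discordance
between the channels.  The fusion rule compares the two hourly channel
means L = min(A, B) and H = max(A, B):

* if the absolute difference AD = H − L exceeds both an absolute
  threshold (default 10 µg/m³) and half the channel mean m = (L+H)/2,
  the hour is flagged discordant and averaged with a weight on the low
  channel of ``wt_low = 0.5 × (1 + min(1, AD/m))`` — rising from 0.5 at
  mild discordance to 1 (high channel discarded) once AD ≥ m;
* otherwise the plain mean of the two channels is used.

Hours where only one channel reported are retained, flagged, and carry
that channel's value (``wt_low = 1``); completeness matters more for
daily averaging than symmetric weighting does.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError, MissingHourError

__all__ = [
    "ChannelPairHour",
    "FusedHour",
    "fuse_channels",
    "fuse_hourly",
    "discordance_rate",
    "HOURS_PER_YEAR",
]

#: Hours in the nominal (365-day) year used to scale discordance rates.
HOURS_PER_YEAR = 365 * 24

DEFAULT_AD_ABS_THRESHOLD = 10.0
DEFAULT_AD_FRAC_THRESHOLD = 0.5


@dataclass(frozen=True)
class ChannelPairHour:
    """Hourly channel means for one unit, either of which may be missing."""

    hour_start: object
    pm_a: Optional[float]
    pm_b: Optional[float]
    n_records_a: int = 0
    n_records_b: int = 0


@dataclass(frozen=True)
class FusedHour:
    """Result of fusing one hour's A/B channel pair."""

    hour_start: object
    pm25: float
    discordant: bool
    wt_low: float


def _present(x: Optional[float]) -> bool:
    return x is not None and not (isinstance(x, float) and np.isnan(x))


def fuse_channels(
    pair: ChannelPairHour,
    ad_abs_threshold: float = DEFAULT_AD_ABS_THRESHOLD,
    ad_frac_threshold: float = DEFAULT_AD_FRAC_THRESHOLD,
) -> FusedHour:
    """Fuse one hour's A/B channel means into a single PM2.5 value.

    Raises
    ------
    MissingHourError
        If both channels are missing.
    """
    a_ok, b_ok = _present(pair.pm_a), _present(pair.pm_b)
    if not a_ok and not b_ok:
        raise MissingHourError(f"both channels missing for hour {pair.hour_start}")
    if a_ok != b_ok:
        value = pair.pm_a if a_ok else pair.pm_b
        return FusedHour(pair.hour_start, float(value), discordant=True, wt_low=1.0)

    lo, hi = float(min(pair.pm_a, pair.pm_b)), float(max(pair.pm_a, pair.pm_b))
    if lo < 0:
        raise InvalidInputError(
            f"channel means must be non-negative, got ({pair.pm_a}, {pair.pm_b})"
        )
    ad = hi - lo
    mean = 0.5 * (lo + hi)
    if ad > ad_abs_threshold and ad > ad_frac_threshold * mean:
        if mean <= 0:
            # unreachable for non-negative channels once ad > abs threshold > 0
            raise InvalidInputError(
                f"zero channel mean with positive discordance at {pair.hour_start}"
            )
        wt_low = 0.5 * (1.0 + min(1.0, ad / mean))
        return FusedHour(
            pair.hour_start,
            wt_low * lo + (1.0 - wt_low) * hi,
            discordant=True,
            wt_low=wt_low,
        )
    return FusedHour(pair.hour_start, mean, discordant=False, wt_low=0.5)


def fuse_hourly(
    hourly: pd.DataFrame,
    ad_abs_threshold: float = DEFAULT_AD_ABS_THRESHOLD,
    ad_frac_threshold: float = DEFAULT_AD_FRAC_THRESHOLD,
) -> pd.DataFrame:
    """Fuse a frame of hourly channel means.

    Parameters
    ----------
    hourly:
        Frame with columns ``hour`` (timestamps), ``pm_a`` and ``pm_b``
        (µg/m³, NaN where a channel is missing).

    Returns
    -------
    Frame with columns ``hour``, ``pm25``, ``discordant``, ``wt_low``.
    Hours where both channels are missing are dropped.
    """
    out = []
    for row in hourly.itertuples(index=False):
        pair = ChannelPairHour(row.hour, row.pm_a, row.pm_b)
        try:
            fused = fuse_channels(pair, ad_abs_threshold, ad_frac_threshold)
        except MissingHourError:
            continue
        out.append((fused.hour_start, fused.pm25, fused.discordant, fused.wt_low))
    return pd.DataFrame(out, columns=["hour", "pm25", "discordant", "wt_low"])


def discordance_rate(
    hours: Sequence[ChannelPairHour] | Iterable[ChannelPairHour],
    ad_abs_threshold: float = DEFAULT_AD_ABS_THRESHOLD,
    ad_frac_threshold: float = DEFAULT_AD_FRAC_THRESHOLD,
) -> float:
    """Rate of threshold-tripping discordant hours, per nominal year.

    Only hours where both channels reported and the two-threshold rule
    trips are counted; single-channel hours are flagged by
    :func:`fuse_channels` but are a completeness issue, not laser
    disagreement.  The span is the closed interval from the first to the
    last hour, in units of a nominal 8760-hour year.
    """
    hours = list(hours)
    if not hours:
        raise InvalidInputError("cannot compute a discordance rate on no hours")
    starts = pd.to_datetime([h.hour_start for h in hours])
    span_hours = (starts.max() - starts.min()) / pd.Timedelta(hours=1) + 1.0
    if span_hours <= 0:
        raise InvalidInputError("zero-duration input")
    n_discordant = 0
    for h in hours:
        if not (_present(h.pm_a) and _present(h.pm_b)):
            continue
        fused = fuse_channels(h, ad_abs_threshold, ad_frac_threshold)
        n_discordant += int(fused.discordant)
    return n_discordant * HOURS_PER_YEAR / span_hours
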