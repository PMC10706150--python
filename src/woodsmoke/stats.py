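"""Collocation statistics between a candidate and a reference daily series.

The comparison convention throughout is *reference on candidate*: the
reference instrument (TEOM/BAM) is the response and the low-cost
candidate the regressor, i.e. ``ref = slope × cand + intercept``.  Both
an ordinary-least-squares fit and a reduced-major-axis (RMA) slope are
reported: with error in both variables OLS attenuates the slope by a
factor of r, while the RMA slope |sd(ref)/sd(cand)| (signed by r) treats
the two instruments symmetrically.

RMSE is computed on the raw pairs, sqrt(mean((cand − ref)²)) — a direct
accuracy measure, not the regression residual.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateSeriesError

__all__ = [
    "CollocationStats",
    "ResidualDiagnostics",
    "paired_days",
    "collocation_stats",
    "residual_diagnostics",
]


@dataclass(frozen=True)
class CollocationStats:
    """One row of a collocation summary table."""

    n_days: int
    r: float
    r_se: float
    rmse: float
    rma_slope: float
    ols_slope: float
    ols_intercept: float
    mean_ref: float
    mean_candidate: float


@dataclass(frozen=True)
class ResidualDiagnostics:
    """Correlations of daily residuals (ref − cand) with size diagnostics."""

    n_days: int
    r_residual_p1: float
    r_residual_pm_ratio: float


def paired_days(
    ref: pd.DataFrame,
    cand: pd.DataFrame,
    date_col: str = "date",
    value_col: str = "pm25",
) -> pd.DataFrame:
    """Inner-join two daily series on usable days.

    A day is usable when it is complete (if a ``complete`` column is
    present), not excluded (if an ``excluded`` column is present) and
    carries a non-missing value.  Returns a frame with columns ``date``,
    ``ref``, ``cand``.
    """

    def usable(frame: pd.DataFrame) -> pd.DataFrame:
        mask = frame[value_col].notna()
        if "complete" in frame:
            mask &= frame["complete"].astype(bool)
        if "excluded" in frame:
            mask &= ~frame["excluded"].astype(bool)
        return frame.loc[mask, [date_col, value_col]]

    left = usable(ref).rename(columns={value_col: "ref"})
    right = usable(cand).rename(columns={value_col: "cand"})
    pairs = left.merge(right, on=date_col, how="inner")
    if pairs.empty:
        raise DegenerateSeriesError(
            "no overlapping complete, non-excluded days between the two series"
        )
    return pairs.rename(columns={date_col: "date"})


def collocation_stats(pairs: pd.DataFrame) -> CollocationStats:
    """Compute the full collocation summary for a paired daily frame.

    Parameters
    ----------
    pairs:
        Frame with columns ``ref`` and ``cand`` (µg/m³ daily means).

    Raises
    ------
    DegenerateSeriesError
        With fewer than 3 pairs or zero variance in either member.
    """
    ref = np.asarray(pairs["ref"], dtype=float)
    cand = np.asarray(pairs["cand"], dtype=float)
    n = len(ref)
    if n < 3:
        raise DegenerateSeriesError(f"need at least 3 paired days, got {n}")
    sd_ref = ref.std(ddof=1)
    sd_cand = cand.std(ddof=1)
    if sd_ref == 0 or sd_cand == 0:
        raise DegenerateSeriesError("zero variance in one of the paired series")

    r = float(sps.pearsonr(ref, cand).statistic)
    # Large-sample SE of a correlation coefficient.
    r_se = math.sqrt((1.0 - r * r) / (n - 2))
    rmse = float(np.sqrt(np.mean((cand - ref) ** 2)))
    rma_slope = math.copysign(sd_ref / sd_cand, r) if r != 0 else sd_ref / sd_cand
    fit = sps.linregress(cand, ref)
    return CollocationStats(
        n_days=n,
        r=r,
        r_se=r_se,
        rmse=rmse,
        rma_slope=rma_slope,
        ols_slope=float(fit.slope),
        ols_intercept=float(fit.intercept),
        mean_ref=float(ref.mean()),
        mean_candidate=float(cand.mean()),
    )


def residual_diagnostics(
    pairs: pd.DataFrame,
    p1: pd.DataFrame,
    pm_ratio: pd.DataFrame,
) -> ResidualDiagnostics:
    """Correlate daily residuals (ref − cand) with aerosol size diagnostics.

    Parameters
    ----------
    pairs:
        Output of :func:`paired_days` (``date``, ``ref``, ``cand``).
    p1:
        Daily sub-micron mass fraction: columns ``date``, ``p1``.
    pm_ratio:
        Daily reference PM2.5/PM10 ratio: columns ``date``, ``pm_ratio``.

    A positive residual-vs-P1 correlation together with a negative
    residual-vs-ratio correlation is the signature of coarse-particle
    underestimation by a combustion-tuned optical conversion.

    Raises
    ------
    DegenerateSeriesError
        With fewer than 3 aligned days, or constant residuals.
    """
    merged = pairs.merge(p1, on="date").merge(pm_ratio, on="date").dropna(
        subset=["ref", "cand", "p1", "pm_ratio"]
    )
    if len(merged) < 3:
        raise DegenerateSeriesError(
            f"need at least 3 aligned days for residual diagnostics, got {len(merged)}"
        )
    residual = merged["ref"] - merged["cand"]
    if residual.std(ddof=1) == 0:
        raise DegenerateSeriesError("residuals are constant; correlations undefined")
    r_p1 = float(sps.pearsonr(residual, merged["p1"]).statistic)
    r_ratio = float(sps.pearsonr(residual, merged["pm_ratio"]).statistic)
    return ResidualDiagnostics(
        n_days=len(merged), r_residual_p1=r_p1, r_residual_pm_ratio=r_ratio
    )
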