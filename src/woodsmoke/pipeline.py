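"""End-to-end pipeline: raw records → fused hourly → daily → statistics.

For every unit the stages are: convert each laser channel's raw output
to PM2.5 (per-unit linear calibration, default woodsmoke conversion,
count-based ALT-3.4, or the US-EPA RH correction), average to hourly by
interval midpoint, fuse the A/B channels with the discordance rule,
aggregate to daily under the ≥23-hour completeness rule, drop excluded
windows, then pair with the reference daily series and compute the
collocation summary for the whole span and for the wood-heating season
(April–September).
"""

from __future__ import annotations

import logging
from typing import Dict, Mapping, Tuple

import numpy as np
import pandas as pd

from . import conversions as conv
from .errors import DegenerateSeriesError, SchemaError
from .io import PipelineConfig, calibration_for
from .qc import fuse_hourly
from .stats import collocation_stats, paired_days
from .temporal import apply_exclusions, hourly_to_daily, records_to_hourly

logger = logging.getLogger(__name__)

__all__ = [
    "channel_pm25",
    "unit_daily_series",
    "reference_daily_series",
    "run_pipeline",
    "report_to_text",
    "REPORT_COLUMNS",
]

REPORT_COLUMNS = [
    "site",
    "unit",
    "conversion",
    "period",
    "n_days",
    "r",
    "r_se",
    "rmse",
    "rma_slope",
    "ols_slope",
    "ols_intercept",
    "mean_ref",
    "mean_pa",
]

#: Months of the wood-heating season (southern hemisphere).
HEATING_SEASON_MONTHS = range(4, 10)


def channel_pm25(
    records: pd.DataFrame, conversion: str, config: PipelineConfig, unit_id: str
) -> pd.DataFrame:
    """Per-record PM2.5 for each laser channel under the chosen conversion.

    Returns a frame with ``timestamp_start``, ``timestamp_end``,
    ``pm_a``, ``pm_b``.  The US-EPA conversion can go slightly negative
    at very low cf1 and high humidity; values are floored at zero so the
    discordance rule's non-negativity precondition holds.
    """
    out = records[["timestamp_start", "timestamp_end"]].copy()
    if conversion in ("fitted", "default_woodsmoke"):
        cal = (
            conv.DEFAULT_WOODSMOKE
            if conversion == "default_woodsmoke"
            else calibration_for(unit_id, config.calibrations)
        )
        for ch in ("a", "b"):
            out[f"pm_{ch}"] = conv.apply_linear_calibration(
                records[f"cf1_{ch}"].to_numpy(), cal
            )
    elif conversion == "alt34":
        for ch in ("a", "b"):
            out[f"pm_{ch}"] = conv.alt34_from_channels(
                records[f"n_gt_0p3_{ch}"].to_numpy(),
                records[f"n_gt_0p5_{ch}"].to_numpy(),
                records[f"n_gt_1_{ch}"].to_numpy(),
                records[f"n_gt_2p5_{ch}"].to_numpy(),
            )
    elif conversion == "usepa":
        if "rh" not in records:
            raise SchemaError("usepa conversion needs a relative-humidity column")
        for ch in ("a", "b"):
            out[f"pm_{ch}"] = np.clip(
                conv.usepa_conversion(
                    records[f"cf1_{ch}"].to_numpy(), records["rh"].to_numpy()
                ),
                0.0,
                None,
            )
    else:
        raise SchemaError(f"unknown conversion {conversion!r}")
    return out


def unit_daily_series(
    records: pd.DataFrame,
    conversion: str,
    config: PipelineConfig,
    unit_id: str,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Daily fused PM2.5 for one unit; returns (daily, fused_hourly)."""
    per_record = channel_pm25(records, conversion, config, unit_id)
    hourly = records_to_hourly(per_record, value_cols=["pm_a", "pm_b"])
    fused = fuse_hourly(
        hourly, config.ad_abs_threshold, config.ad_frac_threshold
    )
    daily = hourly_to_daily(fused, min_hours=config.min_hours)
    daily = apply_exclusions(daily, config.exclusion_windows)
    return daily, fused


def reference_daily_series(
    reference: pd.DataFrame, config: PipelineConfig
) -> pd.DataFrame:
    """Daily reference PM2.5 under the same completeness/exclusion rules."""
    hourly = reference.rename(columns={"hour_start": "hour"})
    daily = hourly_to_daily(hourly, min_hours=config.min_hours)
    daily = apply_exclusions(daily, config.exclusion_windows)
    return daily


def _period_mask(pairs: pd.DataFrame, period: str) -> pd.Series:
    if period == "all":
        return pd.Series(True, index=pairs.index)
    if period == "apr_sep":
        months = pd.to_datetime(pairs["date"]).dt.month
        return months.isin(list(HEATING_SEASON_MONTHS))
    raise SchemaError(f"unknown period {period!r}")


def run_pipeline(
    config: PipelineConfig,
    units: Mapping[str, pd.DataFrame],
    reference: pd.DataFrame,
    periods: Tuple[str, ...] = ("all", "apr_sep"),
) -> Tuple[pd.DataFrame, Dict[str, pd.DataFrame]]:
    """Run the full collocation comparison for every unit and conversion.

    Parameters
    ----------
    config:
        Pipeline settings (calibrations, conversion per unit, QC
        thresholds, completeness rule, exclusion windows).
    units:
        Mapping unit_id → raw records in the canonical dialect.
    reference:
        Hourly reference records (``hour_start``, ``pm25`` [, ``pm10``]).
    periods:
        Named comparison periods; ``all`` and the April–September
        heating season are built in.

    Returns
    -------
    (report, dailies):
        ``report`` has one row per unit × period with the collocation
        summary; ``dailies`` maps unit_id (and ``"reference"``) to the
        daily series used.  Deterministic given inputs.
    """
    ref_daily = reference_daily_series(reference, config)
    rows = []
    dailies: Dict[str, pd.DataFrame] = {"reference": ref_daily}
    for unit_id, records in units.items():
        conversion = config.conversions.get(unit_id, "fitted")
        daily, _ = unit_daily_series(records, conversion, config, unit_id)
        dailies[unit_id] = daily
        try:
            pairs = paired_days(ref_daily, daily)
        except DegenerateSeriesError as exc:
            logger.warning("unit %s: pairing failed (%s); skipped", unit_id, exc)
            continue
        for period in periods:
            subset = pairs[_period_mask(pairs, period)]
            if len(subset) < 3:
                logger.warning(
                    "unit %s period %s: only %d paired day(s); skipped",
                    unit_id,
                    period,
                    len(subset),
                )
                continue
            try:
                st = collocation_stats(subset)
            except DegenerateSeriesError as exc:
                logger.warning(
                    "unit %s period %s: degenerate (%s); skipped",
                    unit_id,
                    period,
                    exc,
                )
                continue
            rows.append(
                {
                    "site": config.site_id,
                    "unit": unit_id,
                    "conversion": conversion,
                    "period": period,
                    "n_days": st.n_days,
                    "r": st.r,
                    "r_se": st.r_se,
                    "rmse": st.rmse,
                    "rma_slope": st.rma_slope,
                    "ols_slope": st.ols_slope,
                    "ols_intercept": st.ols_intercept,
                    "mean_ref": st.mean_ref,
                    "mean_pa": st.mean_candidate,
                }
            )
    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    return report, dailies


def report_to_text(report: pd.DataFrame) -> str:
    """Human-readable fixed-width rendering of a collocation report."""
    if report.empty:
        return "(no comparable periods)\n"
    show = report.copy()
    for col in show.columns:
        if show[col].dtype.kind == "f":
            show[col] = show[col].map(lambda v: f"{v:.3f}")
    return show.to_string(index=False) + "\n"
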