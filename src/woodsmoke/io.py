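"""Readers, writers and configuration for the pipeline.

The canonical sensor CSV dialect has one row per raw interval record:

    timestamp_start, timestamp_end, cf1_a, cf1_b,
    n_gt_0p3_a, n_gt_0p5_a, n_gt_1_a, n_gt_2p5_a,
    n_gt_0p3_b, n_gt_0p5_b, n_gt_1_b, n_gt_2p5_b,
    rh [, cfa_a, cfa_b]

Vendor exports with other column names are mapped onto this dialect by
the caller (a ``column_map`` argument), not guessed.  Reference CSVs
carry ``hour_start, pm25 [, pm10, scattering]``.  All timestamps are
naive local standard time; tz-aware values are rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date
from importlib import resources
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence, Tuple

import pandas as pd
import yaml

from .conversions import CalibrationSource, DEFAULT_WOODSMOKE, SensorCalibration
from .errors import SchemaError, TimestampError
from .temporal import DEFAULT_MIN_HOURS, ExclusionWindow

logger = logging.getLogger(__name__)

__all__ = [
    "PA_MANDATORY_COLUMNS",
    "PipelineConfig",
    "load_calibrations",
    "packaged_calibrations",
    "read_pa_csv",
    "read_reference_csv",
    "write_pa_csv",
    "write_reference_csv",
]

PA_MANDATORY_COLUMNS = (
    "timestamp_start",
    "timestamp_end",
    "cf1_a",
    "cf1_b",
    "n_gt_0p3_a",
    "n_gt_0p5_a",
    "n_gt_1_a",
    "n_gt_2p5_a",
    "n_gt_0p3_b",
    "n_gt_0p5_b",
    "n_gt_1_b",
    "n_gt_2p5_b",
)
PA_OPTIONAL_COLUMNS = ("rh", "cfa_a", "cfa_b")

REFERENCE_MANDATORY_COLUMNS = ("hour_start", "pm25")
REFERENCE_OPTIONAL_COLUMNS = ("pm10", "scattering")


def _parse_calibration(unit_id: str, row: Mapping) -> SensorCalibration:
    return SensorCalibration(
        unit_id=unit_id,
        intercept=float(row["intercept"]),
        slope=float(row["slope"]),
        source=CalibrationSource(row.get("source", "fitted_2018")),
    )


def load_calibrations(path: Path | str) -> Dict[str, SensorCalibration]:
    """Load a unit→calibration table from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    table = raw.get("calibrations", raw) if isinstance(raw, dict) else None
    if not isinstance(table, dict):
        raise SchemaError(f"{path}: expected a 'calibrations' mapping")
    return {uid: _parse_calibration(uid, row) for uid, row in table.items()}


def packaged_calibrations() -> Dict[str, SensorCalibration]:
    """The calibration table shipped with the package (eight units from
    the 2018 Armidale collocation campaign)."""
    ref = resources.files("woodsmoke").joinpath("data/calibrations.yaml")
    with resources.as_file(ref) as path:
        return load_calibrations(path)


def calibration_for(
    unit_id: str, table: Mapping[str, SensorCalibration]
) -> SensorCalibration:
    """Look up a unit's calibration, falling back to the default
    woodsmoke conversion with a logged warning."""
    cal = table.get(unit_id)
    if cal is None:
        logger.warning(
            "no calibration for unit %s; using default woodsmoke conversion",
            unit_id,
        )
        cal = SensorCalibration(
            unit_id=unit_id,
            intercept=DEFAULT_WOODSMOKE.intercept,
            slope=DEFAULT_WOODSMOKE.slope,
            source=CalibrationSource.DEFAULT_WOODSMOKE,
        )
    return cal


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the end-to-end pipeline needs beyond the input files."""

    calibrations: Mapping[str, SensorCalibration] = field(default_factory=dict)
    #: Conversion per unit: one of fitted, default_woodsmoke, alt34, usepa.
    conversions: Mapping[str, str] = field(default_factory=dict)
    ad_abs_threshold: float = 10.0
    ad_frac_threshold: float = 0.5
    min_hours: int = DEFAULT_MIN_HOURS
    exclusion_windows: Tuple[ExclusionWindow, ...] = ()
    site_id: str = "site"

    def __post_init__(self) -> None:
        valid = {"fitted", "default_woodsmoke", "alt34", "usepa"}
        for unit, conv in self.conversions.items():
            if conv not in valid:
                raise SchemaError(
                    f"unknown conversion {conv!r} for unit {unit!r}; "
                    f"expected one of {sorted(valid)}"
                )
        if not 0 <= self.min_hours <= 24:
            raise SchemaError("min_hours must lie in [0, 24]")

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cals = {
            uid: _parse_calibration(uid, row)
            for uid, row in (raw.get("calibrations") or {}).items()
        }
        windows = tuple(
            ExclusionWindow(
                label=w["label"],
                start_date=date.fromisoformat(str(w["start_date"])),
                end_date=date.fromisoformat(str(w["end_date"])),
            )
            for w in (raw.get("exclusion_windows") or [])
        )
        qc = raw.get("qc") or {}
        return cls(
            calibrations=cals or packaged_calibrations(),
            conversions=raw.get("conversions") or {},
            ad_abs_threshold=float(qc.get("ad_abs_threshold", 10.0)),
            ad_frac_threshold=float(qc.get("ad_frac_threshold", 0.5)),
            min_hours=int(raw.get("min_hours", DEFAULT_MIN_HOURS)),
            exclusion_windows=windows,
            site_id=str(raw.get("site_id", "site")),
        )


def _read_csv(path: Path | str, mandatory: Sequence[str], optional: Sequence[str]):
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file is empty") from None
    missing = [c for c in mandatory if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    keep = [c for c in (*mandatory, *optional) if c in frame.columns]
    return frame[keep]


def read_pa_csv(
    path: Path | str,
    column_map: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Read raw sensor records in the canonical dialect.

    Malformed rows (unparseable timestamps, negative cf1, non-monotone
    cumulative counts) are skipped and counted in a single log message.
    ``column_map`` renames vendor columns onto the canonical names
    before validation.

    Returns the validated frame, time-sorted, with parsed timestamps.
    """
    if column_map:
        frame = pd.read_csv(path).rename(columns=dict(column_map))
        missing = [c for c in PA_MANDATORY_COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
        keep = [
            c
            for c in (*PA_MANDATORY_COLUMNS, *PA_OPTIONAL_COLUMNS)
            if c in frame.columns
        ]
        frame = frame[keep]
    else:
        frame = _read_csv(path, PA_MANDATORY_COLUMNS, PA_OPTIONAL_COLUMNS)

    n_raw = len(frame)
    for col in ("timestamp_start", "timestamp_end"):
        frame[col] = pd.to_datetime(frame[col], errors="coerce")
        if getattr(frame[col].dtype, "tz", None) is not None:
            raise TimestampError(
                f"{path}: {col} carries a timezone offset; supply naive "
                "local standard time"
            )
    numeric = [c for c in frame.columns if c not in ("timestamp_start", "timestamp_end")]
    frame[numeric] = frame[numeric].apply(pd.to_numeric, errors="coerce")

    ok = frame["timestamp_start"].notna() & frame["timestamp_end"].notna()
    ok &= frame["timestamp_end"] > frame["timestamp_start"]
    ok &= (frame["cf1_a"] >= 0) & (frame["cf1_b"] >= 0)
    for ch in ("a", "b"):
        a, b = frame[f"n_gt_0p3_{ch}"], frame[f"n_gt_0p5_{ch}"]
        c, d = frame[f"n_gt_1_{ch}"], frame[f"n_gt_2p5_{ch}"]
        ok &= (a >= b) & (b >= c) & (c >= d) & (d >= 0)

    dropped = int(n_raw - ok.sum())
    if dropped:
        logger.warning("%s: skipped %d malformed row(s) of %d", path, dropped, n_raw)
    out = frame.loc[ok].sort_values("timestamp_start").reset_index(drop=True)
    return out


def read_reference_csv(path: Path | str) -> pd.DataFrame:
    """Read hourly reference-station records.

    Negative PM2.5 (instrument noise around zero) is accepted; missing
    hours are simply absent rows.  An optional ``pm10`` column is parsed
    when present.
    """
    frame = _read_csv(path, REFERENCE_MANDATORY_COLUMNS, REFERENCE_OPTIONAL_COLUMNS)
    frame["hour_start"] = pd.to_datetime(frame["hour_start"], errors="coerce")
    if getattr(frame["hour_start"].dtype, "tz", None) is not None:
        raise TimestampError(
            f"{path}: hour_start carries a timezone offset; supply naive "
            "local standard time"
        )
    numeric = [c for c in frame.columns if c != "hour_start"]
    frame[numeric] = frame[numeric].apply(pd.to_numeric, errors="coerce")
    ok = frame["hour_start"].notna()
    dropped = int(len(frame) - ok.sum())
    if dropped:
        logger.warning("%s: skipped %d malformed row(s)", path, dropped)
    return frame.loc[ok].sort_values("hour_start").reset_index(drop=True)


def write_pa_csv(records: pd.DataFrame, path: Path | str) -> None:
    """Write sensor records in the canonical dialect."""
    records.to_csv(path, index=False)


def write_reference_csv(reference: pd.DataFrame, path: Path | str) -> None:
    """Write hourly reference records."""
    reference.to_csv(path, index=False)
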