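"""Synthetic collocated-site generator with woodsmoke structure.

Generates a minute-resolution "true" PM2.5 series with the features a
woodsmoke-dominated town exhibits — low daytime baseline, a smooth
evening peak from wood-heater lighting, strong winter-high seasonality,
and heavy-tailed day-to-day variation — plus instrument observations of
that truth:

* dual-laser optical units reporting 2-min cf1 per channel and
  size-channel particle counts constructed so the count-based conversion
  recovers a target mass with a prescribed sub-micron fraction, with
  rare one-channel spikes (the failure mode the A/B QC rule targets);
* an FDMS-TEOM reference whose hourly value samples only the five 6-min
  measurement windows of each 12-min filter-dynamics cycle, plus
  Gaussian noise (negative readings can and do occur);
* an integrating nephelometer consistent with the woodsmoke scattering
  relationship.

Seasons follow the southern hemisphere: the woodsmoke peak is centred on
1 July, the coarse-dust peak on 1 January.  All randomness flows from
one seed; each instrument draws from its own child stream, so adding an
instrument never perturbs the others.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Mapping, Tuple

import numpy as np
import pandas as pd

from .conversions import (
    ALT_SCALE,
    ALT_WEIGHTS,
    DEFAULT_WOODSMOKE,
    NEPH_INTERCEPT,
    NEPH_SLOPE,
    SensorCalibration,
)
from .errors import InvalidInputError

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "SiteBundle",
    "simulate_truth",
    "simulate_pa_unit",
    "simulate_teom_fdms",
    "simulate_nephelometer",
    "simulate_site",
]

MINUTES_PER_DAY = 1440
#: Day of year of the woodsmoke (winter) peak, southern hemisphere.
WINTER_PEAK_DOY = 182.0

# Fixed child-stream indices; appending instruments never reseeds others.
_STREAM_TRUTH = 0
_STREAM_TEOM = 1
_STREAM_NEPH = 2
_STREAM_UNIT_BASE = 10


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic collocated site.

    Defaults describe a woodsmoke-dominated NSW-tablelands-like town:
    a ~3 µg/m³ non-smoke baseline, winter evening peaks pushing daily
    means into the teens of µg/m³, near-total sub-micron mass in winter,
    and instrument noise levels typical of the hardware emulated.
    """

    seed: int
    n_days: int = 365
    start: str = "2022-01-01"
    #: Non-smoke background PM2.5, µg/m³.
    baseline_pm: float = 3.0
    #: Amplitude of the evening woodsmoke peak at seasonal maximum, µg/m³.
    evening_peak_pm: float = 20.0
    #: Relative winter/summer modulation of the evening peak, in [0, 1).
    seasonal_amplitude: float = 0.8
    #: Local hour of the evening maximum and Gaussian kernel width (hours).
    diurnal_peak_hour: float = 21.0
    diurnal_width_hours: float = 3.0
    #: Lognormal sigma of the day-to-day (weather) factor.
    day_factor_sigma: float = 0.4
    #: Lognormal sigma of minute-scale multiplicative noise.
    minute_sigma: float = 0.2
    #: Sub-micron ALT mass fraction at the winter and summer extremes.
    p1_winter: float = 0.95
    p1_summer: float = 0.75
    #: Per-record multiplicative noise CV of each laser channel.
    sensor_noise_cv: float = 0.05
    units: Tuple[str, ...] = ("PA1",)
    per_unit_calibrations: Mapping[str, SensorCalibration] = field(
        default_factory=dict
    )
    #: One-channel spurious-spike events per unit per year, and their size.
    spike_rate: float = 1.25
    spike_magnitude: float = 50.0
    #: Gaussian noise SD of the hourly reference value, µg/m³
    #: (manufacturer-quoted 1-h precision of an FDMS TEOM).
    teom_noise_sd: float = 1.5
    teom_duty_cycle: bool = True
    #: First minute of each 6-min FDMS measurement window within the hour.
    fdms_sample_phase: Tuple[int, ...] = (0, 12, 24, 36, 48)
    fdms_window_minutes: int = 6
    #: Mean coarse (PM10 − PM2.5) mass and its summer-high modulation.
    coarse_pm_mean: float = 4.0
    coarse_seasonal_amplitude: float = 0.3
    #: Noise SD of the nephelometer in reported scattering units.
    neph_noise_sd: float = 0.01
    #: Share of sub-micron ALT mass placed in the 0.3-0.5 µm bin.
    n1_mass_share: float = 0.4

    def __post_init__(self) -> None:
        if self.n_days <= 0:
            raise InvalidInputError("n_days must be positive")
        for name in (
            "baseline_pm",
            "evening_peak_pm",
            "day_factor_sigma",
            "minute_sigma",
            "sensor_noise_cv",
            "spike_rate",
            "teom_noise_sd",
            "neph_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be non-negative")
        for name in ("p1_winter", "p1_summer", "n1_mass_share"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise InvalidInputError(f"{name} must lie in (0, 1), got {v}")
        if not 0 <= self.seasonal_amplitude < 1:
            raise InvalidInputError("seasonal_amplitude must lie in [0, 1)")


@dataclass(frozen=True)
class SiteBundle:
    """Everything the pipeline consumes for one simulated site."""

    truth: pd.DataFrame
    units: Dict[str, pd.DataFrame]
    spike_logs: Dict[str, pd.DataFrame]
    reference: pd.DataFrame
    nephelometer: pd.DataFrame
    config: SimulationConfig


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def _seasonal_factor(doy: np.ndarray, amplitude: float, peak_doy: float) -> np.ndarray:
    return 1.0 + amplitude * np.cos(2.0 * np.pi * (doy - peak_doy) / 365.25)


def simulate_truth(config: SimulationConfig) -> pd.DataFrame:
    """Minute-resolution true PM2.5 and true sub-micron fraction.

    Returns a frame indexed by naive local-standard-time minutes with
    columns ``pm_true`` (µg/m³) and ``p1_true``.  Deterministic given
    the seed.
    """
    rng = _rng(config, _STREAM_TRUTH)
    idx = pd.date_range(
        config.start, periods=config.n_days * MINUTES_PER_DAY, freq="min"
    )
    hod = idx.hour.to_numpy() + idx.minute.to_numpy() / 60.0
    doy = idx.dayofyear.to_numpy().astype(float)

    dh = np.abs(hod - config.diurnal_peak_hour)
    dh = np.minimum(dh, 24.0 - dh)  # circular distance in hours
    kernel = np.exp(-0.5 * (dh / config.diurnal_width_hours) ** 2)
    seasonal = _seasonal_factor(doy, config.seasonal_amplitude, WINTER_PEAK_DOY)

    day_index = np.arange(len(idx)) // MINUTES_PER_DAY
    if config.day_factor_sigma > 0:
        s = config.day_factor_sigma
        day_factor = np.exp(rng.normal(-0.5 * s * s, s, size=config.n_days))
    else:
        day_factor = np.ones(config.n_days)
    if config.minute_sigma > 0:
        s = config.minute_sigma
        minute_factor = np.exp(rng.normal(-0.5 * s * s, s, size=len(idx)))
    else:
        minute_factor = np.ones(len(idx))

    pm = (
        (config.baseline_pm + config.evening_peak_pm * kernel * seasonal)
        * day_factor[day_index]
        * minute_factor
    )

    winter_weight = 0.5 * (1.0 + np.cos(2.0 * np.pi * (doy - WINTER_PEAK_DOY) / 365.25))
    p1 = config.p1_summer + (config.p1_winter - config.p1_summer) * winter_weight

    return pd.DataFrame({"pm_true": pm, "p1_true": p1}, index=idx)


def _counts_from_mass(mass: np.ndarray, p1: np.ndarray, n1_share: float):
    """Solve cumulative size-channel counts so the count conversion hits
    ``mass`` with sub-micron fraction ``p1`` exactly (coarsest bin empty
    above 2.5 µm)."""
    w1, w2, w3 = (ALT_SCALE * w for w in ALT_WEIGHTS)
    n1 = p1 * mass * n1_share / w1
    n2 = p1 * mass * (1.0 - n1_share) / w2
    n3 = (1.0 - p1) * mass / w3
    n_gt_2p5 = np.zeros_like(n3)
    n_gt_1 = n3
    n_gt_0p5 = n3 + n2
    n_gt_0p3 = n3 + n2 + n1
    return n_gt_0p3, n_gt_0p5, n_gt_1, n_gt_2p5


def simulate_pa_unit(
    truth: pd.DataFrame,
    config: SimulationConfig,
    unit_id: str,
    unit_index: int = 0,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Observe the truth with one dual-laser unit at 2-min cadence.

    Each channel sees the truth through the unit's calibration inverted
    (``cf1 = (pm − intercept)/slope``) with multiplicative Gaussian noise
    of CV ``sensor_noise_cv``, floored at zero, so applying the
    calibration recovers the truth in expectation.  Size-channel counts
    are solved so the count-based conversion equals the channel's noisy
    mass with the true sub-micron fraction.  One-channel spurious spikes
    (Poisson-timed, affecting a random channel for a whole hour) are
    injected and logged.

    Returns
    -------
    (records, spike_log):
        ``records`` in the canonical sensor CSV schema; ``spike_log``
        with columns ``hour``, ``channel``, ``magnitude``.
    """
    cal = config.per_unit_calibrations.get(unit_id)
    if cal is None:
        logger.warning(
            "unit %s has no calibration; using the default woodsmoke conversion",
            unit_id,
        )
        cal = DEFAULT_WOODSMOKE
    rng = _rng(config, _STREAM_UNIT_BASE + unit_index)

    # 2-min means of the minute truth.
    n2 = len(truth) // 2
    pm2 = truth["pm_true"].to_numpy()[: 2 * n2].reshape(n2, 2).mean(axis=1)
    p12 = truth["p1_true"].to_numpy()[: 2 * n2].reshape(n2, 2).mean(axis=1)
    t_start = truth.index[0::2][:n2]
    t_end = t_start + pd.Timedelta(minutes=2)

    # Poisson-timed one-channel spikes, one whole hour each.
    n_hours = config.n_days * 24
    n_spikes = rng.poisson(config.spike_rate * config.n_days / 365.0)
    spike_hours = np.sort(rng.choice(n_hours, size=min(n_spikes, n_hours), replace=False))
    spike_channels = rng.choice(["a", "b"], size=len(spike_hours))
    spike_add = {"a": np.zeros(n2), "b": np.zeros(n2)}
    rec_hour = np.arange(n2) * 2 // 60
    for h, ch in zip(spike_hours, spike_channels):
        spike_add[ch][rec_hour == h] += config.spike_magnitude
    spike_log = pd.DataFrame(
        {
            "hour": truth.index[0].normalize() + pd.to_timedelta(spike_hours, unit="h"),
            "channel": spike_channels,
            "magnitude": config.spike_magnitude,
        }
    )

    cols: Dict[str, np.ndarray] = {}
    for ch in ("a", "b"):
        mass = pm2 + spike_add[ch]
        if config.sensor_noise_cv > 0:
            mass = mass * (1.0 + rng.normal(0.0, config.sensor_noise_cv, size=n2))
        mass = np.clip(mass, 0.0, None)
        cf1 = np.clip((mass - cal.intercept) / cal.slope, 0.0, None)
        counts = _counts_from_mass(mass, p12, config.n1_mass_share)
        cols[f"cf1_{ch}"] = cf1
        cols[f"cfa_{ch}"] = cf1  # carried for round-trip I/O, never used
        for name, v in zip(("n_gt_0p3", "n_gt_0p5", "n_gt_1", "n_gt_2p5"), counts):
            cols[f"{name}_{ch}"] = v

    # Relative humidity: early-morning maximum plus noise, clipped.
    hod = t_start.hour.to_numpy() + t_start.minute.to_numpy() / 60.0
    rh = 60.0 + 25.0 * np.cos(2.0 * np.pi * (hod - 5.0) / 24.0)
    rh = np.clip(rh + rng.normal(0.0, 3.0, size=n2), 5.0, 100.0)

    records = pd.DataFrame(
        {"timestamp_start": t_start, "timestamp_end": t_end, **cols, "rh": rh}
    )
    return records, spike_log


def _hourly_index(truth: pd.DataFrame) -> pd.DatetimeIndex:
    return pd.date_range(truth.index[0], truth.index[-1], freq="h")


def simulate_teom_fdms(
    truth: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Hourly reference records from an FDMS-TEOM observing the truth.

    With the duty cycle on, each hourly PM2.5 is the mean of the truth
    over the five 6-min measurement windows only — any within-hour
    variation outside those windows becomes sampling error.  Gaussian
    instrument noise is added and negative values are retained.  PM10 is
    PM2.5 truth plus a seasonally varying coarse mass (summer-high).

    Returns a frame with columns ``hour_start``, ``pm25``, ``pm10``.
    """
    rng = _rng(config, _STREAM_TEOM)
    minute_of_hour = truth.index.minute.to_numpy()
    in_window = np.zeros(len(truth), dtype=bool)
    for start in config.fdms_sample_phase:
        in_window |= (minute_of_hour >= start) & (
            minute_of_hour < start + config.fdms_window_minutes
        )

    pm = truth["pm_true"]
    hour = truth.index.floor("h")
    if config.teom_duty_cycle:
        sampled = pm.where(pd.Series(in_window, index=truth.index))
        hourly = sampled.groupby(hour).mean()
    else:
        hourly = pm.groupby(hour).mean()

    noise = rng.normal(0.0, config.teom_noise_sd, size=len(hourly))
    pm25 = hourly.to_numpy() + noise

    doy = hourly.index.dayofyear.to_numpy().astype(float)
    summer_peak_doy = WINTER_PEAK_DOY - 365.25 / 2.0
    coarse = config.coarse_pm_mean * _seasonal_factor(
        doy, config.coarse_seasonal_amplitude, summer_peak_doy
    )
    # PM10 = full-hour fine truth + coarse mass + its own instrument noise.
    pm10 = pm.groupby(hour).mean().to_numpy() + coarse + rng.normal(
        0.0, config.teom_noise_sd, size=len(hourly)
    )

    return pd.DataFrame(
        {"hour_start": hourly.index, "pm25": pm25, "pm10": pm10}
    ).reset_index(drop=True)


def simulate_nephelometer(
    truth: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Hourly scattering consistent with the woodsmoke relationship.

    Inverts ``pm = 0.53 + 22.186 × scattering`` on the full-hour truth
    mean and adds Gaussian noise in scattering units; negative scattering
    (clean-air noise) is retained.
    """
    rng = _rng(config, _STREAM_NEPH)
    hour = truth.index.floor("h")
    hourly = truth["pm_true"].groupby(hour).mean()
    scattering = (hourly.to_numpy() - NEPH_INTERCEPT) / NEPH_SLOPE
    scattering = scattering + rng.normal(0.0, config.neph_noise_sd, size=len(hourly))
    return pd.DataFrame(
        {"hour_start": hourly.index, "scattering": scattering}
    ).reset_index(drop=True)


def simulate_site(config: SimulationConfig) -> SiteBundle:
    """Simulate a full collocated site: truth, units, reference, neph."""
    truth = simulate_truth(config)
    units: Dict[str, pd.DataFrame] = {}
    spikes: Dict[str, pd.DataFrame] = {}
    for i, unit_id in enumerate(config.units):
        records, spike_log = simulate_pa_unit(truth, config, unit_id, unit_index=i)
        units[unit_id] = records
        spikes[unit_id] = spike_log
    reference = simulate_teom_fdms(truth, config)
    neph = simulate_nephelometer(truth, config)
    return SiteBundle(
        truth=truth,
        units=units,
        spike_logs=spikes,
        reference=reference,
        nephelometer=neph,
        config=config,
    )
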