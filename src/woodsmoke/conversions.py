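"""Conversions from raw optical-sensor output to PM2.5 mass concentration.

Plantower-based units (e.g. PurpleAir) report two kinds of raw output per
laser channel: proprietary mass estimates (``cf1``, assuming metal-particle
density, and ``cfa``, assuming average atmospheric density) and cumulative
particle counts in size channels (>0.3, >0.5, >1, >2.5 µm).  This module
implements the conversions used when evaluating such sensors against
reference monitors at woodsmoke-dominated sites:

* per-unit linear calibration of cf1 against a collocated TEOM
  (``reference = intercept + slope × cf1``);
* the ALT-3.4 conversion, which builds PM2.5 directly from differenced
  size-channel counts with three fixed mass weights;
* the sub-micron mass fraction P1, a diagnostic for coarse-particle bias;
* the nephelometer woodsmoke relationship; and
* the US-EPA relative-humidity correction of cf1.

All numeric functions accept scalars or numpy arrays and are vectorised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np

from .errors import InvalidCountsError, InvalidInputError

logger = logging.getLogger(__name__)

__all__ = [
    "ALT_SCALE",
    "ALT_WEIGHTS",
    "CalibrationSource",
    "DEFAULT_WOODSMOKE",
    "SensorCalibration",
    "SizeChannelCounts",
    "alt34",
    "alt34_from_channels",
    "apply_linear_calibration",
    "neph_to_pm25",
    "p1_fraction",
    "p1_from_channels",
    "sphere_mass_ratio",
    "usepa_conversion",
]

# ALT-3.4 conversion: empirical scale times per-channel mass weights
# (volume-equivalent water-sphere mass per counted particle) for the
# 0.3-0.5, 0.5-1 and 1-2.5 µm channels.
ALT_SCALE = 3.4
ALT_WEIGHTS = (0.00030418, 0.0018512, 0.02069706)

# Woodsmoke nephelometer relationship, bound to the Aurora 1000G
# integrating nephelometer's reported scattering value.
NEPH_INTERCEPT = 0.53
NEPH_SLOPE = 22.186

# US-EPA nationwide PurpleAir correction: pm25 = a*cf1 + b*rh + c.
USEPA_CF1_COEF = 0.524
USEPA_RH_COEF = -0.0862
USEPA_INTERCEPT = 5.75


class CalibrationSource(str, Enum):
    """Provenance of a per-unit calibration."""

    FITTED_2018 = "fitted_2018"
    DEFAULT_WOODSMOKE = "default_woodsmoke"


@dataclass(frozen=True)
class SensorCalibration:
    """Linear calibration of one unit's cf1 output against a reference.

    The fitted relationship is ``reference = intercept + slope * cf1``.

    Parameters
    ----------
    unit_id:
        Identifier of the physical sensor unit.
    intercept:
        Calibration intercept, µg/m³.
    slope:
        Calibration slope, dimensionless; must be positive.
    source:
        Whether the pair was fitted from collocation data or is the
        default woodsmoke conversion used for uncalibrated units.
    """

    unit_id: str
    intercept: float
    slope: float
    source: CalibrationSource = CalibrationSource.FITTED_2018

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise InvalidInputError(
                f"calibration slope must be positive, got {self.slope!r} "
                f"for unit {self.unit_id!r}"
            )


#: Default woodsmoke conversion applied to units never collocated.
DEFAULT_WOODSMOKE = SensorCalibration(
    unit_id="default",
    intercept=0.53,
    slope=0.55,
    source=CalibrationSource.DEFAULT_WOODSMOKE,
)


@dataclass(frozen=True)
class SizeChannelCounts:
    """Cumulative particle counts per unit sampled volume.

    Fields are the counts of particles larger than 0.3, 0.5, 1 and
    2.5 µm.  Because the channels are cumulative the counts must be
    monotone non-increasing; averaging records yields fractional counts,
    so reals are accepted.  Fields may be scalars or numpy arrays of a
    common shape.
    """

    n_gt_0p3: float | np.ndarray
    n_gt_0p5: float | np.ndarray
    n_gt_1: float | np.ndarray
    n_gt_2p5: float | np.ndarray

    def __post_init__(self) -> None:
        a, b, c, d = (np.asarray(x, dtype=float) for x in self.as_tuple())
        ok = (a >= b) & (b >= c) & (c >= d) & (d >= 0)
        if not np.all(ok):
            raise InvalidCountsError(
                "cumulative size-channel counts must satisfy "
                "n>0.3 ≥ n>0.5 ≥ n>1 ≥ n>2.5 ≥ 0; got "
                f"({self.n_gt_0p3!r}, {self.n_gt_0p5!r}, "
                f"{self.n_gt_1!r}, {self.n_gt_2p5!r})"
            )

    def as_tuple(self):
        return (self.n_gt_0p3, self.n_gt_0p5, self.n_gt_1, self.n_gt_2p5)

    def differenced(self):
        """Counts per exclusive size bin (0.3-0.5, 0.5-1, 1-2.5 µm)."""
        a, b, c, d = (np.asarray(x, dtype=float) for x in self.as_tuple())
        return a - b, b - c, c - d


@dataclass(frozen=True)
class SensorRecord:
    """One timestamped raw observation from a dual-laser optical unit.

    ``cfa`` values are carried for round-trip I/O but are never used in
    any computation; all conversions operate on cf1 or on the counts.
    """

    timestamp_start: "np.datetime64 | object"
    timestamp_end: "np.datetime64 | object"
    cf1_a: float
    cf1_b: float
    counts_a: SizeChannelCounts
    counts_b: SizeChannelCounts
    rh: Optional[float] = None
    cfa_a: Optional[float] = None
    cfa_b: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.timestamp_end > self.timestamp_start:
            raise InvalidInputError(
                f"record interval must have positive length: "
                f"{self.timestamp_start} .. {self.timestamp_end}"
            )
        for name in ("cf1_a", "cf1_b"):
            v = getattr(self, name)
            if v < 0:
                raise InvalidInputError(f"{name} must be non-negative, got {v}")


def apply_linear_calibration(cf1, cal: SensorCalibration):
    """Convert raw cf1 mass to calibrated PM2.5 via ``intercept + slope*cf1``.

    Parameters
    ----------
    cf1:
        Raw cf1 output, µg/m³; scalar or array, all values ≥ 0.
    cal:
        The unit's calibration.

    Returns
    -------
    Calibrated PM2.5 in µg/m³, same shape as ``cf1``.
    """
    x = np.asarray(cf1, dtype=float)
    if np.any(x < 0):
        bad = np.atleast_1d(x)[np.atleast_1d(x < 0)]
        raise InvalidInputError(
            f"cf1 must be non-negative for unit {cal.unit_id!r}; "
            f"offending value(s): {bad[:5].tolist()}"
        )
    out = cal.intercept + cal.slope * x
    return out.item() if np.isscalar(cf1) else out


def alt34_from_channels(n_gt_0p3, n_gt_0p5, n_gt_1, n_gt_2p5):
    """ALT-3.4 PM2.5 from the four cumulative count channels (vectorised)."""
    return alt34(SizeChannelCounts(n_gt_0p3, n_gt_0p5, n_gt_1, n_gt_2p5))


def alt34(counts: SizeChannelCounts):
    """PM2.5 mass from differenced particle counts (ALT-3.4 conversion).

    Each exclusive size bin's count is multiplied by the mass of a
    volume-equivalent water sphere and an overall empirical scale of 3.4:

        pm25 = 3.4 × (0.00030418·N1 + 0.0018512·N2 + 0.02069706·N3)

    with N1, N2, N3 the counts in the 0.3-0.5, 0.5-1 and 1-2.5 µm bins.
    The result is non-negative for any valid (monotone) count vector and
    is linear in the counts.
    """
    n1, n2, n3 = counts.differenced()
    w1, w2, w3 = ALT_WEIGHTS
    out = ALT_SCALE * (w1 * n1 + w2 * n2 + w3 * n3)
    return out.item() if out.ndim == 0 else out


def p1_fraction(counts: SizeChannelCounts):
    """Fraction of ALT-3.4 mass contributed by particles below 1 µm.

        P1 = (W_0.5 + W_1) / (W_0.5 + W_1 + W_2.5)

    Used as a source diagnostic: woodsmoke aerosols sit near 1, dusty
    aerosols lower.  Where the total ALT-3.4 mass is zero the fraction is
    undefined and NaN is returned; callers must treat NaN as missing.
    """
    n1, n2, n3 = counts.differenced()
    w1, w2, w3 = ALT_WEIGHTS
    fine = w1 * n1 + w2 * n2
    total = fine + w3 * n3
    total = np.asarray(total, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, np.asarray(fine, dtype=float) / total, np.nan)
    return frac.item() if frac.ndim == 0 else frac


def p1_from_channels(n_gt_0p3, n_gt_0p5, n_gt_1, n_gt_2p5):
    """Sub-micron mass fraction from the four cumulative channels."""
    return p1_fraction(SizeChannelCounts(n_gt_0p3, n_gt_0p5, n_gt_1, n_gt_2p5))


def neph_to_pm25(scattering):
    """Woodsmoke PM2.5 from integrating-nephelometer scattering.

        pm25 = 0.53 + 22.186 × scattering

    The coefficient is bound to the scattering value reported by the
    Aurora 1000G nephelometer; negative scattering (instrument noise) is
    allowed and maps to values below the intercept.
    """
    s = np.asarray(scattering, dtype=float)
    out = NEPH_INTERCEPT + NEPH_SLOPE * s
    return out.item() if np.isscalar(scattering) else out


def usepa_conversion(cf1, rh):
    """US-EPA nationwide PurpleAir correction using relative humidity.

        pm25 = 0.524 × cf1 − 0.0862 × RH + 5.75

    At cf1 = 0 the two trailing terms form an RH-dependent intercept:
    −2.87 µg/m³ at 100% RH, zero near 66.7% RH, +2.91 µg/m³ at 33% RH.

    Parameters
    ----------
    cf1:
        Raw cf1 mass, µg/m³.
    rh:
        Relative humidity, percent in [0, 100].
    """
    r = np.asarray(rh, dtype=float)
    if np.any((r < 0) | (r > 100)):
        bad = np.atleast_1d(r)[np.atleast_1d((r < 0) | (r > 100))]
        raise InvalidInputError(
            f"relative humidity must lie in [0, 100] percent; "
            f"offending value(s): {bad[:5].tolist()}"
        )
    x = np.asarray(cf1, dtype=float)
    out = USEPA_CF1_COEF * x + USEPA_RH_COEF * r + USEPA_INTERCEPT
    return out.item() if np.isscalar(cf1) and np.isscalar(rh) else out


def sphere_mass_ratio(diameter_large: float, diameter_small: float) -> float:
    """Mass ratio of two spheres of equal density, (d_large/d_small)³.

    A 2.5 µm particle weighs ~16× a 1 µm particle; when aerosol mass is
    skewed coarse, conversions tuned to combustion size distributions
    underestimate PM2.5.  This helper quantifies that leverage.
    """
    if diameter_small <= 0 or diameter_large <= 0:
        raise InvalidInputError("diameters must be positive")
    return (diameter_large / diameter_small) ** 3
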