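# Methods

This note documents the models, conventions and numerical choices
behind the `woodsmoke` pipeline, and what the synthetic study
conditions do and do not establish about real deployments.

## Conversions

Four routes turn raw dual-laser sensor output into PM2.5 mass:

1. **Linear calibration** `pm = intercept + slope·cf1` against a
   collocated reference. The packaged table holds eight units
   (intercepts 0.53–1.66 µg/m³, slopes 0.510–0.596) from a 2018
   collocation campaign; units without a fitted pair fall back to the
   default woodsmoke conversion (0.53, 0.55) with a logged warning.
   Negative cf1 is a hard input error — the vendor algorithm never
   reports one, so a negative value indicates a corrupted record.
2. **ALT-3.4** computes mass directly from differenced cumulative size
   channels with fixed per-bin weights (volume-equivalent water-sphere
   mass) times an empirical 3.4. It is linear and non-negative on any
   monotone count vector; monotonicity violations raise rather than
   clip, since they indicate corrupted counts, not physics. Counts are
   accepted as reals because averaged records legitimately carry
   fractional counts. The module is agnostic about the count
   normalisation volume (the vendor convention is per 0.1 L); the
   weights absorb it.
3. **Sub-micron fraction P1** = fine-bin mass share of the ALT-3.4
   total. Undefined at zero total mass; returned as NaN so downstream
   aggregation treats it as missing rather than aborting an entire
   file.
4. **Nephelometer and US-EPA conversions** are fixed published linear
   forms. The scattering coefficient 22.186 is bound to the reported
   output of the Aurora 1000G integrating nephelometer; the input is
   treated as "instrument-reported scattering value" and no unit
   conversion is attempted. The US-EPA form validates RH to [0, 100]%;
   its RH-dependent intercept at cf1 = 0 decreases from +5.75 at 0% RH
   through zero near 66.7% to −2.87 at 100%.

The `cfa` channel is parsed and round-tripped but never used in any
computation; only cf1 and the counts enter the conversions.

## A/B discordance QC

With L and H the low and high hourly channel means, AD = H − L and
m = (L + H)/2, an hour is discordant when `AD > 10 µg/m³` **and**
`AD > 0.5·m`. Discordant hours are averaged with
`wt_low = 0.5·(1 + min(1, AD/m))`, which rises continuously from 0.5
and saturates at 1 exactly when AD = m, at which point the high channel
is discarded. Reading "50% of the mean" as `AD > 0.5·m` is consistent
with that saturation point being "the difference exceeds their mean".
Non-discordant hours take the plain two-channel mean. Hours with only
one reporting channel are retained with `wt_low = 1` and flagged —
dropping them would sacrifice daily completeness to a Wi-Fi hiccup —
but they are excluded from the discordance *rate*, which counts only
threshold trips. Division by m is guarded although unreachable: with
non-negative channels, AD > 10 forces m > 5. Both thresholds are
configurable; the defaults are the deployed values.

## Temporal conventions

All timestamps are naive local standard time; inputs declaring a UTC
offset are rejected rather than converted, because reference networks
in the emulated region ignore daylight saving. Records are assigned to
the hour containing their interval midpoint (a 23:58:59–00:00:59 record
belongs to 23:00). Daily means require ≥ 23 of 24 hourly values —
deliberately stricter than the common 18-hour rule, because a
woodsmoke evening missing from an 18-hour day shifts the daily mean
substantially. Negative hourly (and even daily) reference values are
legitimate instrument noise around zero and are retained. Exclusion
windows are date-inclusive on both ends; the packaged defaults exclude
a summer bushfire episode (2019-11-01 to 2020-01-31) and a span of
questionable reference data (2022-01-01 to 2022-05-31), both
user-editable.

## Collocation statistics

The orientation is fixed: reference on candidate,
`ref = slope·cand + intercept`. RMSE is √mean((cand − ref)²) on the raw
pairs. The RMA slope is sign(r)·sd(ref)/sd(cand) — symmetric in the two
error-bearing instruments, and satisfying the reciprocal identity
`rma(ref, cand)·rma(cand, ref) = 1`; OLS attenuates relative to it by a
factor |r|. The correlation SE uses the large-sample form
`√((1 − r²)/(n − 2))`; no exact small-sample form is attempted, and at
least 3 pairs with non-zero variance are required. Residual diagnostics
correlate daily (ref − cand) with P1 and with the reference
PM2.5/PM10 ratio; a negative ratio correlation is the signature of
coarse-dust underestimation by combustion-tuned conversions (a 2.5 µm
sphere weighs (2.5/1)³ ≈ 16× a 1 µm sphere, so coarse-skewed aerosols
defeat size distributions assumed by the optical conversions).

## Synthetic study conditions

The generator produces minute-scale truth
`pm(t) = (baseline + peak·K(hod)·S(doy)) · D(day) · M(minute)` with a
wrapped-Gaussian evening kernel K (peak 21:00, width 3 h), a winter-high
sinusoid S (peak 1 July, relative amplitude 0.8 — southern-hemisphere
seasons), a lognormal day factor D (σ = 0.4, the dominant source of
day-to-day variation weather produces) and lognormal minute noise M
(σ = 0.2). Defaults (baseline 3 µg/m³, evening peak 20 µg/m³) give
winter daily means in the mid-teens and summer means of a few µg/m³,
the regime the pipeline targets. True P1 interpolates sinusoidally
between 0.95 (winter, nearly pure combustion aerosol) and 0.75
(summer, more dust).

Sensors observe the truth through the inverted calibration with 5%
multiplicative channel noise, floored at zero. Size-channel counts are
solved exactly from the channel's (noisy) mass and the true P1, with
40% of sub-micron mass in the 0.3–0.5 µm bin and nothing above 2.5 µm —
a three-unknown linear system, so the count conversion reproduces the
target mass and fraction to rounding error. One-channel spikes
(default 1.25 events/unit/year, the observed field rate; +50 µg/m³ for
one full hour on one random channel) reproduce the transient fault the
QC rule exists for, and are logged so tests can verify detection.

The reference instrument samples the truth only during the five 6-min
FDMS measurement windows per hour (phase configurable, default minutes
0–5, 12–17, …) and adds Gaussian noise of SD 1.5 µg/m³, the
manufacturer-quoted 1-h precision class of an FDMS TEOM; negative
hourly values occur near zero and are kept. PM10 adds a summer-high
coarse mass (mean 4 µg/m³, relative amplitude 0.3). All streams draw
from per-instrument child seeds of one root seed, so adding an
instrument never perturbs another's realisation.

**What the synthetic conditions do not emulate:** calibration drift,
humidity-dependent optical bias (RH is generated but does not distort
the sensors), aerosol composition changes within a day, correlated
multi-hour sensor faults, data gaps from power/Wi-Fi loss, and the
vendor cf1 zero-threshold at very low concentrations. Passing tests
therefore demonstrate that the *pipeline arithmetic* is right and that
recovery works under honest noise — not that any physical sensor is
accurate.

## Calibration recovery

Calibrations are fitted on *hourly* collocation pairs (reference hourly
value against hourly-mean raw cf1), the natural cadence at which
reference data are reported; over one simulated winter (92 days,
~2200 hours) the injected slope and intercept are recovered to a few
percent. Daily pairs (n ≈ 92) carry an intercept standard error of the
same order as 5% of a ~1.7 µg/m³ intercept and are not used for
fitting.

## Numerical and design choices

* Clipping: simulated cf1 and the US-EPA conversion inside the pipeline
  are floored at 0 (a mass channel cannot be negative); reference
  values are *not* floored.
* Problem sizes in the test suite (10–92 simulated days, single site)
  keep the full suite in seconds while leaving every estimator's
  sampling error small relative to its test tolerance.
* The discordance rate is scaled to a nominal 8760-hour year.
* The report renders floats at 3 decimals; the underlying CSV keeps
  full precision and is byte-deterministic for identical inputs.

## Known limitations

* The correlation SE printed per row can disagree with small-sample
  exact methods at small n; it is a descriptive companion to r, not an
  inferential tool.
* The bushfire-range quadratic correction (cf1 > 343 µg/m³) and the
  dust correction keyed to the 0.3 µm/5 µm count ratio are out of
  scope; the pipeline's conversions are not validated above the
  woodsmoke concentration range.
* No live vendor-API ingestion; only the documented canonical CSV
  dialect plus a caller-supplied column mapping.
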