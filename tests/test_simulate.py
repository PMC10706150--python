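import numpy as np
import pandas as pd
import pytest

from woodsmoke.conversions import apply_linear_calibration, p1_from_channels
from woodsmoke.qc import ChannelPairHour, fuse_channels
from woodsmoke.simulate import (
    SimulationConfig,
    simulate_pa_unit,
    simulate_site,
    simulate_teom_fdms,
    simulate_truth,
)
from woodsmoke.temporal import records_to_hourly


def noiseless(seed=0, **overrides):
    base = dict(
        seed=seed,
        n_days=4,
        start="2022-06-01",
        day_factor_sigma=0.0,
        minute_sigma=0.0,
        sensor_noise_cv=0.0,
        spike_rate=0.0,
        teom_noise_sd=0.0,
        teom_duty_cycle=False,
        neph_noise_sd=0.0,
    )
    base.update(overrides)
    return SimulationConfig(**base)


class TestSimulateTruth:
    def test_no_peak_no_noise_is_flat_baseline(self):
        truth = simulate_truth(noiseless(evening_peak_pm=0.0))
        assert np.allclose(truth["pm_true"], 3.0)

    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(seed=123, n_days=2)
        pd.testing.assert_frame_equal(simulate_truth(cfg), simulate_truth(cfg))

    def test_different_seeds_differ(self):
        a = simulate_truth(SimulationConfig(seed=1, n_days=2))
        b = simulate_truth(SimulationConfig(seed=2, n_days=2))
        assert not np.allclose(a["pm_true"], b["pm_true"])

    def test_winter_exceeds_summer(self):
        cfg = SimulationConfig(seed=4, n_days=365, start="2022-01-01")
        truth = simulate_truth(cfg)
        daily = truth["pm_true"].resample("D").mean()
        winter = daily[daily.index.month.isin([6, 7, 8])].mean()
        summer = daily[daily.index.month.isin([12, 1, 2])].mean()
        assert winter > summer

    def test_p1_higher_in_winter(self):
        truth = simulate_truth(SimulationConfig(seed=4, n_days=365))
        p1 = truth["p1_true"].resample("D").mean()
        assert p1[p1.index.month == 7].mean() > p1[p1.index.month == 1].mean()


class TestSimulatePaUnit:
    def test_zero_noise_calibration_inverts_exactly(self, calibrations):
        cal = calibrations["ARC17"]
        cfg = noiseless(per_unit_calibrations={"ARC17": cal}, units=("ARC17",))
        truth = simulate_truth(cfg)
        records, _ = simulate_pa_unit(truth, cfg, "ARC17")
        truth2 = truth["pm_true"].to_numpy().reshape(-1, 2).mean(axis=1)
        recovered = apply_linear_calibration(records["cf1_a"].to_numpy(), cal)
        np.testing.assert_allclose(recovered, truth2, rtol=1e-12)

    def test_counts_hit_target_submicron_fraction(self):
        cfg = noiseless()
        truth = simulate_truth(cfg)
        records, _ = simulate_pa_unit(truth, cfg, "PA1")
        p1 = p1_from_channels(
            records["n_gt_0p3_a"].to_numpy(),
            records["n_gt_0p5_a"].to_numpy(),
            records["n_gt_1_a"].to_numpy(),
            records["n_gt_2p5_a"].to_numpy(),
        )
        target = truth["p1_true"].to_numpy().reshape(-1, 2).mean(axis=1)
        np.testing.assert_allclose(p1, target, atol=1e-9)

    def test_counts_are_monotone(self):
        cfg = SimulationConfig(seed=3, n_days=2)
        truth = simulate_truth(cfg)
        records, _ = simulate_pa_unit(truth, cfg, "PA1")
        for ch in ("a", "b"):
            a = records[f"n_gt_0p3_{ch}"].to_numpy()
            b = records[f"n_gt_0p5_{ch}"].to_numpy()
            c = records[f"n_gt_1_{ch}"].to_numpy()
            d = records[f"n_gt_2p5_{ch}"].to_numpy()
            assert np.all(a >= b) and np.all(b >= c) and np.all(c >= d) and np.all(d >= 0)

    def test_injected_spike_trips_discordance_rule(self):
        cfg = noiseless(n_days=10, spike_rate=200.0, spike_magnitude=50.0)
        truth = simulate_truth(cfg)
        records, spikes = simulate_pa_unit(truth, cfg, "PA1")
        assert len(spikes) > 0
        hourly = records_to_hourly(
            records.rename(columns={"cf1_a": "pm_a", "cf1_b": "pm_b"}),
            value_cols=["pm_a", "pm_b"],
        )
        hourly = hourly.set_index("hour")
        for row in spikes.itertuples(index=False):
            pair = ChannelPairHour(
                row.hour,
                hourly.loc[row.hour, "pm_a"],
                hourly.loc[row.hour, "pm_b"],
            )
            assert fuse_channels(pair).discordant


class TestSimulateTeomFdms:
    def minute_truth(self, values, start="2022-06-01"):
        idx = pd.date_range(start, periods=len(values), freq="min")
        return pd.DataFrame({"pm_true": values, "p1_true": 0.9}, index=idx)

    def test_constant_truth_zero_noise_is_exact(self):
        cfg = noiseless()
        out = simulate_teom_fdms(self.minute_truth([12.0] * 120), noiseless(teom_duty_cycle=True))
        assert np.allclose(out["pm25"], 12.0)

    def test_within_hour_step_biases_duty_cycled_value(self):
        # 10 µg/m³ in the first half-hour, 0 after: the five 6-min
        # measurement windows oversample the high half.
        values = [10.0] * 30 + [0.0] * 30
        duty = simulate_teom_fdms(self.minute_truth(values), noiseless(teom_duty_cycle=True))
        full = simulate_teom_fdms(self.minute_truth(values), noiseless(teom_duty_cycle=False))
        assert full.loc[0, "pm25"] == pytest.approx(5.0)
        assert duty.loc[0, "pm25"] == pytest.approx(6.0)

    def test_negative_readings_occur_near_zero(self):
        cfg = noiseless(teom_noise_sd=3.0)
        out = simulate_teom_fdms(self.minute_truth([0.0] * (1000 * 60)), cfg)
        assert (out["pm25"] < 0).any()


class TestSimulateSite:
    def test_zero_noise_bundle_round_trips(self, noiseless_winter_bundle):
        bundle = noiseless_winter_bundle
        assert set(bundle.units) == {"ARC17"}
        assert len(bundle.reference) == 10 * 24

    def test_adding_a_unit_does_not_perturb_reference_or_first_unit(self):
        one = simulate_site(SimulationConfig(seed=6, n_days=2, units=("U1",)))
        two = simulate_site(SimulationConfig(seed=6, n_days=2, units=("U1", "U2")))
        pd.testing.assert_frame_equal(one.reference, two.reference)
        pd.testing.assert_frame_equal(one.units["U1"], two.units["U1"])

    def test_nephelometer_consistent_with_woodsmoke_relationship(self, noiseless_winter_bundle):
        from woodsmoke.conversions import neph_to_pm25

        bundle = noiseless_winter_bundle
        hourly_truth = bundle.truth["pm_true"].resample("h").mean()
        recovered = neph_to_pm25(bundle.nephelometer["scattering"].to_numpy())
        np.testing.assert_allclose(recovered, hourly_truth.to_numpy(), rtol=1e-9)
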