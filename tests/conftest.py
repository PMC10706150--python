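import pandas as pd
import pytest

from woodsmoke.io import packaged_calibrations
from woodsmoke.simulate import SimulationConfig, simulate_site


@pytest.fixture(scope="session")
def calibrations():
    return packaged_calibrations()


@pytest.fixture(scope="session")
def noiseless_winter_bundle(calibrations):
    """A 10-day noise-free winter site: every stage should be exact."""
    cfg = SimulationConfig(
        seed=0,
        n_days=10,
        start="2022-06-01",
        units=("ARC17",),
        per_unit_calibrations={"ARC17": calibrations["ARC17"]},
        day_factor_sigma=0.0,
        minute_sigma=0.0,
        sensor_noise_cv=0.0,
        spike_rate=0.0,
        teom_noise_sd=0.0,
        teom_duty_cycle=False,
        neph_noise_sd=0.0,
    )
    return simulate_site(cfg)


@pytest.fixture(scope="session")
def noisy_winter_bundle(calibrations):
    """A 30-day winter site under the default noise conditions."""
    cfg = SimulationConfig(
        seed=7,
        n_days=30,
        start="2022-06-01",
        units=("ARC17",),
        per_unit_calibrations={"ARC17": calibrations["ARC17"]},
    )
    return simulate_site(cfg)


@pytest.fixture()
def one_day_records(noisy_winter_bundle):
    """First simulated day of raw 2-min records (720 rows)."""
    records = noisy_winter_bundle.units["ARC17"]
    day0 = records["timestamp_start"].dt.normalize() == records[
        "timestamp_start"
    ].iloc[0].normalize()
    return records.loc[day0].reset_index(drop=True)
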