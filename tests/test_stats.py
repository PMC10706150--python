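import math

import numpy as np
import pandas as pd
import pytest

from woodsmoke.errors import DegenerateSeriesError
from woodsmoke.stats import collocation_stats, paired_days, residual_diagnostics


def daily(dates, values, **extra):
    frame = pd.DataFrame({"date": pd.to_datetime(dates), "pm25": values})
    for k, v in extra.items():
        frame[k] = v
    return frame


def pair_frame(ref, cand):
    n = len(ref)
    return pd.DataFrame(
        {"date": pd.date_range("2022-01-01", periods=n), "ref": ref, "cand": cand}
    )


class TestPairedDays:
    dates10 = pd.date_range("2022-06-01", periods=10)

    def test_identical_date_sets(self):
        ref = daily(self.dates10, range(10))
        cand = daily(self.dates10, range(10))
        assert len(paired_days(ref, cand)) == 10

    def test_missing_days_drop_pairs(self):
        ref = daily(self.dates10[2:], range(8))
        cand = daily(self.dates10, range(10))
        assert len(paired_days(ref, cand)) == 8

    def test_incomplete_and_excluded_days_ignored(self):
        ref = daily(self.dates10, range(10), complete=[True] * 9 + [False])
        cand = daily(self.dates10, range(10), excluded=[True] + [False] * 9)
        assert len(paired_days(ref, cand)) == 8

    def test_empty_intersection_rejected(self):
        ref = daily(self.dates10, range(10), excluded=True)
        cand = daily(self.dates10, range(10))
        with pytest.raises(DegenerateSeriesError):
            paired_days(ref, cand)


def brute_force_stats(ref, cand):
    """Direct formula evaluation, independent of the implementation path."""
    ref, cand = np.asarray(ref, float), np.asarray(cand, float)
    n = len(ref)
    mr, mc = ref.mean(), cand.mean()
    sr = math.sqrt(((ref - mr) ** 2).sum() / (n - 1))
    sc = math.sqrt(((cand - mc) ** 2).sum() / (n - 1))
    r = (((ref - mr) * (cand - mc)).sum() / (n - 1)) / (sr * sc)
    rmse = math.sqrt(((cand - ref) ** 2).mean())
    ols_slope = (((ref - mr) * (cand - mc)).sum()) / (((cand - mc) ** 2).sum())
    ols_intercept = mr - ols_slope * mc
    rma = math.copysign(sr / sc, r)
    r_se = math.sqrt((1 - r * r) / (n - 2))
    return r, r_se, rmse, rma, ols_slope, ols_intercept


class TestCollocationStats:
    def test_identity_input(self):
        vals = np.arange(10, dtype=float)
        st = collocation_stats(pair_frame(vals, vals))
        assert st.r == pytest.approx(1.0)
        assert st.rmse == 0.0
        assert st.rma_slope == pytest.approx(1.0)
        assert st.ols_slope == pytest.approx(1.0)
        assert st.ols_intercept == pytest.approx(0.0, abs=1e-12)

    def test_exact_doubling(self):
        cand = np.arange(1.0, 11.0)
        st = collocation_stats(pair_frame(2 * cand, cand))
        assert st.rma_slope == pytest.approx(2.0)
        assert st.ols_slope == pytest.approx(2.0)
        assert st.ols_intercept == pytest.approx(0.0, abs=1e-12)
        assert st.rmse == pytest.approx(math.sqrt((cand**2).mean()))

    def test_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(11)
        ref = rng.uniform(0, 40, 50)
        cand = ref + rng.normal(0, 3, 50)
        st = collocation_stats(pair_frame(ref, cand))
        r, r_se, rmse, rma, slope, intercept = brute_force_stats(ref, cand)
        assert st.r == pytest.approx(r, abs=1e-12)
        assert st.r_se == pytest.approx(r_se, abs=1e-12)
        assert st.rmse == pytest.approx(rmse, abs=1e-12)
        assert st.rma_slope == pytest.approx(rma, abs=1e-12)
        assert st.ols_slope == pytest.approx(slope, abs=1e-12)
        assert st.ols_intercept == pytest.approx(intercept, abs=1e-12)

    def test_rma_reciprocal_identity_and_ols_attenuation(self):
        rng = np.random.default_rng(5)
        ref = rng.uniform(0, 30, 80)
        cand = 0.8 * ref + rng.normal(0, 2, 80)
        forward = collocation_stats(pair_frame(ref, cand))
        backward = collocation_stats(pair_frame(cand, ref))
        assert forward.rma_slope * backward.rma_slope == pytest.approx(1.0)
        assert abs(forward.ols_slope) <= abs(forward.rma_slope)

    def test_rmse_invariant_to_pair_order(self):
        rng = np.random.default_rng(9)
        ref = rng.uniform(0, 30, 40)
        cand = ref + rng.normal(0, 1, 40)
        st = collocation_stats(pair_frame(ref, cand))
        perm = rng.permutation(40)
        st_perm = collocation_stats(pair_frame(ref[perm], cand[perm]))
        assert st.rmse == pytest.approx(st_perm.rmse, abs=1e-12)
        assert st.r == pytest.approx(st_perm.r, abs=1e-12)

    def test_rmse_estimates_additive_noise_sd(self):
        rng = np.random.default_rng(2)
        sigma = 2.5
        ref = rng.uniform(0, 40, 2000)
        cand = ref + rng.normal(0, sigma, 2000)
        st = collocation_stats(pair_frame(ref, cand))
        assert st.rmse == pytest.approx(sigma, rel=0.10)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(DegenerateSeriesError):
            collocation_stats(pair_frame([1.0, 2.0], [1.0, 2.0]))

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateSeriesError):
            collocation_stats(pair_frame([1.0] * 5, [1.0, 2, 3, 4, 5]))


class TestResidualDiagnostics:
    dates = pd.date_range("2022-01-01", periods=60)

    def make_inputs(self, ref, cand, p1, ratio):
        pairs = pd.DataFrame({"date": self.dates[: len(ref)], "ref": ref, "cand": cand})
        p1f = pd.DataFrame({"date": self.dates[: len(ref)], "p1": p1})
        rat = pd.DataFrame({"date": self.dates[: len(ref)], "pm_ratio": ratio})
        return pairs, p1f, rat

    def test_residual_equal_to_p1_gives_unit_correlation(self):
        rng = np.random.default_rng(1)
        p1 = rng.uniform(0.5, 1.0, 30)
        ref = 10.0 + p1  # residual (ref − cand) equals p1 exactly
        cand = np.full(30, 10.0)
        pairs, p1f, rat = self.make_inputs(ref, cand, p1, rng.uniform(0.3, 0.9, 30))
        d = residual_diagnostics(pairs, p1f, rat)
        assert d.r_residual_p1 == pytest.approx(1.0)

    def test_constant_residuals_rejected(self):
        pairs, p1f, rat = self.make_inputs(
            np.full(10, 12.0), np.full(10, 10.0), np.linspace(0.5, 1, 10), np.linspace(0.3, 0.9, 10)
        )
        with pytest.raises(DegenerateSeriesError):
            residual_diagnostics(pairs, p1f, rat)

    def test_coarse_bias_sign_pattern(self):
        # candidate underestimates in proportion to the coarse share, so
        # days with a low fine/coarse ratio under-read: residual-vs-ratio
        # correlation must come out negative.
        rng = np.random.default_rng(8)
        n = 60
        ratio = rng.uniform(0.3, 0.95, n)  # PM2.5/PM10
        ref = rng.uniform(5, 25, n)
        cand = ref * (1.0 - 0.5 * (1.0 - ratio)) + rng.normal(0, 0.2, n)
        pairs, p1f, rat = self.make_inputs(ref, cand, rng.uniform(0.6, 1.0, n), ratio)
        d = residual_diagnostics(pairs, p1f, rat)
        assert d.r_residual_pm_ratio < 0

    def test_insufficient_overlap_rejected(self):
        pairs, p1f, rat = self.make_inputs([1.0, 2.0], [1.0, 1.0], [0.9, 0.8], [0.5, 0.6])
        with pytest.raises(DegenerateSeriesError):
            residual_diagnostics(pairs, p1f, rat)
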