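"""Feature-engineering oracles: clock, circadian dynamics, filters and
cardiac transforms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.stats import spearmanr

import wearsleep as ws
from wearsleep.features import (
    FilterSpec,
    acceleration_to_counts,
    convolve,
    free_running_period,
    hr_preprocess,
    hr_variation,
    kernel,
    minmax_scale,
)


class TestCosineClock:
    def test_onset_and_half_period(self):
        assert ws.cosine_clock([0.0]) == pytest.approx(1.0)
        assert ws.cosine_clock([12.0]) == pytest.approx(-1.0)

    def test_periodicity_24h(self, rng):
        t = rng.uniform(0, 48, size=20)
        assert ws.cosine_clock(t) == pytest.approx(ws.cosine_clock(t + 24.0))


class TestActivityToLight:
    def test_zero_counts_give_darkness(self):
        assert (ws.activity_to_light(np.zeros(10)) == 0).all()

    def test_positive_counts_give_active_lux(self):
        lux = ws.activity_to_light(np.array([0.0, 3.0, 0.0]))
        assert lux.tolist() == [0.0, 1000.0, 0.0]

    def test_thresholding_matches_scan_oracle(self, rng):
        counts = rng.integers(0, 5, size=100).astype(float)
        lux = ws.activity_to_light(counts, threshold=1.0)
        oracle = [1000.0 if c > 1.0 else 0.0 for c in counts]
        assert lux.tolist() == oracle

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ws.activity_to_light(np.array([-1.0]))


class TestCircadian:
    def test_origin_is_fixed_point_in_darkness(self):
        for dt in (15.0, 60.0):
            traj = ws.integrate_circadian(np.zeros(200), dt=dt)
            assert (traj[["x", "x_c"]].to_numpy() == 0.0).all()

    @pytest.mark.parametrize("tau", [23.5, 24.2, 24.6])
    def test_free_running_period_tracks_tau(self, tau):
        params = ws.CircadianParams(tau_x=tau)
        n = 10 * 24 * 60  # ten days at one-minute steps
        traj = ws.integrate_circadian(
            np.zeros(n), params, ws.CircadianState(x=1.0), dt=60.0
        )
        period = free_running_period(traj, 60.0)
        assert period == pytest.approx(0.99669 * tau, rel=0.05)

    def test_limit_cycle_attracts_different_amplitudes(self):
        amps = []
        for x0 in (1.0, 2.0):
            traj = ws.integrate_circadian(
                np.zeros(10 * 24 * 60), None, ws.CircadianState(x=x0), dt=60.0
            )
            amps.append(traj["x"].to_numpy()[-1440:].max())
        assert amps[0] == pytest.approx(amps[1], rel=0.02)

    def test_halved_step_agrees(self):
        # integration-accuracy guard: dt=60 vs dt=30 over one day
        t1 = ws.integrate_circadian(np.zeros(1440), None, ws.CircadianState(x=1.0), dt=60.0)
        t2 = ws.integrate_circadian(np.zeros(2880), None, ws.CircadianState(x=1.0), dt=30.0)
        assert t1["x"].iloc[-1] == pytest.approx(t2["x"].iloc[-1], abs=1e-6)

    def test_light_entrains_and_keeps_activation_bounded(self):
        light = np.tile(np.r_[np.zeros(480), np.full(960, 1000.0)], 3)
        traj = ws.integrate_circadian(light, dt=60.0)
        assert traj["n_l"].between(0, 1).all()
        assert traj["x"].abs().max() > 0  # light kicks the oscillator

    def test_step_cap_enforced(self):
        with pytest.raises(ValueError):
            ws.integrate_circadian(np.zeros(5), dt=120.0)


class TestAccelerationCounts:
    def test_zero_and_constant_acceleration_give_zero_counts(self):
        n = 3000  # 30 s epochs at 10 Hz, 10 epochs
        zero = np.zeros((n, 3))
        gravity = np.tile([0.0, 0.0, 1.0], (n, 1))
        assert acceleration_to_counts(zero, fs=10).sum() == 0
        assert acceleration_to_counts(gravity, fs=10).sum() == 0

    def test_burst_epochs_detected_exactly(self, rng):
        fs, epoch = 10.0, 30.0
        n_epochs, spe = 10, int(fs * epoch)
        a = np.zeros((n_epochs * spe, 3))
        burst_epochs = [2, 7]
        for e in burst_epochs:
            s = e * spe + 50
            a[s : s + 40, 0] = np.sin(np.linspace(0, 20 * np.pi, 40))
        counts = acceleration_to_counts(a, fs=fs, epoch=epoch)
        # filtfilt ringing is orders of magnitude below the burst peak
        big = np.flatnonzero(counts > counts.max() * 0.01)
        assert big.tolist() == burst_epochs

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            acceleration_to_counts(np.zeros((10, 3)), fs=10.0, epoch=30.0)


class TestConvolve:
    def test_gaussian_kernel_unit_sum_dog_zero_sum(self):
        g = kernel(FilterSpec(sigma=50))
        d = kernel(FilterSpec(kind="difference_of_gaussians", sigma=120, sigma2=600))
        assert g.sum() == pytest.approx(1.0, abs=1e-12)
        assert d.sum() == pytest.approx(0.0, abs=1e-12)

    def test_constant_through_gaussian_unchanged(self):
        out = convolve(np.full(500, 7.5), FilterSpec(sigma=20))
        assert out == pytest.approx(7.5, abs=1e-9)

    def test_constant_through_dog_vanishes(self):
        spec = FilterSpec(kind="difference_of_gaussians", sigma=5, sigma2=25)
        out = convolve(np.full(500, 7.5), spec)
        assert np.abs(out).max() < 1e-9 * 7.5

    def test_impulse_response_is_kernel(self):
        spec = FilterSpec(sigma=3, truncation=4)
        k = kernel(spec)
        x = np.zeros(201)
        x[100] = 1.0
        out = convolve(x, spec)
        assert out[100 - len(k) // 2 : 100 + len(k) // 2 + 1] == pytest.approx(k)

    def test_mean_preserved_on_interior_dominant_series(self, rng):
        x = np.sin(np.linspace(0, 6 * np.pi, 2000)) + rng.normal(0, 0.1, 2000)
        out = convolve(x, FilterSpec(sigma=10))
        assert out.mean() == pytest.approx(x.mean(), abs=1e-3)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="shorter than kernel"):
            convolve(np.ones(5), FilterSpec(sigma=10))

    def test_dog_requires_wider_second_sigma(self):
        with pytest.raises(ValueError):
            FilterSpec(kind="difference_of_gaussians", sigma=10, sigma2=5)


class TestHeartRate:
    def test_interpolation_midpoint(self):
        idx = pd.DatetimeIndex(["2021-12-16 06:00:00", "2021-12-16 06:01:00"])
        hr = ws.EpochTable(pd.DataFrame({"hr": [60.0, 62.0]}, index=idx), 60)
        out = hr_preprocess(hr, smooth=FilterSpec(sigma=1e-6))
        assert out.iloc[30] == pytest.approx(61.0, abs=1e-6)

    def test_constant_hr_stays_constant(self):
        idx = pd.date_range("2021-12-16 06:00:00", periods=10, freq="60s")
        hr = ws.EpochTable(pd.DataFrame({"hr": np.full(10, 58.0)}, index=idx), 60)
        out = hr_preprocess(hr)
        assert out.to_numpy() == pytest.approx(58.0)

    def test_interpolation_matches_two_point_formula(self, rng):
        idx = pd.date_range("2021-12-16 06:00:00", periods=6, freq="60s")
        vals = rng.uniform(55, 75, size=6)
        hr = ws.EpochTable(pd.DataFrame({"hr": vals}, index=idx), 60)
        out = hr_preprocess(hr, smooth=FilterSpec(sigma=1e-6)).to_numpy()
        t = np.arange(0, 301)
        oracle = np.interp(t, np.arange(0, 301, 60), vals)
        assert out == pytest.approx(oracle, abs=1e-6)

    def test_variation_direct_arithmetic(self):
        out = hr_variation([60.0, 63.0, 60.0], 61.0)
        assert out == pytest.approx([3 / 61, 3 / 61])

    def test_variation_constant_is_zero(self):
        assert hr_variation(np.full(10, 60.0), 60.0) == pytest.approx(0.0)

    def test_variation_matches_elementwise_oracle(self, rng):
        h = rng.uniform(50, 80, 50)
        out = hr_variation(h, 65.0)
        oracle = [abs(h[i + 1] - h[i]) / 65.0 for i in range(49)]
        assert out == pytest.approx(oracle)

    def test_variation_needs_positive_mean(self):
        with pytest.raises(ValueError):
            hr_variation([60.0, 61.0], 0.0)


class TestScaling:
    def test_log_positify_worked_values(self):
        assert ws.log_positify([0.0, 3.0]) == pytest.approx([0.0, 2.0])
        assert ws.log_positify([-1.0, 0.0]) == pytest.approx([0.0, 1.0])

    @given(
        arrays(np.float64, st.integers(2, 30),
               elements=st.integers(-10**6, 10**6).map(float))
    )
    def test_log_positify_nonnegative_rank_preserving(self, y):
        # integer-valued inputs: differences survive the +1 shift, so the
        # monotonicity property is tested free of float-resolution artefacts
        out = ws.log_positify(y)
        assert out.min() == pytest.approx(0.0, abs=1e-12)
        assert np.argmin(out) == np.argmin(y)
        if len(np.unique(y)) > 1:
            rho = spearmanr(y, out).statistic
            assert rho == pytest.approx(1.0)

    def test_minmax_known_bounds(self):
        train = pd.DataFrame({"a": [0.0, 10.0]})
        _, scaled, _ = minmax_scale(train, pd.DataFrame({"a": [5.0, 20.0]}))
        assert scaled["a"].tolist() == pytest.approx([0.5, 2.0])

    def test_minmax_constant_column_maps_to_zero(self):
        train = pd.DataFrame({"a": [3.0, 3.0, 3.0]})
        scaled, _, _ = minmax_scale(train)
        assert (scaled["a"] == 0.0).all()

    def test_minmax_inverse_round_trip(self, rng):
        train = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        scaled, _, scaler = minmax_scale(train)
        back = scaler.inverse_transform(scaled)
        assert back == pytest.approx(train.to_numpy(), abs=1e-12)


def test_night_feature_table_columns_and_determinism(one_night):
    t1 = ws.night_feature_table(one_night)
    t2 = ws.night_feature_table(one_night)
    for col in ("time", "cosine", "circadian", "hr", "hr_var", "steps", "stage"):
        assert col in t1.columns
    pd.testing.assert_frame_equal(t1.frame, t2.frame)
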