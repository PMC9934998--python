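"""STV, interventricular deltas, AT-ARI regression, window selection."""
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import cavbep
from cavbep.fiducials import measure_egm_series
from cavbep.repol_stats import (at_ari_slope, delta_at, delta_mapd,
                                select_measurement_window, stv)
from cavbep.synth import SynthParams, synth_recording

finite_series = st.lists(
    st.floats(min_value=-500.0, max_value=500.0, allow_nan=False), min_size=31,
    max_size=40)


class TestStv:
    def test_constant_series_is_zero(self):
        assert stv([200.0] * 31) == 0.0

    def test_alternating_closed_form(self):
        series = [200.0, 210.0] * 16  # 31+ beats, |diff| = 10 throughout
        assert stv(series[:31]) == pytest.approx(300.0 / (30 * math.sqrt(2)),
                                                 abs=1e-9)

    def test_insufficient_beats_message_states_count(self):
        with pytest.raises(ValueError, match="31"):
            stv([1.0] * 30)

    def test_literal_mode_uses_n_beats(self):
        series = [200.0, 210.0] * 15  # 30 beats, 29 differences
        expect = 29 * 10.0 / (30 * math.sqrt(2))
        assert stv(series, mode="literal") == pytest.approx(expect, abs=1e-9)

    def test_monte_carlo_calibration(self):
        # E[STV] = sigma * sqrt(2/pi); mean |N(0, 2 s^2)| = 2 s / sqrt(pi)
        sigma = 1.2533
        rng = np.random.default_rng(12345)
        v = stv(rng.normal(0.0, sigma, 3001), n_diffs=3000)
        assert v == pytest.approx(sigma * math.sqrt(2 / math.pi), rel=0.05)

    @given(finite_series, st.floats(min_value=-100, max_value=100,
                                    allow_nan=False))
    def test_translation_invariant(self, series, c):
        d = np.asarray(series)
        assert stv(d + c) == pytest.approx(stv(d), abs=1e-8)

    @given(finite_series, st.floats(min_value=-4.0, max_value=4.0,
                                    allow_nan=False))
    def test_absolutely_homogeneous_and_nonnegative(self, series, a):
        d = np.asarray(series)
        assert stv(d) >= 0.0
        assert stv(a * d) == pytest.approx(abs(a) * stv(d), rel=1e-9, abs=1e-8)

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            stv([1.0, np.nan] + [1.0] * 30)


class TestDeltas:
    def test_delta_mapd_values(self):
        assert delta_mapd(213.9, 192.8) == pytest.approx(21.1, abs=1e-9)
        assert delta_mapd(455.7, 328.2) == pytest.approx(127.5, abs=1e-9)
        assert delta_mapd(200.0, 200.0) == 0.0

    def test_delta_at_values(self):
        assert delta_at(43.6, 46.0) == pytest.approx(-2.4, abs=1e-9)
        assert delta_at(30.0, 30.0) == 0.0

    @given(st.floats(-500, 500, allow_nan=False),
           st.floats(-500, 500, allow_nan=False))
    def test_antisymmetry(self, a, b):
        assert delta_mapd(a, b) == pytest.approx(-delta_mapd(b, a), abs=1e-9)
        assert delta_at(a, b) == pytest.approx(-delta_at(b, a), abs=1e-9)


class TestAtAriSlope:
    def test_exact_line(self):
        at = np.array([10.0, 20.0, 30.0, 40.0, 55.0])
        fit = at_ari_slope(at, 250.0 - 0.4 * at)
        assert fit.slope == pytest.approx(-0.4, abs=1e-12)
        assert fit.intercept == pytest.approx(250.0, abs=1e-9)
        assert fit.r == pytest.approx(-1.0, abs=1e-9)

    def test_duplicating_points_keeps_fit(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(10, 60, 8)
        y = 240 - 1.5 * x + rng.normal(0, 3, 8)
        f1 = at_ari_slope(x, y)
        f2 = at_ari_slope(np.r_[x, x], np.r_[y, y])
        assert f2.slope == pytest.approx(f1.slope, abs=1e-12)
        assert f2.intercept == pytest.approx(f1.intercept, abs=1e-9)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            n = int(rng.integers(3, 9))
            x = rng.uniform(0, 80, n)
            if np.ptp(x) == 0:
                continue
            y = rng.uniform(150, 400, n)
            a = np.column_stack([np.ones(n), x])
            beta = np.linalg.solve(a.T @ a, a.T @ y)
            fit = at_ari_slope(x, y)
            assert fit.slope == pytest.approx(beta[1], abs=1e-9)
            assert fit.intercept == pytest.approx(beta[0], abs=1e-9)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError, match=">= 3"):
            at_ari_slope([1.0, 2.0], [3.0, 4.0])
        with pytest.raises(ValueError, match="variance"):
            at_ari_slope([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])

    def test_nan_pairs_dropped(self):
        x = [10.0, 20.0, np.nan, 40.0]
        y = [250.0, 246.0, 240.0, 238.0]
        assert at_ari_slope(x, y).n_points == 3


@pytest.mark.parametrize("noise,tol", [(0.0, 0.05), (None, 0.3)])
def test_end_to_end_slope_recovery(noise, tol):
    """Programmed AT-ARI slopes (including the acute-AV-block-like
    positive regime) are recovered from full recordings, both noise-free
    and at the generator's default noise level."""
    for target in (-4.5, -3.2, -0.8, -0.4, 0.0, 0.5):
        kw = dict(duration_s=12, stv_sigma_ms=0.0, at_ari_slope=target, seed=17)
        if noise is not None:
            kw["noise_sd"] = noise
        rec, gt = synth_recording(SynthParams(**kw))
        at, ari = measure_egm_series(rec, gt.beat_times_ms)
        fit = at_ari_slope(np.nanmean(at[2:7], axis=0),
                           np.nanmean(ari[2:7], axis=0))
        assert fit.slope == pytest.approx(target, abs=tol)


class TestMeasurementWindow:
    times = np.arange(0.0, 400_000.0, 1000.0)  # 400 beats at 60 bpm

    def test_no_ectopy_window_ends_at_ramp_end(self):
        ect = np.zeros_like(self.times, dtype=bool)
        idx = select_measurement_window(self.times, ect, dofetilide_start_s=50.0,
                                        phase="dofetilide")
        assert self.times[idx[-1]] <= 50_000.0 + 300_000.0
        assert self.times[idx[-1]] == 350_000.0

    def test_window_truncated_at_first_ectopic(self):
        ect = np.zeros_like(self.times, dtype=bool)
        ect[self.times == 170_000.0] = True  # 120 s after the 50 s start
        idx = select_measurement_window(self.times, ect, dofetilide_start_s=50.0,
                                        phase="dofetilide")
        assert self.times[idx[-1]] < 170_000.0

    def test_baseline_unaffected_by_post_start_ectopy(self):
        ect = np.zeros_like(self.times, dtype=bool)
        ect[self.times == 20_000.0] = True  # ectopic before the infusion
        idx = select_measurement_window(self.times, ect, dofetilide_start_s=50.0,
                                        phase="baseline")
        assert self.times[idx[0]] > 20_000.0
        assert self.times[idx[-1]] < 50_000.0

    def test_no_qualifying_window_raises(self):
        ect = np.ones_like(self.times, dtype=bool)
        with pytest.raises(ValueError, match="baseline"):
            select_measurement_window(self.times, ect, phase="baseline")
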