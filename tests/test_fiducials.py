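"""Fiducial extraction against generator ground truth and analytic cases."""
import numpy as np
import pytest

import cavbep
from cavbep.fiducials import (LV_ELECTRODES, detect_beats, egm_ari, egm_at,
                              jtc, mapd80, measure_egm_series,
                              measure_intervals, measure_map_series,
                              qtc_van_der_water)
from cavbep.synth import EpisodeSpec, SynthParams, _qrs_wavelet, synth_recording


class TestDetectBeats:
    def test_annotation_count_matches_beats(self, noise_free, noise_free_beats):
        _, _, gt = noise_free
        assert len(noise_free_beats) == len(gt.beat_times_ms)
        assert not any(b.ectopic for b in noise_free_beats)

    def test_injected_run_flagged_ectopic(self):
        p = SynthParams(duration_s=60, seed=3,
                        ectopy=[EpisodeSpec(onset_s=20.3, n_beats=5)])
        rec, gt = synth_recording(p)
        beats = detect_beats(rec)
        assert sum(b.ectopic for b in beats) == 5
        flagged = [b.beat_time_ms for b in beats if b.ectopic]
        assert np.allclose(sorted(flagged), sorted(gt.beat_times_ms[gt.ectopic]))

    def test_flat_line_raises(self, noise_free):
        _, rec, _ = noise_free
        flat = cavbep.SignalRecording(
            data=np.zeros_like(rec.data), channel_names=rec.channel_names,
            roles=rec.roles, fs_hz=rec.fs_hz,
            pacing_spikes_ms=rec.pacing_spikes_ms)
        with pytest.raises(ValueError, match="flat"):
            detect_beats(flat)


class TestFiducialRecovery:
    """On noise-free input every fiducial matches truth within 1 sample."""

    def test_ecg_fiducials_within_one_sample(self, noise_free, noise_free_beats):
        _, _, gt = noise_free
        for b in noise_free_beats[:-1]:
            i = b.beat_index
            assert abs(b.qrs_on_ms - gt.qrs_on_ms[i]) <= 1.0
            assert abs(b.qrs_off_ms - gt.qrs_off_ms[i]) <= 1.0
            assert abs(b.t_peak_ms - gt.t_peak_ms[i]) <= 1.0
            assert abs(b.t_end_ms - gt.t_end_ms[i]) <= 1.0

    def test_egm_and_map_within_one_sample(self, noise_free):
        _, rec, gt = noise_free
        n = 12
        at, ari = measure_egm_series(rec, gt.beat_times_ms[:n])
        assert np.nanmax(np.abs(at - gt.at_ms[:n, 1:9])) <= 1.0
        assert np.nanmax(np.abs(ari - gt.ari_ms[:n, 1:9])) <= 1.0
        rv_at, mapd = measure_map_series(rec, gt.beat_times_ms[:n])
        assert np.nanmax(np.abs(rv_at - gt.rv_at_ms[:n])) <= 1.0
        assert np.nanmax(np.abs(mapd - gt.mapd_ms[:n])) <= 1.0


class TestIntervals:
    def test_noise_free_interval_recovery(self, noise_free, noise_free_beats):
        p, rec, _ = noise_free
        iv = measure_intervals(rec, noise_free_beats)
        assert iv.rr == pytest.approx(1000.0, abs=0.5)
        assert iv.qrs == pytest.approx(p.qrs_ms, abs=1.0)
        assert iv.qt == pytest.approx(p.qt_ms, abs=1.0)
        assert iv.tpe == pytest.approx(p.tpe_ms, abs=1.0)
        # coupled atria: PP tracks RR
        assert iv.pp == pytest.approx(iv.rr, abs=2.0)

    def test_reported_value_is_mean_of_selected_beats(self, noise_free,
                                                      noise_free_beats):
        _, rec, _ = noise_free
        iv = measure_intervals(rec, noise_free_beats, n_beats=5)
        per_beat = [noise_free_beats[i].t_end_ms - noise_free_beats[i].qrs_on_ms
                    for i in iv.beat_indices]
        assert len(per_beat) == 5
        assert iv.qt == pytest.approx(np.mean(per_beat), abs=1e-9)

    def test_too_few_clean_beats_raises(self, noise_free, noise_free_beats):
        _, rec, _ = noise_free
        with pytest.raises(ValueError, match="dofetilide"):
            measure_intervals(rec, noise_free_beats, n_beats=50,
                              phase="dofetilide")


class TestQTcJTc:
    @pytest.mark.parametrize("qt,rr,expect", [
        (300.0, 1000.0, 300.0),   # RR = 1000 means no correction
        (262.3, 587.1, 298.2),    # tachycardic sinus-rhythm means
        (339.1, 1084.0, 331.8),   # bradycardic AV-block means
    ])
    def test_van_der_water(self, qt, rr, expect):
        assert qtc_van_der_water(qt, rr) == pytest.approx(expect, abs=0.05)

    @pytest.mark.parametrize("qtc,qrs,expect", [
        (300.0, 100.0, 200.0),
        (293.1, 66.5, 226.6),
        (250.0, 250.0, 0.0),
    ])
    def test_jtc(self, qtc, qrs, expect):
        assert jtc(qtc, qrs) == pytest.approx(expect, abs=0.05)

    def test_positivity_required(self):
        with pytest.raises(ValueError):
            qtc_van_der_water(-1.0, 800.0)


class TestMapd80:
    def test_square_pulse_analytic(self):
        x = np.zeros(2000)
        x[350:600] = 1.0  # width 250 ms at 1 kHz
        rv_at, mapd = mapd80(x, 1000.0, spike_ms=300.0)
        assert mapd == pytest.approx(250.0, abs=1.0)
        assert rv_at == pytest.approx(50.0, abs=1.0)

    def test_amplitude_scale_invariance(self):
        x = np.zeros(2000)
        x[350:600] = 1.0
        _, m1 = mapd80(x, 1000.0, 300.0)
        _, m2 = mapd80(2.0 * x, 1000.0, 300.0)
        assert m1 == pytest.approx(m2, abs=1e-9)

    def test_no_upstroke_gives_missing(self):
        assert np.isnan(mapd80(np.zeros(2000), 1000.0, 300.0)[1])


class TestEgmAt:
    def test_tie_break_earliest(self):
        sig = np.zeros(1000)
        t = np.arange(1000, dtype=float)
        sig += _qrs_wavelet(t, 130.0, 3.0, 1.0)
        sig += _qrs_wavelet(t, 142.0, 3.0, 1.0)
        at = egm_at(sig, 1000.0, spike_ms=100.0)
        assert at == pytest.approx(30.0, abs=0.5)

    def test_lv_aggregate_excludes_distal_proximal(self):
        # electrodes 1 and 10 are excluded from all LV aggregates
        assert LV_ELECTRODES == tuple(range(2, 10))

    def test_flat_window_missing(self):
        assert np.isnan(egm_at(np.zeros(1000), 1000.0, 100.0))


class TestEgmAri:
    def test_flat_t_window_missing(self, noise_free):
        _, rec, gt = noise_free
        sig = rec.channel("egm5")
        spike = gt.beat_times_ms[5]
        # a window of pure baseline (diastole of the same beat)
        assert np.isnan(egm_ari(sig, 1000.0, spike, (spike + 700.0, spike + 950.0)))

    def test_inverted_t_wave_same_ari(self):
        p_up = SynthParams(duration_s=15, noise_sd=0.0, stv_sigma_ms=0.0)
        p_dn = SynthParams(duration_s=15, noise_sd=0.0, stv_sigma_ms=0.0,
                           egm_t_polarity=-1)
        for p in (p_up, p_dn):
            rec, gt = synth_recording(p)
            _, ari = measure_egm_series(rec, gt.beat_times_ms[:8])
            assert np.nanmax(np.abs(ari - gt.ari_ms[:8, 1:9])) <= 1.0
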