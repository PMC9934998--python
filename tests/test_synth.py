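"""Generator contracts: schedules, ground-truth placement, determinism."""
import numpy as np
import pytest

import cavbep
from cavbep.synth import (DofetilideSpec, EpisodeSpec, SegmentSpec,
                          StrainSynthParams, SynthParams, make_beat_schedule,
                          strain_params_for_walls, synth_recording,
                          synth_strain)


class TestBeatSchedule:
    def test_regular_schedule_arithmetic(self):
        sched = make_beat_schedule(SynthParams(rate_bpm=60, duration_s=60))
        assert len(sched.times_ms) == 60
        assert np.allclose(np.diff(sched.times_ms), 1000.0)
        assert not sched.ectopic.any()

    def test_episode_beat_count_conserved(self):
        p = SynthParams(duration_s=60, ectopy=[EpisodeSpec(onset_s=20.3, n_beats=5)])
        sched = make_beat_schedule(p)
        assert sched.ectopic.sum() == 5

    def test_schedule_deterministic(self):
        p = SynthParams(duration_s=30, ectopy=[EpisodeSpec(onset_s=10.1, n_beats=4)],
                        seed=7)
        a, b = make_beat_schedule(p), make_beat_schedule(p)
        assert np.array_equal(a.times_ms, b.times_ms)
        assert np.array_equal(a.ectopic, b.ectopic)

    def test_overlapping_episodes_error_names_both(self):
        p = SynthParams(duration_s=60, ectopy=[
            EpisodeSpec(onset_s=20.0, n_beats=10),
            EpisodeSpec(onset_s=21.0, n_beats=3)])
        with pytest.raises(ValueError, match="0 and 1"):
            make_beat_schedule(p)

    def test_too_short_duration(self):
        with pytest.raises(ValueError, match="too short"):
            make_beat_schedule(SynthParams(duration_s=0.2))

    @pytest.mark.parametrize("bad", [
        dict(electrode_ats=(1.0, 2.0)),
        dict(stv_sigma_ms=-1.0),
        dict(rate_bpm=0.0),
        dict(fs_hz=-5.0),
    ])
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            SynthParams(**bad).validate()


class TestRecordingGroundTruth:
    def test_bit_identical_given_seed(self):
        p = SynthParams(duration_s=25, seed=42, stv_sigma_ms=1.0,
                        dofetilide=DofetilideSpec(start_s=10.0, ramp_s=10.0),
                        ectopy=[EpisodeSpec(onset_s=18.2, n_beats=5)])
        r1, g1 = synth_recording(p)
        r2, g2 = synth_recording(p)
        assert np.array_equal(r1.data, r2.data)
        assert np.array_equal(g1.ari_ms, g2.ari_ms, equal_nan=True)

    def test_degenerate_gradient_all_aris_equal(self):
        p = SynthParams(duration_s=10, at_ari_slope=0.0, stv_sigma_ms=0.0,
                        noise_sd=0.0)
        _, gt = synth_recording(p)
        assert np.allclose(gt.ari_ms[~gt.ectopic], p.ari_base_ms)

    def test_programmed_slope_exact_on_truth(self):
        # the motivating sinus-rhythm regime: programmed slope -0.4
        p = SynthParams(duration_s=10, at_ari_slope=-0.4, stv_sigma_ms=0.0,
                        noise_sd=0.0)
        _, gt = synth_recording(p)
        fit = cavbep.at_ari_slope(gt.at_ms[0], gt.ari_ms[0])
        assert fit.slope == pytest.approx(-0.4, abs=1e-9)

    def test_true_series_stv_matches_closed_form(self):
        # E[STV] = sigma * sqrt(2/pi) for iid Normal perturbations
        sigma = 1.2533
        p = SynthParams(rate_bpm=120, duration_s=505, stv_sigma_ms=sigma,
                        noise_sd=0.0, seed=9)
        _, gt = synth_recording(p)
        series = np.nanmean(gt.ari_ms[:, 1:9], axis=1)
        series = series[np.isfinite(series)]
        v = cavbep.stv(series, n_diffs=len(series) - 1)
        assert v == pytest.approx(sigma * np.sqrt(2 / np.pi), rel=0.05)

    def test_dofetilide_ramp_and_gradient(self):
        dof = DofetilideSpec(start_s=10.0, ari_gain_ms=100.0,
                             gradient_weight=0.5, ramp_s=20.0)
        p = SynthParams(duration_s=40, stv_sigma_ms=0.0, noise_sd=0.0,
                        dofetilide=dof)
        _, gt = synth_recording(p)
        pre = gt.beat_times_ms < 10_000.0
        post = gt.beat_times_ms > 30_000.0
        base_mean = gt.ari_ms[pre].mean(axis=0)
        full_mean = gt.ari_ms[post].mean(axis=0)
        prolong = full_mean - base_mean
        # mean prolongation equals the gain; rank-normalized earliness spans
        # [-0.5, +0.5], so the earliest electrode gets gain * (1 + 0.5 gw)
        # and the latest gain * (1 - 0.5 gw)
        assert prolong.mean() == pytest.approx(100.0, abs=1e-9)
        earliest = int(np.argmin(gt.electrode_ats))
        latest = int(np.argmax(gt.electrode_ats))
        assert prolong[earliest] == pytest.approx(125.0, abs=1e-9)
        assert prolong[latest] == pytest.approx(75.0, abs=1e-9)

    def test_t_polarity_flip_preserves_truth_changes_signal(self):
        up = SynthParams(duration_s=10, noise_sd=0.0, stv_sigma_ms=0.0)
        dn = SynthParams(duration_s=10, noise_sd=0.0, stv_sigma_ms=0.0,
                         egm_t_polarity=-1)
        r1, g1 = synth_recording(up)
        r2, g2 = synth_recording(dn)
        assert np.array_equal(g1.ari_ms, g2.ari_ms, equal_nan=True)
        assert not np.array_equal(r1.channel("egm5"), r2.channel("egm5"))


class TestStrainSynth:
    def test_argmax_at_programmed_ttp(self):
        segs = {name: SegmentSpec(onset_ms=20.0, ttp_ms=300.0, ps_pct=30.0)
                for name in cavbep.strain.SEGMENTS}
        curves = synth_strain(StrainSynthParams(segments=segs))
        for tr in curves.traces.values():
            assert curves.time_ms[int(np.argmax(tr))] == pytest.approx(300.0)

    def test_identical_walls_zero_delta(self):
        sp = strain_params_for_walls((30.0, 20.0, 300.0), (30.0, 20.0, 300.0))
        _, deltas = cavbep.analyze_strain(synth_strain(sp))
        assert deltas.d_ttp == pytest.approx(0.0, abs=1e-6)
        assert deltas.d_ps == pytest.approx(0.0, abs=1e-6)

    def test_invalid_segment_spec(self):
        with pytest.raises(ValueError):
            SegmentSpec(onset_ms=50.0, ttp_ms=40.0, ps_pct=10.0).validate()
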