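"""Forward-model correctness: cascade fixed points and steady states,
beat-clock exactness, template and wavefront geometry, noise calibration."""

import numpy as np
import pytest

import cardiomea as cm
from cardiomea.core import ValidationError


class TestPhotoResponse:
    def test_dark_state_is_a_fixed_point(self):
        p = cm.PhotoResponseParams()
        prot = cm.StimulusProtocol.constant(0.0, 600.0)
        t, c, r = cm.simulate_camp_and_rate(p, prot, 600.0)
        assert np.allclose(c, p.c0)
        assert np.allclose(r, p.R0)

    @pytest.mark.parametrize("irr", [0.3, 0.56, 2.7, 27.0])
    def test_steady_state_matches_closed_form(self, irr):
        # analytic limit: fold -> 1 + delta_max * I / (I + K_I)
        p = cm.PhotoResponseParams()
        prot = cm.StimulusProtocol.constant(irr, 7200.0)
        t, c, r = cm.simulate_camp_and_rate(p, prot, 7200.0, dt_s=1.0)
        expected = 1.0 + p.delta_max * irr / (irr + p.K_I)
        assert abs(r[-1] / p.R0 - expected) / expected < 1e-3
        assert abs(r[-1] / p.R0 - p.steady_state_fold(irr)) < 1e-3

    def test_half_saturating_irradiance_gives_half_the_elevation(self):
        p = cm.PhotoResponseParams()
        prot = cm.StimulusProtocol.constant(p.K_I, 7200.0)
        _, _, r = cm.simulate_camp_and_rate(p, prot, 7200.0)
        assert abs(r[-1] / p.R0 - (1 + p.delta_max / 2)) < 1e-3

    def test_saturating_light_gives_14_percent_elevation(self):
        p = cm.PhotoResponseParams()
        fold = float(p.steady_state_fold(27.0))
        assert abs(fold - 1.137) < 0.001   # 1 + 0.14 * 27 / 27.56

    def test_response_is_monotone_within_constant_epoch(self):
        p = cm.PhotoResponseParams()
        prot = cm.StimulusProtocol(((0.0, 300.0, 0.0), (300.0, 2100.0, 27.0)))
        t, c, r = cm.simulate_camp_and_rate(p, prot, 2100.0)
        lit = t >= 300.0
        assert np.all(np.diff(c[lit]) >= -1e-12)
        assert np.all(np.diff(r[lit]) >= -1e-12)

    def test_camp_half_rise_is_under_2_5_minutes(self):
        p = cm.PhotoResponseParams()
        prot = cm.StimulusProtocol.constant(27.0, 3600.0)
        t, c, _ = cm.simulate_camp_and_rate(p, prot, 3600.0)
        c_inf = float(p.camp_target(27.0))
        t50 = t[np.argmax(c >= p.c0 + 0.5 * (c_inf - p.c0))] / 60.0
        assert t50 <= 2.5

    def test_rate_half_rise_falls_in_6_to_8_minutes(self):
        p = cm.PhotoResponseParams()
        prot = cm.StimulusProtocol.constant(27.0, 3600.0)
        t, _, r = cm.simulate_camp_and_rate(p, prot, 3600.0)
        r_inf = p.R0 * float(p.steady_state_fold(27.0))
        t50 = t[np.argmax(r >= p.R0 + 0.5 * (r_inf - p.R0))] / 60.0
        assert 6.0 <= t50 <= 8.0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValidationError):
            cm.PhotoResponseParams(delta_max=1.5)
        with pytest.raises(ValidationError):
            cm.PhotoResponseParams(c_max=1.0)  # below c0


class TestBeatClock:
    def test_constant_rate_clock_is_exact(self):
        beats = cm.constant_rate_beats(5.0, 6.0)
        assert len(beats) == 30
        assert np.allclose(np.diff(beats), 0.2)

    def test_expected_count_matches_rate_integral(self):
        # oracle: count = floor(integral of R dt + initial phase)
        counts = [len(cm.constant_rate_beats(5.7, 60.0, jitter_ms=1.0,
                                             seed=s)) for s in range(100)]
        assert abs(np.mean(counts) - 342) <= 1

    def test_interbeat_interval_tracks_rising_rate(self):
        p = cm.PhotoResponseParams()
        prot = cm.StimulusProtocol.constant(27.0, 1800.0)
        t, _, r = cm.simulate_camp_and_rate(p, prot, 1800.0)
        beats = cm.generate_beat_times(t, r)
        ibi = np.diff(beats)
        # smoothed IBI shrinks monotonically toward the plateau
        k = 20
        smooth = np.convolve(ibi, np.ones(k) / k, mode="valid")
        assert np.all(np.diff(smooth) <= 1e-4)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValidationError):
            cm.generate_beat_times(np.array([0.0, 1.0]),
                                   np.array([1.0, 0.0]))


class TestSpikeTemplate:
    def test_biphasic_template_has_zero_net_area(self):
        tpl = cm.SpikeTemplate(morphology=0.0)
        t = np.linspace(-tpl.half_support_s, tpl.half_support_s, 20001)
        area = np.trapezoid(tpl.evaluate(t), t)
        peak_area = tpl.amplitude_uV * tpl.sigma_s
        assert abs(area) < 1e-3 * peak_area

    @pytest.mark.parametrize("m", [-1.0, -0.3, 0.0, 0.5, 1.0])
    def test_peak_equals_amplitude_within_1_percent(self, m):
        tpl = cm.SpikeTemplate(amplitude_uV=300.0, morphology=m)
        t = np.linspace(-tpl.half_support_s, tpl.half_support_s, 20001)
        assert abs(np.max(np.abs(tpl.evaluate(t))) - 300.0) < 3.0

    def test_monophasic_extremes_have_single_lobe_sign(self):
        t = np.linspace(-0.004, 0.004, 2001)
        assert np.all(cm.SpikeTemplate(morphology=1.0).evaluate(t) >= 0)
        assert np.all(cm.SpikeTemplate(morphology=-1.0).evaluate(t) <= 0)


class TestWavefront:
    def test_planar_intercolumn_delay_is_pitch_over_speed(self):
        # 0.2 mm / 50 mm s^-1 = 4 ms between columns
        lay = cm.grid_layout(1, 4)
        wf = cm.WavefrontParams(mode="planar", speed_mm_s=50.0,
                                direction_deg=0.0)
        delays = wf.delays_s(lay)
        assert np.allclose(delays, [0.0, 0.004, 0.008, 0.012])

    def test_radial_delay_is_distance_over_speed(self):
        lay = cm.grid_layout(3, 3)
        wf = cm.WavefrontParams(mode="radial", speed_mm_s=50.0,
                                origin_um=(200.0, 200.0))
        delays = wf.delays_s(lay)
        assert delays[4] == 0.0                      # centre electrode
        assert np.isclose(delays[0], 200 * np.sqrt(2) / 50000.0)


class TestSynthesis:
    def test_zero_beats_zero_noise_gives_all_zero(self):
        lay = cm.grid_layout(2, 2)
        rec = cm.synthesize_recording(np.array([]), cm.WavefrontParams(),
                                      cm.SpikeTemplate(), lay,
                                      noise_rms_uV=0.0, duration_s=0.5)
        assert np.all(rec.data == 0)

    def test_spike_count_is_conserved_per_live_channel(self):
        lay = cm.grid_layout(2, 2)
        beats = cm.constant_rate_beats(5.0, 2.0)
        rec = cm.synthesize_recording(beats, cm.WavefrontParams(),
                                      cm.SpikeTemplate(), lay,
                                      noise_rms_uV=0.0, duration_s=2.1)
        for i in range(rec.n_channels):
            times, _ = cm.detect_peaks(rec.data[i], rec.sample_rate_hz)
            assert len(times) == len(beats)

    def test_dead_channels_carry_noise_only(self):
        lay = cm.default_layout()
        dead = [int(i) for i in lay.electrode_ids[[5, 13, 21]]]
        beats = cm.constant_rate_beats(5.7, 2.0)
        rec = cm.synthesize_recording(beats, cm.WavefrontParams(),
                                      cm.SpikeTemplate(), lay,
                                      noise_rms_uV=7.0, dead_channels=dead,
                                      duration_s=2.1, seed=5)
        silent = [int(cid) for i, cid in enumerate(rec.channel_ids)
                  if np.max(np.abs(rec.data[i])) < 50.0]
        assert sorted(silent) == sorted(dead)

    def test_realized_noise_rms_matches_request(self):
        lay = cm.grid_layout(1, 2)
        rec = cm.synthesize_recording(np.array([]), cm.WavefrontParams(),
                                      cm.SpikeTemplate(), lay,
                                      noise_rms_uV=7.0, duration_s=6.0,
                                      seed=11)
        rms = float(np.std(rec.data[0]))
        assert abs(rms - 7.0) / 7.0 < 0.05

    def test_overlap_warning_for_wide_templates(self):
        lay = cm.grid_layout(2, 2)
        beats = cm.constant_rate_beats(5.0, 1.0)
        with pytest.warns(UserWarning, match="overlap"):
            cm.synthesize_recording(beats, cm.WavefrontParams(),
                                    cm.SpikeTemplate(width_ms=120.0), lay,
                                    noise_rms_uV=0.0, duration_s=1.0)


class TestPresets:
    def test_unknown_preset_lists_available(self):
        with pytest.raises(ValidationError, match="nt_baseline"):
            cm.make_fixture("nope")

    def test_nt_baseline_beats_at_5_7_bps(self):
        fx = cm.make_fixture("nt_baseline", seed=1, duration_s=4.0)
        assert fx.recording.n_channels == 32
        ibi = np.median(np.diff(fx.truth["beat_times_s"]))
        assert abs(1.0 / ibi - 5.7) / 5.7 < 0.02

    def test_stepwise_preset_protocol(self):
        fx = cm.make_fixture("bpac_stepwise", seed=0,
                             synthesize_waveform=False)
        assert [e[2] for e in fx.protocol.epochs] == [0.0, 0.3, 27.0]
        lengths = [(b - a) / 60.0 for a, b, _ in fx.protocol.epochs]
        assert lengths == [5.0, 30.0, 15.0]

    def test_dead_channels_truth_lists_injected_ids(self):
        fx = cm.make_fixture("dead_channels", seed=0, duration_s=2.0)
        assert len(fx.truth["dead_channel_ids"]) == 3
        assert fx.truth["n_live"] == 29

    def test_fixture_write_produces_sidecar(self, tmp_path):
        fx = cm.make_fixture("nt_baseline", seed=0, duration_s=1.0)
        fx.write(tmp_path)
        assert (tmp_path / "recording.h5").exists()
        assert (tmp_path / "protocol.csv").exists()
        assert (tmp_path / "truth.json").exists()
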