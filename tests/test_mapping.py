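"""Beat clustering, activation surfaces and conduction-velocity recovery."""

import numpy as np
import pytest

import cardiomea as cm
from cardiomea.core import ValidationError
from cardiomea.mapping import DegenerateMapError


def _planar_recording(speed, direction=30.0, noise=0.0, duration=2.0,
                      seed=0, layout=None, rate=5.7):
    lay = layout if layout is not None else cm.grid_layout(8, 4)
    wf = cm.WavefrontParams(mode="planar", speed_mm_s=speed,
                            direction_deg=direction)
    beats = cm.constant_rate_beats(rate, duration)
    rec = cm.synthesize_recording(beats, wf, cm.SpikeTemplate(), lay,
                                  noise_rms_uV=noise, sample_rate_hz=25000.0,
                                  duration_s=duration, seed=seed)
    return rec, beats, wf


class TestBeatCluster:
    def test_synchronized_fixture_clusters_every_beat(self):
        rec, beats, _ = _planar_recording(1e6)   # effectively zero delays
        trains = {int(c): cm.detect_peaks(rec.data[i], 25000.0)[0]
                  for i, c in enumerate(rec.channel_ids)}
        clusters = cm.beat_cluster(trains)
        assert len(clusters) == len(beats)
        assert all(len(c) == rec.n_channels for c in clusters)

    def test_planar_wave_clusters_preserve_injected_delays(self):
        rec, beats, wf = _planar_recording(50.0)
        trains = {int(c): cm.detect_peaks(rec.data[i], 25000.0)[0]
                  for i, c in enumerate(rec.channel_ids)}
        clusters = cm.beat_cluster(trains)
        assert len(clusters) == len(beats)
        true_delays = wf.delays_s(rec.layout)
        for cl in clusters:
            rel = np.array([cl[int(c)] for c in rec.channel_ids])
            rel -= rel.min()
            assert np.allclose(rel, true_delays, atol=2 / 25000.0)

    def test_silent_channel_is_excluded_without_error(self):
        rec, beats, _ = _planar_recording(50.0)
        trains = {int(c): cm.detect_peaks(rec.data[i], 25000.0)[0]
                  for i, c in enumerate(rec.channel_ids)}
        trains[0] = np.array([])
        clusters = cm.beat_cluster(trains)
        assert len(clusters) == len(beats)
        assert all(0 not in c for c in clusters)

    def test_too_few_channels_rejected(self):
        with pytest.raises(ValidationError):
            cm.beat_cluster({0: np.array([0.1]), 1: np.array([0.1]),
                             2: np.array([0.1])})


class TestActivationTimes:
    def test_zero_delays_give_zero_times(self):
        cluster = {i: 1.0 for i in range(8)}
        times = cm.activation_times(cluster)
        assert all(v == 0.0 for v in times.values())

    def test_planar_column_times_match_pitch_over_speed(self):
        lay = cm.grid_layout(1, 4)
        rec, _, _ = _planar_recording(50.0, direction=0.0, layout=lay,
                                      duration=1.0)
        trains = {int(c): cm.detect_peaks(rec.data[i], 25000.0)[0]
                  for i, c in enumerate(rec.channel_ids)}
        clusters = cm.beat_cluster(trains)
        times = cm.activation_times(clusters[0])
        expected = {0: 0.0, 1: 4.0, 2: 8.0, 3: 12.0}
        for cid, exp in expected.items():
            assert times[cid] == pytest.approx(exp, abs=0.1)

    @pytest.mark.parametrize("morphology", [-1.0, -0.4, 0.4, 1.0])
    def test_extremum_and_xcorr_agree_on_clean_waveforms(self, morphology):
        lay = cm.grid_layout(4, 4)
        wf = cm.WavefrontParams(mode="planar", speed_mm_s=50.0,
                                direction_deg=20.0)
        beats = cm.constant_rate_beats(5.0, 1.0)
        rec = cm.synthesize_recording(
            beats, wf, cm.SpikeTemplate(morphology=morphology), lay,
            noise_rms_uV=0.0, sample_rate_hz=25000.0, duration_s=1.0)
        trains = {int(c): cm.detect_peaks(rec.data[i], 25000.0)[0]
                  for i, c in enumerate(rec.channel_ids)}
        cl = cm.beat_cluster(trains)[1]
        t_ext = cm.activation_times(cl, method="extremum")
        t_xc = cm.activation_times(cl, method="xcorr", rec=rec)
        for cid in cl:
            assert abs(t_ext[cid] - t_xc[cid]) < 1.0


class TestSurface:
    def test_thin_plate_reproduces_affine_surface(self):
        # planar activation T = x / v is affine: interpolation is exact
        lay = cm.grid_layout(8, 4)
        v_um_ms = 50.0
        times = {int(c): float(x) / v_um_ms
                 for c, x in zip(lay.electrode_ids, lay.x_um)}
        gx, gy, T = cm.interpolate_surface(times, lay)
        xx, _ = np.meshgrid(gx, gy)
        expected = xx / v_um_ms
        scale = expected.max()
        assert np.max(np.abs(T - expected)) < 1e-3 * scale

    def test_constant_times_give_constant_surface(self):
        lay = cm.grid_layout(4, 4)
        times = {int(c): 3.0 for c in lay.electrode_ids}
        _, _, T = cm.interpolate_surface(times, lay)
        assert np.allclose(T, 3.0, atol=1e-9)

    def test_radial_surface_is_monotone_along_rays(self):
        lay = cm.grid_layout(6, 6)
        origin = (500.0, 500.0)
        v = 50.0
        times = {int(c): float(np.hypot(x - origin[0], y - origin[1])) / v
                 for c, x, y in zip(lay.electrode_ids, lay.x_um, lay.y_um)}
        gx, gy, T = cm.interpolate_surface(times, lay)
        ix = np.argmin(np.abs(gx - origin[0]))
        iy = np.argmin(np.abs(gy - origin[1]))
        ray = T[iy, ix:]
        assert np.all(np.diff(ray) > -1e-6)
        # origin recovered within one pitch
        amin = np.unravel_index(np.argmin(T), T.shape)
        assert abs(gx[amin[1]] - origin[0]) <= 200.0
        assert abs(gy[amin[0]] - origin[1]) <= 200.0

    def test_collinear_electrodes_rejected(self):
        lay = cm.grid_layout(1, 5)
        times = {int(c): float(i) for i, c in enumerate(lay.electrode_ids)}
        with pytest.raises(ValidationError, match="collinear"):
            cm.interpolate_surface(times, lay)


class TestVelocityField:
    def test_planar_surface_gives_exact_speed_and_zero_sem(self):
        lay = cm.grid_layout(8, 4)
        v = 50.0
        times = {int(c): float(x) / v
                 for c, x in zip(lay.electrode_ids, lay.x_um)}
        gx, gy, T = cm.interpolate_surface(times, lay)
        _, _, speed, valid, mean, sem, n, direction = cm.velocity_field(
            gx, gy, T, lay.positions())
        assert mean == pytest.approx(50.0, rel=1e-3)
        assert sem < 0.05
        assert abs(direction) < 1.0
        assert n > 0

    def test_constant_surface_is_degenerate(self):
        lay = cm.grid_layout(4, 4)
        times = {int(c): 1.0 for c in lay.electrode_ids}
        gx, gy, T = cm.interpolate_surface(times, lay)
        with pytest.raises(DegenerateMapError):
            cm.velocity_field(gx, gy, T, lay.positions())

    def test_speed_invariant_to_time_offset(self):
        lay = cm.grid_layout(8, 4)
        times = {int(c): float(x) / 50.0
                 for c, x in zip(lay.electrode_ids, lay.x_um)}
        shifted = {c: t + 11.5 for c, t in times.items()}
        m1 = cm.velocity_field(*cm.interpolate_surface(times, lay),
                               lay.positions())
        m2 = cm.velocity_field(*cm.interpolate_surface(shifted, lay),
                               lay.positions())
        assert m1[4] == pytest.approx(m2[4], rel=1e-9)


class TestEndToEnd:
    @pytest.mark.parametrize("speed", [20.0, 50.0, 80.0])
    def test_noiseless_speed_recovery_within_5_percent(self, speed):
        rec, _, _ = _planar_recording(speed, duration=1.0)
        filt = cm.bandpass_filter(rec)
        _, summary = cm.map_recording(filt, max_beats=3)
        assert summary.mean_speed_mm_s == pytest.approx(speed, rel=0.05)
        assert abs(summary.mean_direction_deg - 30.0) < 5.0

    def test_noisy_speed_recovery_within_10_percent(self):
        speeds = []
        for seed in range(20):
            rec, _, _ = _planar_recording(50.0, noise=7.0, duration=1.0,
                                          seed=seed)
            filt = cm.bandpass_filter(rec)
            _, summary = cm.map_recording(filt, max_beats=2)
            speeds.append(summary.mean_speed_mm_s)
        assert abs(np.mean(speeds) - 50.0) / 50.0 < 0.10

    def test_per_beat_speeds_are_stable_over_a_minute(self):
        rec, _, _ = _planar_recording(50.0, noise=7.0, duration=10.0, seed=1)
        filt = cm.bandpass_filter(rec)
        maps, summary = cm.map_recording(filt, max_beats=None)
        per_beat = summary.per_beat_mean_mm_s
        assert len(per_beat) >= 50
        cv = np.std(per_beat) / np.mean(per_beat)
        assert cv < 0.10

    def test_radial_source_recovered_within_one_pitch(self):
        lay = cm.grid_layout(6, 6)
        origin = (600.0, 600.0)
        wf = cm.WavefrontParams(mode="radial", speed_mm_s=50.0,
                                origin_um=origin)
        beats = cm.constant_rate_beats(5.0, 1.0)
        rec = cm.synthesize_recording(beats, wf, cm.SpikeTemplate(), lay,
                                      noise_rms_uV=0.0, duration_s=1.0)
        maps, _ = cm.map_recording(cm.bandpass_filter(rec), max_beats=1)
        m = maps[0]
        amin = np.unravel_index(np.argmin(m.surface_ms), m.surface_ms.shape)
        assert abs(m.grid_x[amin[1]] - origin[0]) <= 200.0
        assert abs(m.grid_y[amin[0]] - origin[1]) <= 200.0


class TestRendering:
    def test_planar_map_renders_png(self, tmp_path, noiseless_planar_recording):
        maps, _ = cm.map_recording(
            cm.bandpass_filter(noiseless_planar_recording), max_beats=1)
        out = tmp_path / "iso.png"
        cm.render_isochronal_map(maps[0], out)
        assert out.exists() and out.stat().st_size > 0
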