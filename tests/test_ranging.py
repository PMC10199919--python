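"""Two-step ranging: dechirp/separate, adaptive band-pass, phase ToF, tracking."""

import numpy as np
import pytest
import scipy.signal

from conftest import synth_frame
from acuheight.signal_model import ChirpConfig, SpeakerArray, generate_chirp
from acuheight.scene_sim import (
    AcousticScene, ClockModel, PropagationPath, Trajectory, render_received,
)
from acuheight.ranging import (
    dechirp_and_separate, adaptive_bandpass, phase_to_tof, track_distances,
    _fir_taps,
)
from acuheight.time_sync import TimeMapping, beacon_align


class TestDechirpAndSeparate:
    def test_beat_peak_at_delay_times_sweep_rate(self, cfg):
        tau = 2.915e-3  # 1 m
        frame = synth_frame(cfg, [tau], speakers=(0,))
        out = dechirp_and_separate(frame, cfg)
        f_expect = cfg.B / cfg.T * tau  # ~271 Hz above speaker 0's base offset
        assert out.peak_freq[0] == pytest.approx(f_expect, abs=cfg.fs / cfg.n_samples)

    def test_three_speakers_at_base_offsets_for_zero_delay(self, cfg):
        frame = synth_frame(cfg, [0.0, 0.0, 0.0])
        out = dechirp_and_separate(frame, cfg)
        base = cfg.B * cfg.shift_fraction
        for i in (1, 2):
            assert out.peak_freq[i] == pytest.approx(
                i * base, abs=1.5 * cfg.fs / cfg.n_samples
            )

    def test_snr_estimate_tracks_rendered_snr(self, cfg, array):
        scene = AcousticScene(
            array=array, cfg=cfg, trajectory=Trajectory.static([0, 0, 0.8]),
            noise_snr_db=20.0,
        )
        res = render_received(scene, 2.0, seed=9)
        snrs = []
        for k in range(5, 40):
            out = dechirp_and_separate(
                res.wave[k * cfg.n_samples : (k + 1) * cfg.n_samples], cfg, array
            )
            snrs.append([out.snr_db[i] for i in array.active])
        mean_snr = np.mean(snrs, axis=0)
        # speakers 1/2 lose a little tone support to the in-frame wrap
        assert mean_snr[0] == pytest.approx(20.0, abs=2.0)

    def test_all_zero_frame_flagged_invalid(self, cfg):
        out = dechirp_and_separate(np.zeros(cfg.n_samples), cfg)
        assert not out.valid and out.peak_freq == {}
        with pytest.raises(ValueError):
            dechirp_and_separate(np.zeros(100), cfg)


class TestAdaptiveBandpass:
    def test_group_delay_lengths_by_snr_regime(self, cfg):
        assert len(_fir_taps(500.0, 15.0, cfg)) == 1501  # 15 ms at 50 kHz
        assert len(_fir_taps(500.0, 5.0, cfg)) == 3001   # 30 ms at 50 kHz
        assert len(_fir_taps(500.0, 10.0, cfg)) == 3001  # boundary: not > 10 dB

    def test_passband_unity_stopband_rejection(self, cfg):
        taps = _fir_taps(500.0, 15.0, cfg)
        w, h = scipy.signal.freqz(taps, worN=8192, fs=cfg.fs)
        gain_db = 20 * np.log10(np.abs(h) + 1e-12)
        at = lambda f: gain_db[np.argmin(np.abs(w - f))]
        assert abs(at(500.0)) < 0.5
        width = 4 / cfg.T  # full passband width
        assert at(500.0 + 3 * width) < -40
        assert at(500.0 - 3 * width) < -40

    def test_group_delay_is_compensated(self, cfg):
        t = np.arange(6000) / cfg.fs
        x = np.exp(2j * np.pi * 500.0 * t)
        y = adaptive_bandpass(x, snr_db=15.0, center_hz=500.0, cfg=cfg)
        mid = slice(2000, 4000)
        phase_err = np.angle(y[mid] / x[mid])
        assert np.abs(phase_err).max() < 0.02  # aligned, not delayed
        with pytest.raises(ValueError):
            adaptive_bandpass(x, snr_db=np.nan, center_hz=500.0, cfg=cfg)


class TestPhaseToTof:
    def test_zero_phase_zero_coarse_gives_zero_delay(self, cfg):
        assert phase_to_tof(0.0, cfg, coarse=0.0) == pytest.approx(0.0, abs=1e-12)

    def test_root_selection_follows_prior_not_coarse(self, cfg):
        from acuheight.signal_model import forward_phase
        td = 2.0e-3
        phi = float(forward_phase(cfg.T / 2, td, cfg))
        wrapped = (phi + np.pi) % (2 * np.pi) - np.pi
        # ambiguity spacing is ~50 us; a prior near the truth disambiguates
        assert phase_to_tof(wrapped, cfg, prior=td + 8e-6, coarse=0.0) == pytest.approx(
            td, abs=1e-7
        )

    def test_returns_in_range_root_of_the_quadratic(self, cfg):
        """The quadratic has two roots; the far one (~0.43 s) lies outside
        the chirp period and must never be returned."""
        from acuheight.signal_model import forward_phase
        for td in (0.5e-3, 3e-3, 10e-3):
            phi = float(forward_phase(cfg.T / 2, td, cfg))
            wrapped = (phi + np.pi) % (2 * np.pi) - np.pi
            out = phase_to_tof(wrapped, cfg, coarse=td + 5e-6)
            assert out is not None and 0.0 <= out <= cfg.T
            assert out == pytest.approx(td, abs=1e-7)


class TestTrackDistances:
    def test_static_scene_distances_flat_and_accurate(self, cfg, array, static_render):
        scene, res = static_render
        rt = track_distances(res.wave, TimeMapping.identity(cfg.fs), cfg, array)
        true_d = array.distances(np.array([0.0, 0.0, 1.0]))[:3]
        est = rt.d_tilde[5:]
        assert rt.valid.all()
        assert np.abs(est - true_d).max() < 2e-3       # within +/-2 mm of truth
        assert np.ptp(est, axis=0).max() < 2e-3        # flat after warm-up

    def test_5cm_step_moves_all_speakers_consistently(self, cfg, array):
        z0, z1 = 1.0, 0.95
        traj = Trajectory(
            np.array([0.0, 2.0, 3.5, 6.0]),
            np.array([[0, 0, z0], [0, 0, z0], [0, 0, z1], [0, 0, z1]]),
        )
        scene = AcousticScene(array=array, cfg=cfg, trajectory=traj)
        res = render_received(scene, 6.0, seed=2)
        rt = track_distances(res.wave, TimeMapping.identity(cfg.fs), cfg, array)
        d_before = rt.d_tilde[(rt.t > 1.0) & (rt.t < 1.9)].mean(axis=0)
        d_after = rt.d_tilde[rt.t > 4.0].mean(axis=0)
        expect = (
            array.distances(np.array([0, 0, z1]))[:3]
            - array.distances(np.array([0, 0, z0]))[:3]
        )
        assert np.abs((d_after - d_before) - expect).max() < 2e-3

    def test_monotone_motion_gives_monotone_distances(self, cfg, array):
        traj = Trajectory(
            np.array([0.0, 1.0, 5.0]),
            np.array([[0, 0, 0.8], [0, 0, 0.8], [0, 0, 1.1]]),
        )
        scene = AcousticScene(array=array, cfg=cfg, trajectory=traj)
        res = render_received(scene, 5.0, seed=3)
        rt = track_distances(res.wave, TimeMapping.identity(cfg.fs), cfg, array)
        moving = (rt.t > 1.1) & (rt.t < 4.9)
        steps = np.diff(rt.d_tilde[moving], axis=0)
        assert steps.min() > -2e-4  # nondecreasing within numerical noise

    def test_occlusion_interval_flags_invalid_and_holds(self, cfg, array):
        # full occlusion: the blocker removes the direct path and leaves no
        # strong coherent reflection (a partial occlusion that leaves a
        # dominant body reflection instead produces plausible-but-wrong
        # distances, which is the IMU gate's problem, not ranging's)
        scene = AcousticScene(
            array=array, cfg=cfg, trajectory=Trajectory.static([0, 0, 1.0]),
            noise_snr_db=20.0,
            occlusions=[(1.5, 2.5, 0.02)],
        )
        res = render_received(scene, 4.0, seed=4)
        rt = track_distances(res.wave, TimeMapping.identity(cfg.fs), cfg, array)
        occluded = (rt.t > 1.6) & (rt.t < 2.4)
        before = (rt.t > 1.0) & (rt.t < 1.45)
        assert not rt.valid[occluded].all(axis=1).any()   # flagged invalid
        held = rt.d_tilde[occluded]
        ref = rt.d_tilde[before].mean(axis=0)
        assert np.abs(held - ref).max() < 2e-3            # values held

    def test_phase_beats_correlation_under_body_multipath(self, cfg, array):
        """Single-path: phase and interpolated cross-correlation agree within
        half a 20 kHz wavelength, with the phase route under 1 mm.  With a
        body reflection the correlation peak degrades while the tracked
        phase stays within 5 mm."""
        def xcorr_distance(wave, cfg):
            tx = generate_chirp(0, cfg).real
            frame = wave[5 * cfg.n_samples : 7 * cfg.n_samples]
            xc = scipy.signal.correlate(frame, tx, "valid")
            k = int(np.argmax(xc[: cfg.n_samples]))
            a, b, c = np.abs(xc[k - 1 : k + 2])
            delta = 0.5 * (a - c) / (a - 2 * b + c) if (a - 2 * b + c) else 0.0
            return (k + delta) / cfg.fs * 343.0

        one = SpeakerArray(L=1e-4)
        truth = 1.0
        clean = AcousticScene(array=one, cfg=cfg,
                              trajectory=Trajectory.static([0, 0, truth]))
        res = render_received(clean, 2.0, seed=5)
        rt = track_distances(res.wave, TimeMapping.identity(cfg.fs), cfg, one)
        d_phase = rt.d_tilde[5:, 0].mean()
        d_xc = xcorr_distance(res.wave, cfg)
        assert abs(d_phase - truth) < 1e-3
        assert abs(d_phase - d_xc) < 343.0 / 20_000.0 / 2  # half wavelength
        assert abs(d_phase - truth) < abs(d_xc - truth) + 1e-6

        mp = AcousticScene(
            array=one, cfg=cfg, trajectory=Trajectory.static([0, 0, truth]),
            paths=[PropagationPath(s, 0.06, 0.5) for s in (0, 1, 2)],
        )
        res2 = render_received(mp, 2.0, seed=5)
        rt2 = track_distances(res2.wave, TimeMapping.identity(cfg.fs), cfg, one)
        # constant unwrap offset is what calibration absorbs; compare modulo it
        d_mp = rt2.d_tilde[5:, 0].mean()
        lam = 343.0 / 20_000.0
        err_phase = abs((d_mp - truth + lam / 2) % lam - lam / 2)
        err_xc = abs(xcorr_distance(res2.wave, cfg) - truth)
        assert err_phase < 5e-3
        assert err_xc > err_phase

    def test_track_csv_round_trip(self, cfg, array, static_render, tmp_path):
        _, res = static_render
        rt = track_distances(res.wave, TimeMapping.identity(cfg.fs), cfg, array)
        p = tmp_path / "track.csv"
        rt.to_csv(str(p))
        from acuheight.ranging import RangeTrack
        back = RangeTrack.from_csv(str(p))
        assert np.allclose(back.d_tilde, rt.d_tilde)
        assert np.array_equal(back.valid, rt.valid)
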