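"""Triangulation, calibration, IMU gating and the full tracker."""

import numpy as np
import pytest

from acuheight.signal_model import ChirpConfig, SpeakerArray
from acuheight.scene_sim import (
    AcousticScene, ClockModel, Trajectory, render_received, scripted_bed_session,
)
from acuheight.ranging import track_distances
from acuheight.time_sync import TimeMapping
from acuheight.localization import (
    CalibrationError, calibrate, triangulate, imu_gate, run_tracker,
    CalibrationOffsets,
)


def exact_distances(array, point):
    return array.distances(np.asarray(point, dtype=float))[list(array.active)]


class TestTriangulate:
    def test_equal_distances_put_device_on_axis(self):
        X, Y, Z = triangulate(0.9, 0.9, 0.9, L=0.1)
        assert X == 0.0 and Y == 0.0 and Z == pytest.approx(0.9)

    def test_far_field_error_within_oracle_bounds(self, array):
        """Exact geometric distances through the far-field formulas versus
        the true position (exact trilateration is the oracle): a typical
        bedside point lands within 1.5 cm laterally and 0.5 cm in height."""
        p = np.array([0.05, -0.03, 0.80])
        d = exact_distances(array, p)
        X, Y, Z = triangulate(*d, array.L)
        assert abs(X - p[0]) < 0.015 and abs(Y - p[1]) < 0.015
        assert abs(Z - p[2]) < 0.005

    def test_far_field_error_bounded_on_position_grid(self, array):
        rng = np.random.default_rng(42)
        for z in np.linspace(0.3, 2.0, 10):
            for _ in range(10):
                p = np.array([*rng.uniform(-0.10, 0.10, 2), z])
                d = exact_distances(array, p)
                X, Y, Z = triangulate(*d, array.L)
                assert abs(X - p[0]) < 0.005 and abs(Y - p[1]) < 0.005
                assert abs(Z - p[2]) < 0.020
                if z >= 0.8:
                    assert abs(Z - p[2]) < 0.008

    def test_height_changes_cancel_the_far_field_bias(self, array):
        """5 cm height steps are recovered within 2 mm across the working
        envelope: the bias of the height formula is nearly constant."""
        for z in np.linspace(0.4, 1.95, 12):
            for xy in [(0, 0), (0.05, -0.03), (0.1, 0.1)]:
                d1 = exact_distances(array, [*xy, z])
                d2 = exact_distances(array, [*xy, z + 0.05])
                Z1 = triangulate(*d1, array.L)[2]
                Z2 = triangulate(*d2, array.L)[2]
                assert abs((Z2 - Z1) - 0.05) < 0.002

    def test_swapping_d2_d3_swaps_x_y(self):
        X1, Y1, _ = triangulate(1.0, 0.98, 1.01, L=0.1)
        X2, Y2, _ = triangulate(1.0, 1.01, 0.98, L=0.1)
        assert X1 == pytest.approx(Y2) and Y1 == pytest.approx(X2)

    def test_inconsistent_distances_flagged(self):
        X, Y, Z = triangulate(1.0, 0.2, 1.0, L=0.1)  # radicand < 0
        assert np.isnan(Z)

    def test_height_invariant_under_array_rotation(self, array):
        """Rotating panel + device 90 degrees about z and relabeling the
        speakers by panel position leaves Z unchanged (exactly on axis; to
        far-field order off axis, since the relabeling swaps the redundant
        fourth corner into the active set)."""
        Rz = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]], dtype=float)
        P = array.positions
        # rotated speaker j lands on the location of original speaker loc[j]
        P_rot = P @ Rz.T
        loc = [int(np.argmin(np.linalg.norm(P - P_rot[j], axis=1))) for j in range(4)]
        # the tracker reads the speakers at panel locations 0,1,2
        reads = [loc.index(k) for k in (0, 1, 2)]
        for p, tol in [(np.array([0.0, 0.0, 1.1]), 1e-12),
                       (np.array([0.06, -0.04, 1.1]), 2e-3)]:
            d = np.linalg.norm(p - P, axis=1)          # rotation preserves these
            Z1 = triangulate(*d[:3], array.L)[2]
            Z2 = triangulate(*d[reads], array.L)[2]
            assert Z2 == pytest.approx(Z1, abs=tol)


@pytest.fixture(scope="module")
def cal_scene(cfg, array):
    ref = np.array([0.0, 0.0, 0.05])
    scene = AcousticScene(array=array, cfg=cfg, trajectory=Trajectory.static(ref))
    res = render_received(scene, 1.5, seed=21)
    rt = track_distances(res.wave, TimeMapping.identity(cfg.fs), cfg, array)
    return ref, rt


class TestCalibrate:
    def test_unbiased_simulator_gives_near_zero_offsets(self, array, cal_scene):
        ref, rt = cal_scene
        offs = calibrate(rt, array, ref)
        assert np.abs(offs.D).max() < 2e-3

    def test_recovers_injected_speaker_offsets(self, cfg, array):
        ref = np.array([0.0, 0.0, 0.05])
        scene = AcousticScene(
            array=array, cfg=cfg, trajectory=Trajectory.static(ref),
            speaker_range_bias=(0.03, 0.03, 0.03, 0.03),
        )
        res = render_received(scene, 1.5, seed=22)
        rt = track_distances(res.wave, TimeMapping.identity(cfg.fs), cfg, array)
        offs = calibrate(rt, array, ref)
        assert np.allclose(offs.D, 0.03, atol=2e-3)

    def test_motion_during_calibration_rejected(self, array, cal_scene):
        ref, rt = cal_scene
        flags = np.zeros(len(rt.frames), dtype=bool)
        flags[4] = True
        with pytest.raises(CalibrationError):
            calibrate(rt, array, ref, motion_flags=flags)

    def test_json_round_trip(self, array, cal_scene):
        ref, rt = cal_scene
        offs = calibrate(rt, array, ref)
        back = CalibrationOffsets.from_json(offs.to_json())
        assert np.allclose(back.D, offs.D)


class TestImuGate:
    rate = 23.0

    def stream(self, segments):
        """Build (t, z, valid, motion) from (duration, z, valid, motion) specs."""
        t, z, valid, motion = [], [], [], []
        t0 = 0.0
        for dur, zz, vv, mm in segments:
            n = int(dur * self.rate)
            tt = t0 + np.arange(n) / self.rate
            t.append(tt)
            z.append(np.full(n, zz, dtype=float))
            valid.append(np.full(n, vv, dtype=bool))
            motion.append(np.full(n, mm, dtype=bool))
            t0 = tt[-1] + 1 / self.rate
        return (np.concatenate(t), np.concatenate(z),
                np.concatenate(valid), np.concatenate(motion))

    def test_occlusion_without_motion_freezes_output(self):
        # static device; an occlusion transient swings the acoustic height
        # wildly but the IMU sees no motion -> output never changes
        t, z, valid, motion = self.stream(
            [(5, 1.00, True, False), (2, 1.30, True, False), (4, 1.00, True, False)]
        )
        gated, state = imu_gate(t, z, valid, motion)
        settled = t > 3.0
        assert np.allclose(gated[settled], 1.00, atol=1e-9)
        assert not state[settled].any()  # idle throughout

    def test_motion_with_clear_path_converges_within_2s(self):
        t, z, valid, motion = self.stream(
            [(5, 1.00, True, False), (1.5, 1.025, True, True), (6, 1.05, True, False)]
        )
        gated, state = imu_gate(t, z, valid, motion)
        t_move_end = 6.5
        after = t > t_move_end + 2.0
        assert np.allclose(gated[after], 1.05, atol=1e-6)

    def test_occlusion_during_motion_tracks_until_stable(self):
        # occlusion persists 3 s past the motion; measurements are invalid
        # until it clears, then the gate settles at the new height
        t, z, valid, motion = self.stream(
            [(5, 1.00, True, False),
             (1.5, 1.02, False, True),   # moving, occluded
             (3.0, 0.70, False, False),  # occluded garbage, motion over
             (6.0, 1.05, True, False)]   # cleared at the new height
        )
        gated, state = imu_gate(t, z, valid, motion)
        occluded = (t > 6.6) & (t < 9.4)
        assert state[occluded].all()                # still actively tracking
        assert np.allclose(gated[t > 12.5], 1.05, atol=1e-6)


class TestRunTracker:
    def test_deterministic_given_seed(self, cfg, array):
        scene = AcousticScene(
            array=array, cfg=cfg, trajectory=Trajectory.static([0, 0, 1.0]),
            noise_snr_db=18.0, clocks=ClockModel(ppm_tx=-20, ppm_rx=20),
        )
        tracks = []
        for _ in range(2):
            res = render_received(scene, 3.0, seed=33)
            tracks.append(run_tracker(res, array, cfg))
        assert np.array_equal(tracks[0].Z, tracks[1].Z)
        assert np.array_equal(tracks[0].h_cm, tracks[1].h_cm)

    def test_bed_step_recovered_as_height_gain(self, cfg, array):
        traj = scripted_bed_session([0.0, 5.0], dwell=6.0, start_z=1.0)
        scene = AcousticScene(array=array, cfg=cfg, trajectory=traj,
                              noise_snr_db=25.0)
        res = render_received(scene, 13.0, seed=34)
        ht = run_tracker(res, array, cfg, postprocess=False)
        h0 = np.nanmean(ht.h_cm[(ht.t > 2) & (ht.t < 5.5)])
        h1 = np.nanmean(ht.h_cm[ht.t > 10.0])
        assert h1 - h0 == pytest.approx(5.0, abs=0.5)
        # gate idle on the plateaus, active through the transition
        assert ht.gate_state[(ht.t > 6.1) & (ht.t < 7.2)].any()

    def test_height_track_csv_round_trip(self, cfg, array, tmp_path):
        scene = AcousticScene(array=array, cfg=cfg,
                              trajectory=Trajectory.static([0, 0, 1.0]))
        res = render_received(scene, 2.0, seed=35)
        ht = run_tracker(res, array, cfg)
        p = tmp_path / "height.csv"
        ht.to_csv(str(p))
        from acuheight.localization import HeightTrack
        back = HeightTrack.from_csv(str(p))
        assert np.allclose(back.Z, ht.Z, equal_nan=True)
        assert np.array_equal(back.gate_state, ht.gate_state)
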