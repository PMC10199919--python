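"""Method-agreement statistics and the benchmark evaluation suite.

`agreement` reports the usual method-comparison battery — bias, SD of the
differences, median absolute difference, empirical CDF of |differences|,
two-way random absolute-agreement single-measure intraclass correlation
(ICC(2,1)) and an OLS fit.

`benchmark_suite` reproduces the bench-style evaluation on synthetic
scenes: a static-position accuracy sweep (0.2–2 m), the 10-minute
static-drift scene under three correction regimes (none, beacon sync,
beacon sync + regression post-processing), and a full bed-session
pipeline ending in corrected mean arterial pressures.
"""

from __future__ import annotations

from dataclasses import dataclass
import json
import os

import numpy as np
import pandas as pd

from .signal_model import ChirpConfig, SpeakerArray
from .scene_sim import (
    AcousticScene, ClockModel, PropagationPath, Trajectory, render_received,
    scripted_bed_session, simulate_pressure_session,
)
from .time_sync import beacon_align, postprocess_drift
from .ranging import track_distances
from .localization import calibrate, triangulate, run_tracker
from .pressure import correct_session

__all__ = [
    "AgreementReport",
    "agreement",
    "static_sweep",
    "drift_ladder",
    "bed_session_eval",
    "benchmark_suite",
]


# ---------------------------------------------------------------------------
# agreement statistics
# ---------------------------------------------------------------------------

def icc_2_1(data: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``data`` is (n subjects, k raters).  Classic mean-squares form:
    ``(MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)``.
    """
    x = np.asarray(data, dtype=float)
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("ICC needs at least 2 subjects and 2 raters")
    gm = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * np.sum((row_means - gm) ** 2)
    ssc = n * np.sum((col_means - gm) ** 2)
    sst = np.sum((x - gm) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return 1.0
    return float((msr - mse) / denom)


@dataclass
class AgreementReport:
    """Method-agreement summary between an estimate and a reference series."""

    bias: float
    sd: float
    median_abs: float
    cdf_abs: np.ndarray        # sorted |differences|
    cdf_q: np.ndarray          # matching empirical quantiles
    icc: float
    fit_slope: float
    fit_intercept: float
    n: int

    def to_json(self) -> str:
        return json.dumps(
            {"bias": self.bias, "sd": self.sd, "median_abs": self.median_abs,
             "icc": self.icc, "fit_slope": self.fit_slope,
             "fit_intercept": self.fit_intercept, "n": self.n}
        )


def agreement(est, ref) -> AgreementReport:
    """Agreement battery between paired measurement series.

    Differences are est − ref; the ICC treats the two methods as raters in
    a two-way random-effects absolute-agreement model.
    """
    est = np.asarray(est, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if est.shape != ref.shape:
        raise ValueError("series length mismatch")
    if est.size < 3:
        raise ValueError("need at least 3 paired measurements")
    diff = est - ref
    cdf_abs = np.sort(np.abs(diff))
    cdf_q = np.arange(1, diff.size + 1) / diff.size
    if np.allclose(ref, ref[0]):
        slope, intercept = 0.0, float(np.mean(est))
    else:
        slope, intercept = np.polyfit(ref, est, 1)
    return AgreementReport(
        bias=float(np.mean(diff)),
        sd=float(np.std(diff, ddof=1)),
        median_abs=float(np.median(np.abs(diff))),
        cdf_abs=cdf_abs,
        cdf_q=cdf_q,
        icc=icc_2_1(np.column_stack([est, ref])),
        fit_slope=float(slope),
        fit_intercept=float(intercept),
        n=int(diff.size),
    )


# ---------------------------------------------------------------------------
# benchmark scenes
# ---------------------------------------------------------------------------

#: standard bench conditions
CAL_STANDOFF = np.array([0.0, 0.0, 0.05])  # assumed calibration spot, m
CAL_PLACEMENT_SD = 0.002   # m, per-axis error of hand-placing the device there
MOVE_SPEED = 0.10          # m/s, hand-carry speed between positions
CAL_DWELL = 1.5            # s
# 40 ppm relative drift; the receiver's crystal runs fast so the apparent
# delay of an unsynchronized tracker grows with time
BENCH_CLOCKS = dict(ppm_tx=-20.0, ppm_rx=20.0)


def _draw_paths(rng: np.random.Generator, speakers=(0, 1, 2),
                excess_range=(0.05, 0.20), amp_range=(0.1, 0.5)) -> list[PropagationPath]:
    """One independent body reflection per speaker."""
    return [
        PropagationPath(s, float(rng.uniform(*excess_range)), float(rng.uniform(*amp_range)))
        for s in speakers
    ]


def _cal_then(target_traj_knots_t, target_traj_knots_p, actual_ref, rng) -> Trajectory:
    """Prepend the calibration dwell and a hand-carry move to a trajectory."""
    t0 = CAL_DWELL
    first = target_traj_knots_p[0]
    move = max(float(np.linalg.norm(first - actual_ref)) / MOVE_SPEED, 1.0)
    kt = np.concatenate([[0.0, t0], t0 + move + np.asarray(target_traj_knots_t)])
    kp = np.vstack([actual_ref, actual_ref, target_traj_knots_p])
    return Trajectory(kt, kp), t0 + move


def _single_position_error(
    scene_rng: np.random.Generator, array: SpeakerArray, cfg: ChirpConfig,
    test_dwell: float = 2.0,
) -> dict:
    """One bench measurement: calibrate at the panel, carry to a random
    position 0.2–2 m away, dwell, and compare the triangulated position
    with the ground truth."""
    r = scene_rng.uniform(0.2, 2.0)
    th = scene_rng.uniform(0.0, np.radians(15.0))
    ph = scene_rng.uniform(0.0, 2 * np.pi)
    pos = np.array(
        [r * np.sin(th) * np.cos(ph), r * np.sin(th) * np.sin(ph), r * np.cos(th)]
    )
    actual_ref = CAL_STANDOFF + scene_rng.normal(0.0, CAL_PLACEMENT_SD, 3)
    (traj, t_arrive) = _cal_then(np.array([0.0, test_dwell]), np.vstack([pos, pos]),
                                 actual_ref, scene_rng)
    scene = AcousticScene(
        array=array, cfg=cfg, trajectory=traj,
        paths=_draw_paths(scene_rng),
        noise_snr_db=float(scene_rng.uniform(15.0, 25.0)),
        clocks=ClockModel(**BENCH_CLOCKS),
    )
    duration = traj.knots_t[-1]
    res = render_received(scene, duration, seed=int(scene_rng.integers(2**31)))
    mapping = beacon_align(res.beacons, scene.clocks, cfg.fs,
                           sync_window=min(10.0, duration))
    rt = track_distances(res.wave, mapping, cfg, array)

    n_cal = int(CAL_DWELL / cfg.T)
    cal_track = _slice_track(rt, slice(0, n_cal))
    offs = calibrate(cal_track, array, CAL_STANDOFF, warmup_frames=5)

    n_t0 = int((t_arrive + 0.3) / cfg.T)
    sel = slice(n_t0, len(rt.frames))
    d_abs = rt.d_tilde[sel].mean(axis=0) - offs.D
    X, Y, Z = triangulate(*d_abs, array.L)
    return {
        "x_err_cm": float((X - pos[0]) * 100), "y_err_cm": float((Y - pos[1]) * 100),
        "z_err_cm": float((Z - pos[2]) * 100), "range_m": float(r),
        "valid_frac": float(rt.valid.mean()),
    }


def _slice_track(rt, sl):
    from .ranging import RangeTrack
    return RangeTrack(rt.frames[sl], rt.t[sl], rt.d_tilde[sl], rt.snr_db[sl],
                      rt.valid[sl], rt.speakers)


def static_sweep(
    seed: int, n_scenes: int = 100,
    array: SpeakerArray | None = None, cfg: ChirpConfig | None = None,
) -> pd.DataFrame:
    """Per-axis absolute position errors over seeded random bench scenes."""
    array = array or SpeakerArray()
    cfg = cfg or ChirpConfig()
    rows = []
    for j in range(n_scenes):
        rng = np.random.default_rng([seed, j])
        rows.append(_single_position_error(rng, array, cfg))
    return pd.DataFrame(rows)


def drift_ladder(
    seed: int, duration: float = 600.0, position=(0.0, 0.0, 0.35),
    array: SpeakerArray | None = None, cfg: ChirpConfig | None = None,
) -> dict:
    """Accumulated-drift curves for a static device under three regimes.

    Renders one recording with 40 ppm relative clock drift and processes it
    (a) with no synchronization, (b) with beacon alignment, (c) with beacon
    alignment plus the chunked-regression post-processing.  Returns the
    three drift curves (cm vs time) and their accumulated-drift summaries.
    """
    array = array or SpeakerArray()
    cfg = cfg or ChirpConfig()
    scene = AcousticScene(
        array=array, cfg=cfg, trajectory=Trajectory.static(np.asarray(position)),
        noise_snr_db=25.0, clocks=ClockModel(**BENCH_CLOCKS),
    )
    res = render_received(scene, duration, seed=seed)
    out = {}
    for name, kw in [
        ("uncorrected", dict(use_beacons=False, postprocess=False)),
        ("beacon", dict(use_beacons=True, postprocess=False)),
        ("beacon_postprocess", dict(use_beacons=True, postprocess=True)),
    ]:
        ht = run_tracker(res, array, cfg, calibration=None, gate=False, **kw)
        z = ht.Z
        okv = np.isfinite(z)
        z0 = np.nanmean(z[okv][: int(5 / cfg.T)])
        drift_cm = (z - z0) * 100.0
        tail = drift_cm[okv][-int(5 / cfg.T):]
        out[name] = {
            "t": ht.t, "drift_cm": drift_cm,
            "max_abs_cm": float(np.nanmax(np.abs(drift_cm))),
            "final_abs_cm": float(np.abs(np.nanmean(tail))),
        }
    return out


def bed_session_eval(
    seed: int,
    levels_cm=tuple(range(0, 50, 5)),
    dwell: float = 45.0,
    start_z: float = 1.5,
    map0: float = 85.0,
    device_noise_sd: float = 0.0,
    array: SpeakerArray | None = None,
    cfg: ChirpConfig | None = None,
) -> dict:
    """End-to-end clinical-protocol analogue.

    Calibrate at the panel, attach at ``start_z``, then step the bed
    through ``levels_cm`` with ``dwell`` seconds per plateau; track height,
    simulate the two-transducer pressures and correct the stationary
    transducer's MAP with the tracked height change.  Returns the per-
    plateau Δh and MAP error table and the tracked HeightTrack.
    """
    array = array or SpeakerArray()
    cfg = cfg or ChirpConfig()
    rng = np.random.default_rng([seed, 7])
    bed = scripted_bed_session(levels_cm, dwell, start_z=start_z,
                               respiration_amp=0.005)
    actual_ref = CAL_STANDOFF + rng.normal(0.0, CAL_PLACEMENT_SD, 3)
    traj, t_bed0 = _cal_then(bed.knots_t, bed.knots_pos, actual_ref, rng)
    traj.respiration_amp = bed.respiration_amp
    traj.respiration_rate = bed.respiration_rate
    scene = AcousticScene(
        array=array, cfg=cfg, trajectory=traj, paths=_draw_paths(rng),
        noise_snr_db=20.0, clocks=ClockModel(**BENCH_CLOCKS),
    )
    duration = float(traj.knots_t[-1] + dwell)
    res = render_received(scene, duration, seed=int(rng.integers(2**31)))

    mapping = beacon_align(res.beacons, scene.clocks, cfg.fs, sync_window=10.0)
    rt = track_distances(res.wave, mapping, cfg, array)
    n_cal = int(CAL_DWELL / cfg.T)
    offs = calibrate(_slice_track(rt, slice(0, n_cal)), array, CAL_STANDOFF,
                     warmup_frames=5)
    ht = run_tracker(res, array, cfg, calibration=offs)

    # plateau measurement windows: last 60% of each dwell
    n_levels = len(levels_cm)
    plateau_t0 = [t_bed0 + k * (dwell + 1.5) for k in range(n_levels)]
    windows = [(t0 + 0.4 * dwell, t0 + dwell) for t0 in plateau_t0]

    # simulated pressures at 1 Hz inside the measurement windows
    t_press, dh_true = [], []
    for lev, (w0, w1) in zip(levels_cm, windows):
        tt = np.arange(w0, w1, 1.0)
        t_press.append(tt)
        dh_true.append(np.full(tt.size, float(lev - levels_cm[0])))
    t_press = np.concatenate(t_press)
    dh_true = np.concatenate(dh_true)
    press = simulate_pressure_session(
        t_press, dh_true, seed=int(rng.integers(2**31)), map0=map0,
        device_noise_sd=device_noise_sd,
    )
    corr = correct_session(press, ht.t, ht.h_cm, baseline_t=windows[0])

    rows = []
    h_bar0 = None
    for lev, (w0, w1) in zip(levels_cm, windows):
        m = (ht.t >= w0) & (ht.t <= w1)
        h_bar = float(np.nanmean(ht.h_cm[m]))
        if h_bar0 is None:
            h_bar0 = h_bar
        pm = (corr["t"] >= w0) & (corr["t"] <= w1)
        map_err = float((corr.loc[pm, "MAP_a"] - corr.loc[pm, "MAP_true"]).mean())
        rows.append({
            "level_cm": float(lev),
            "dh_true_cm": float(lev - levels_cm[0]),
            "dh_est_cm": h_bar - h_bar0,
            "dh_err_cm": h_bar - h_bar0 - float(lev - levels_cm[0]),
            "map_a_minus_truth_mmhg": map_err,
        })
    table = pd.DataFrame(rows)
    return {"plateaus": table, "track": ht, "pressures": corr,
            "delta_transducer": corr.attrs["delta_transducer"]}


def benchmark_suite(
    seed: int, outdir: str | None = None,
    n_scenes: int = 100, drift_duration: float = 600.0, dwell: float = 45.0,
) -> dict:
    """Run the full bench battery and optionally write CSV/JSON reports."""
    sweep = static_sweep(seed, n_scenes=n_scenes)
    ladder = drift_ladder(seed + 1, duration=drift_duration)
    bed = bed_session_eval(seed + 2, dwell=dwell)
    summary = {
        "sweep_median_abs_z_cm": float(sweep["z_err_cm"].abs().median()),
        "sweep_median_abs_x_cm": float(sweep["x_err_cm"].abs().median()),
        "sweep_median_abs_y_cm": float(sweep["y_err_cm"].abs().median()),
        "drift_uncorrected_max_cm": ladder["uncorrected"]["max_abs_cm"],
        "drift_beacon_max_cm": ladder["beacon"]["max_abs_cm"],
        "drift_postprocess_final_cm": ladder["beacon_postprocess"]["final_abs_cm"],
        "bed_max_abs_dh_err_cm": float(bed["plateaus"]["dh_err_cm"].abs().max()),
        "bed_max_abs_map_err_mmhg": float(
            bed["plateaus"]["map_a_minus_truth_mmhg"].abs().max()
        ),
    }
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        sweep.to_csv(os.path.join(outdir, "static_sweep.csv"), index=False)
        pd.DataFrame(
            {"t": ladder["uncorrected"]["t"],
             "uncorrected_cm": ladder["uncorrected"]["drift_cm"],
             "beacon_cm": ladder["beacon"]["drift_cm"],
             "beacon_postprocess_cm": ladder["beacon_postprocess"]["drift_cm"]}
        ).to_csv(os.path.join(outdir, "drift_curves.csv"), index=False)
        bed["plateaus"].to_csv(os.path.join(outdir, "bed_session.csv"), index=False)
        with open(os.path.join(outdir, "summary.json"), "w") as f:
            json.dump(summary, f, indent=2)
    return {"sweep": sweep, "ladder": ladder, "bed": bed, "summary": summary}
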