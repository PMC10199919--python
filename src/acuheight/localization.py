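"""3-D position and height from three per-speaker distances.

The far-field triangulation uses the distance differences across the
square panel's baselines:

    X = d̄ (d1 - d2) / L,   Y = d̄ (d1 - d3) / L,   Z = sqrt(d̄² - X² - Y²)

with d̄ the mean of the three absolute distances and L the adjacent-speaker
separation.  Absolute distances come from the raw tracked distances minus
per-speaker calibration offsets D_i measured with the device held at a
known reference spot by the array.  An IMU gate freezes the reported
height whenever the accelerometer sees no motion, which makes the output
immune to acoustic occlusions of a stationary patient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np
import pandas as pd

from .signal_model import ChirpConfig, SpeakerArray
from .scene_sim import RenderResult, ClockModel
from .ranging import RangeTrack, track_distances, repair_cycle_slips
from .time_sync import beacon_align, postprocess_drift, TimeMapping

__all__ = [
    "CalibrationOffsets",
    "HeightTrack",
    "CalibrationError",
    "calibrate",
    "triangulate",
    "imu_gate",
    "run_tracker",
]


class CalibrationError(ValueError):
    """Raised when the device moved during the calibration window."""


@dataclass
class CalibrationOffsets:
    """Per-speaker initial distance offsets D_i (m) and where they were taken."""

    D: np.ndarray                 # (3,) m, one per active speaker
    reference_position: np.ndarray  # (3,) m

    def to_json(self) -> str:
        return json.dumps(
            {"D": np.asarray(self.D).tolist(),
             "reference_position": np.asarray(self.reference_position).tolist()}
        )

    @classmethod
    def from_json(cls, s: str) -> "CalibrationOffsets":
        d = json.loads(s)
        return cls(np.asarray(d["D"]), np.asarray(d["reference_position"]))


def calibrate(
    track: RangeTrack,
    array: SpeakerArray,
    reference_position,
    motion_flags: np.ndarray | None = None,
    warmup_frames: int = 5,
    min_frames: int = 10,
) -> CalibrationOffsets:
    """Calibration offsets from raw readings at a known static position.

    ``D_i`` is the mean raw reading minus the true geometric distance, so
    subsequent ``d_i = d̃_i - D_i`` are absolute.  ``motion_flags`` (one per
    frame, from the accelerometer) reject a calibration during which the
    device moved.
    """
    ref = np.asarray(reference_position, dtype=float)
    if motion_flags is not None and np.any(np.asarray(motion_flags, bool)):
        raise CalibrationError("device moved during calibration; reposition and retry")
    sel = np.arange(len(track.frames)) >= warmup_frames
    sel &= track.valid.all(axis=1)
    if sel.sum() < min_frames:
        raise CalibrationError(
            f"calibration needs >= {min_frames} valid static frames, got {int(sel.sum())}"
        )
    true_d = array.distances(ref)[list(track.speakers)]
    D = track.d_tilde[sel].mean(axis=0) - true_d
    return CalibrationOffsets(D, ref)


def triangulate(d1, d2, d3, L: float):
    """Far-field triangulation of the device from three absolute distances.

    Accepts scalars or arrays.  Returns ``(X, Y, Z)``; geometrically
    inconsistent inputs (negative radicand, non-positive mean distance)
    yield ``Z = nan`` for those entries.
    """
    d1, d2, d3 = (np.asarray(a, dtype=float) for a in (d1, d2, d3))
    d_bar = (d1 + d2 + d3) / 3.0
    X = d_bar * (d1 - d2) / L
    Y = d_bar * (d1 - d3) / L
    rad = d_bar**2 - X**2 - Y**2
    bad = (rad < 0) | (d_bar <= 0)
    Z = np.sqrt(np.where(bad, np.nan, rad))
    return X, Y, Z


#: stability criterion for leaving the active (tracking) state
STABILITY_WINDOW_S = 2.0
STABILITY_SD_CM = 0.3


def imu_gate(
    t: np.ndarray,
    z: np.ndarray,
    valid: np.ndarray,
    motion: np.ndarray,
    stability_window: float = STABILITY_WINDOW_S,
    stability_sd_cm: float = STABILITY_SD_CM,
) -> tuple[np.ndarray, np.ndarray]:
    """Gate a height stream on accelerometer motion.

    While the IMU reports no motion the output is held constant regardless
    of what the acoustics say (occlusions of a stationary device cannot
    move the reported height).  Motion switches to active tracking; the
    gate returns to idle only once motion has stopped and the last
    ``stability_window`` seconds of *valid* measurements are dense and
    quiet (sd below ``stability_sd_cm``) — so if an occlusion coincides
    with motion, tracking continues until the estimate stabilizes.

    Returns ``(gated_z, gate_state)`` with state 1 = active, 0 = idle.
    """
    t = np.asarray(t, float)
    z = np.asarray(z, float)
    valid = np.asarray(valid, bool)
    motion = np.asarray(motion, bool)
    n = t.size
    gated = np.empty(n)
    state = np.zeros(n, dtype=int)
    held = np.nan
    active = True  # acquire until first stable fix
    dt = np.median(np.diff(t)) if n > 1 else 1.0
    win = max(int(round(stability_window / dt)), 2)
    for k in range(n):
        if not active and motion[k]:
            active = True
        if active:
            if valid[k] and np.isfinite(z[k]):
                held = z[k]
            state[k] = 1
            gated[k] = held
            if not motion[k] and k + 1 >= win:
                sl = slice(k + 1 - win, k + 1)
                ok = valid[sl] & np.isfinite(z[sl])
                if ok.sum() >= 0.8 * win and np.std(z[sl][ok]) * 100.0 < stability_sd_cm:
                    held = float(np.mean(z[sl][ok]))
                    gated[k] = held
                    active = False
                    state[k] = 0
        else:
            gated[k] = held
    return gated, state


@dataclass
class HeightTrack:
    """Tracker output: per-frame position, gated height and bookkeeping.

    ``h_cm`` is the height *change* of the device since the session start,
    positive upward (the panel hangs above the patient, so height gain is a
    decrease of Z).  ``unreliable`` marks frames more than 5 s past the
    last fully valid frame.
    """

    frames: np.ndarray
    t: np.ndarray
    X: np.ndarray
    Y: np.ndarray
    Z: np.ndarray              # gated height coordinate, m
    h_cm: np.ndarray
    gate_state: np.ndarray     # 1 active / 0 idle
    valid: np.ndarray
    unreliable: np.ndarray = field(default=None)

    def to_csv(self, path: str) -> None:
        pd.DataFrame(
            {"frame": self.frames, "t": self.t, "X": self.X, "Y": self.Y,
             "Z": self.Z, "h_cm": self.h_cm, "gate_state": self.gate_state,
             "valid": self.valid, "unreliable": self.unreliable}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str) -> "HeightTrack":
        df = pd.read_csv(path)
        return cls(
            df["frame"].to_numpy(), df["t"].to_numpy(), df["X"].to_numpy(),
            df["Y"].to_numpy(), df["Z"].to_numpy(), df["h_cm"].to_numpy(),
            df["gate_state"].to_numpy(), df["valid"].to_numpy(dtype=bool),
            df["unreliable"].to_numpy(dtype=bool),
        )


def _motion_at_frames(imu: pd.DataFrame, t_frames: np.ndarray) -> np.ndarray:
    """Any motion flag within each frame interval (nearest-sample fallback)."""
    t_imu = imu["t"].to_numpy()
    flags = imu["motion_flag"].to_numpy(dtype=bool)
    idx = np.searchsorted(t_imu, t_frames)
    idx = np.clip(idx, 0, len(t_imu) - 1)
    out = flags[idx]
    idx2 = np.clip(idx - 1, 0, len(t_imu) - 1)
    return out | flags[idx2]


def run_tracker(
    render: RenderResult,
    array: SpeakerArray,
    cfg: ChirpConfig,
    calibration: CalibrationOffsets | None = None,
    clocks: ClockModel | None = None,
    c: float = 343.0,
    use_beacons: bool = True,
    postprocess: bool = True,
    gate: bool = True,
    sync_window: float = 10.0,
) -> HeightTrack:
    """Full pipeline: beacon alignment → two-step ranging → calibration
    subtraction → residual-drift post-processing → triangulation → IMU gate.

    With ``calibration=None`` the offsets are taken as zero (relative
    tracking only).  ``use_beacons``/``postprocess``/``gate`` switch the
    corresponding stages off for ablation studies.
    """
    if clocks is None:
        clocks = render.scene.clocks if render.scene is not None else ClockModel()
    if use_beacons:
        mapping = beacon_align(render.beacons, clocks, cfg.fs, sync_window=sync_window)
    else:
        mapping = TimeMapping.identity(cfg.fs)
    rt = track_distances(render.wave, mapping, cfg, array, c=c)
    rt = repair_cycle_slips(rt, c=c)

    d_abs = rt.d_tilde.copy()
    if calibration is not None:
        d_abs = d_abs - np.asarray(calibration.D)[None, :]
    if postprocess:
        for j in range(3):
            ok = np.isfinite(d_abs[:, j])
            if ok.sum() > 2:
                d_abs[ok, j], _ = postprocess_drift(rt.t[ok], d_abs[ok, j])

    X, Y, Z = triangulate(d_abs[:, 0], d_abs[:, 1], d_abs[:, 2], array.L)
    frame_valid = rt.valid.all(axis=1) & np.isfinite(Z)

    motion = _motion_at_frames(render.imu, rt.t)
    if gate:
        Zg, state = imu_gate(rt.t, Z, frame_valid, motion)
    else:
        Zg, state = Z, np.ones(len(Z), dtype=int)

    finite = np.flatnonzero(np.isfinite(Zg))
    z0 = Zg[finite[0]] if finite.size else np.nan
    h_cm = (z0 - Zg) * 100.0

    # unreliable: > 5 s since the last fully valid frame
    unreliable = np.zeros(len(rt.t), dtype=bool)
    last_good = -np.inf
    for k in range(len(rt.t)):
        if frame_valid[k]:
            last_good = rt.t[k]
        unreliable[k] = rt.t[k] - last_good > 5.0
    return HeightTrack(
        rt.frames, rt.t, X, Y, Zg, h_cm, state, frame_valid, unreliable
    )
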