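"""FMCW transmit signals and speaker-array geometry.

The localizer emits near-ultrasonic linear chirps (18-22 kHz, 43 ms) from
three of the four speakers mounted on the corners of a square panel.  Each
speaker transmits the same chirp shifted in time by a fixed fraction of the
chirp period, so a single dechirp operation at the receiver separates the
speakers into disjoint beat-frequency slots.

This module owns the analytic chirp model and the forward phase model of a
delayed chirp after dechirping, which the ranging stage inverts to read
time of flight from phase.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "ChirpConfig",
    "SpeakerArray",
    "generate_chirp",
    "chirp_phase",
    "forward_phase",
]


@dataclass(frozen=True)
class ChirpConfig:
    """Parameters of the frequency-modulated continuous-wave chirp bank.

    Attributes
    ----------
    f0, f1 : float
        Start and end frequency of the sweep, Hz.
    T : float
        Chirp duration, s.  The chirp repeats with period ``T``.
    n_speakers : int
        Number of speakers in the array (the transmit schedule assigns one
        time-shifted chirp per speaker).
    shift_fraction : float
        Per-speaker time shift as a fraction of ``T``; speaker ``i`` is
        delayed by ``i * shift_fraction * T``.
    fs : float
        Sample rate, Hz.
    """

    f0: float = 18_000.0
    f1: float = 22_000.0
    T: float = 0.043
    n_speakers: int = 4
    shift_fraction: float = 0.2
    fs: float = 50_000.0

    def __post_init__(self) -> None:
        if not self.f1 > self.f0:
            raise ValueError(f"f1 ({self.f1}) must exceed f0 ({self.f0})")
        if self.fs <= 2.0 * self.f1:
            raise ValueError(
                f"fs={self.fs} violates Nyquist for f1={self.f1} (need fs > 2*f1)"
            )
        if not (0.0 < self.shift_fraction < 1.0):
            raise ValueError("shift_fraction must lie in (0, 1)")
        if self.T <= 0:
            raise ValueError("chirp duration T must be positive")
        if self.n_speakers < 1:
            raise ValueError("need at least one speaker")

    @property
    def B(self) -> float:
        """Sweep bandwidth f1 - f0, Hz."""
        return self.f1 - self.f0

    @property
    def n_samples(self) -> int:
        """Samples per chirp period at the nominal rate."""
        return int(round(self.T * self.fs))

    @property
    def frame_rate(self) -> float:
        """Chirp repetition rate 1/T, Hz (also the tracker output rate)."""
        return 1.0 / self.T

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "ChirpConfig":
        return cls(**json.loads(s))


def _square_corners(L: float) -> np.ndarray:
    # Corner order chosen so that Eq-style difference pairs (d1-d2) and
    # (d1-d3) carry the sign of the device's true x and y respectively.
    h = L / 2.0
    return np.array(
        [
            [-h, -h, 0.0],
            [+h, -h, 0.0],
            [-h, +h, 0.0],
            [+h, +h, 0.0],
        ]
    )


@dataclass(frozen=True)
class SpeakerArray:
    """Square speaker panel in the z = 0 plane, centred at the origin.

    ``L`` is the adjacent-speaker separation in metres; the z axis points
    from the panel toward the patient.  Exactly three of the four speakers
    transmit; the fourth is redundancy.
    """

    L: float = 0.1
    active: tuple[int, int, int] = (0, 1, 2)

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ValueError("speaker separation L must be positive")
        if len(set(self.active)) != 3 or not all(0 <= i < 4 for i in self.active):
            raise ValueError("active must name exactly 3 distinct speakers in 0..3")

    @property
    def positions(self) -> np.ndarray:
        """(4, 3) speaker coordinates, m."""
        return _square_corners(self.L)

    def distances(self, point: np.ndarray) -> np.ndarray:
        """Euclidean distance from each of the 4 speakers to ``point``.

        ``point`` may be a single (3,) coordinate or an (n, 3) batch.
        """
        p = np.atleast_2d(np.asarray(point, dtype=float))
        d = np.linalg.norm(p[:, None, :] - self.positions[None, :, :], axis=2)
        return d[0] if np.ndim(point) == 1 else d

    def to_json(self) -> str:
        return json.dumps({"L": self.L, "active": list(self.active)})

    @classmethod
    def from_json(cls, s: str) -> "SpeakerArray":
        d = json.loads(s)
        return cls(L=d["L"], active=tuple(d["active"]))


def chirp_phase(t, cfg: ChirpConfig, i: int = 0) -> np.ndarray:
    """Instantaneous phase (radians) of speaker ``i``'s chirp at time ``t``.

    The chirp is periodic with period ``T``; the phase argument restarts at
    every chirp boundary.  ``t`` may be an array.
    """
    if not 0 <= i < cfg.n_speakers:
        raise ValueError(f"speaker index {i} out of range 0..{cfg.n_speakers - 1}")
    u = np.mod(np.asarray(t, dtype=float) - i * cfg.shift_fraction * cfg.T, cfg.T)
    return 2.0 * np.pi * (cfg.f0 * u + cfg.B / (2.0 * cfg.T) * u * u)


def generate_chirp(i: int, cfg: ChirpConfig) -> np.ndarray:
    """Complex baseband chirp of speaker ``i`` over one period.

    Returns ``exp(j*2*pi*(f0*(t - i*s*T) + (B/2T)*(t - i*s*T)^2))`` on the
    sample grid ``t = n / fs``, wrapped periodically over [0, T).  The real
    part is the waveform physically emitted (and exported to WAV).
    """
    t = np.arange(cfg.n_samples) / cfg.fs
    return np.exp(1j * chirp_phase(t, cfg, i))


def forward_phase(t, t_d, cfg: ChirpConfig) -> np.ndarray:
    """Dechirped-signal phase of a path arriving ``t_d`` seconds after the
    reference, sampled at in-chirp time ``t`` (radians, unwrapped).

    phi(t) = -2*pi * (B/T * t * t_d + f0 * t_d - B/(2T) * t_d**2)

    The ranging stage inverts this quadratic in ``t_d`` to turn a measured
    phase into a time of flight.
    """
    t_d_arr = np.asarray(t_d, dtype=float)
    if np.any(t_d_arr < 0) or np.any(t_d_arr > cfg.T):
        raise ValueError("time of arrival t_d must lie in [0, T]")
    t = np.asarray(t, dtype=float)
    return -2.0 * np.pi * (
        cfg.B / cfg.T * t * t_d_arr + cfg.f0 * t_d_arr - cfg.B / (2.0 * cfg.T) * t_d_arr ** 2
    )
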