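"""Per-speaker distance recovery from the received waveform.

Two-step process per chirp frame:

Step 1 — dechirp and band-pass.  The frame is multiplied by the reference
chirp, so the path from speaker ``i`` with time of arrival ``t_d`` appears
as a beat tone at ``(B/T) * (t_d + i*shift*T)`` Hz whose complex amplitude
carries the forward-model phase (conjugated).  A DFT locates the
per-speaker peaks near their base offsets ``i * B * shift_fraction``; a
linear-phase FIR band-pass around each peak rejects distant multipath.
The FIR group delay adapts to the measured SNR: 15 ms above 10 dB, 30 ms
below.  Because the transmitted chirp bank is frame-periodic, the tracker
applies the FIR as circular convolution with the taps wrapped modulo the
frame length, which is simultaneously the group-delay compensation.

Step 2 — phase to time of flight.  The phase of the filtered component,
sampled at t = T/2, is plugged into the dechirped-phase model and the
quadratic is solved for ``t_d``; among the 2*pi-ambiguous candidates the
root in [0, T] nearest the previous frame's estimate (or the coarse
beat-peak delay on the first frame) is kept.  Distance is c * t_d.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
import scipy.fft
from scipy.signal import firwin, fftconvolve

from .signal_model import ChirpConfig, SpeakerArray, generate_chirp, forward_phase
from .time_sync import TimeMapping

__all__ = [
    "RangeTrack",
    "DechirpResult",
    "dechirp_and_separate",
    "adaptive_bandpass",
    "phase_to_tof",
    "track_distances",
    "repair_cycle_slips",
]

#: FIR group delay by SNR regime, s
FIR_DELAY_HIGH_SNR = 0.015
FIR_DELAY_LOW_SNR = 0.030
SNR_SWITCH_DB = 10.0
#: half-width of the band-pass, in chirp-frame-rate bins (passband = 4 bins)
PASSBAND_HALFWIDTH_BINS = 2
#: per-frame distance jump that flags a frame invalid (occlusion artifact), m
JUMP_THRESHOLD_M = 0.03
#: below this estimated SNR a frame is not trusted, dB
SNR_VALID_DB = -5.0


# ---------------------------------------------------------------------------
# cached helpers
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def _reference_chirp(cfg: ChirpConfig) -> np.ndarray:
    return generate_chirp(0, cfg)


@lru_cache(maxsize=32)
def _shifted_reference(i: int, cfg: ChirpConfig) -> np.ndarray:
    return generate_chirp(i, cfg)


def _fir_taps(center_hz: float, snr_db: float, cfg: ChirpConfig) -> np.ndarray:
    delay = FIR_DELAY_HIGH_SNR if snr_db > SNR_SWITCH_DB else FIR_DELAY_LOW_SNR
    n_taps = int(round(2 * delay * cfg.fs)) + 1
    hw = PASSBAND_HALFWIDTH_BINS / cfg.T
    lo = max(center_hz - hw, 1.0)
    hi = min(center_hz + hw, cfg.fs / 2 - 1.0)
    return firwin(n_taps, [lo, hi], pass_zero=False, fs=cfg.fs)


@lru_cache(maxsize=4096)
def _band_response(
    center_bin: int, low_snr: bool, cfg: ChirpConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Band-pass transfer function on the frame's DFT grid, as (bins, H[bins]).

    The symmetric FIR is wrapped modulo the frame length (circular
    convolution is exact for the frame-periodic chirp bank); the wrapped
    response is real (zero phase), so the filtered signal evaluated at any
    sample ``n`` is ``sum_k S_k H_k exp(2j*pi*k*n/N) / N`` over the support
    of H — one small inner product per frame.
    """
    N = cfg.n_samples
    snr_db = 0.0 if low_snr else 20.0
    taps = _fir_taps(center_bin * cfg.fs / N, snr_db, cfg)
    c = (len(taps) - 1) // 2
    hpad = np.zeros(N)
    np.add.at(hpad, (np.arange(len(taps)) - c) % N, taps)
    H = np.fft.fft(hpad).real  # symmetric wrap -> zero-phase, real response
    idx = np.flatnonzero(np.abs(H) > 1e-4 * np.abs(H).max())
    return idx, H[idx]


def _complex_ratio_delta(Sm1: complex, S0: complex, Sp1: complex) -> float:
    """Sub-bin frequency offset from three complex DFT bins.

    The complex-ratio estimator delta = Re[(S[-1]-S[+1]) / (2S[0]-S[-1]-S[+1])]
    is asymptotically unbiased for a rectangular-window complex exponential
    (a log-parabola fit of the Dirichlet mainlobe is biased by ~0.1 bin,
    which is enough to flip the phase-unwrap choice)."""
    denom = 2 * S0 - Sm1 - Sp1
    if denom == 0:
        return 0.0
    return float(np.clip(np.real((Sm1 - Sp1) / denom), -0.5, 0.5))


# ---------------------------------------------------------------------------
# Step 1: dechirp, separate, SNR
# ---------------------------------------------------------------------------

def _frame_spectrum(frame: np.ndarray, cfg: ChirpConfig) -> np.ndarray:
    return scipy.fft.fft(frame * _reference_chirp(cfg))


def _noise_floor(S: np.ndarray, cfg: ChirpConfig) -> float:
    """Mean noise power per DFT bin, from the quiet band above the beat slots
    (beats live below B; the dechirp image sits beyond ~6 kHz)."""
    N = cfg.n_samples
    df = cfg.fs / N
    lo, hi = int((cfg.B + 300) / df), int((cfg.B + 1700) / df)
    return float(np.mean(np.abs(S[lo:hi]) ** 2)) + 1e-300


def _locate_peak_grid(
    S: np.ndarray, fs: float, f_lo: float, f_hi: float
) -> tuple[float, float]:
    """Strongest bin in [f_lo, f_hi] Hz with complex-ratio refinement.
    Returns (peak_freq_hz, mainlobe_power) where the power sums the three
    central bins (scalloping-insensitive to ~0.7 dB)."""
    N = S.size
    df = fs / N
    b_lo = max(int(np.ceil(f_lo / df)), 1)
    b_hi = min(int(np.floor(f_hi / df)), N // 2 - 1)
    mag2 = np.abs(S[b_lo : b_hi + 1]) ** 2
    i = int(np.argmax(mag2)) + b_lo
    delta = _complex_ratio_delta(S[i - 1], S[i], S[i + 1])
    power3 = float(np.sum(np.abs(S[i - 1 : i + 2]) ** 2))
    return (i + delta) * df, power3


def _locate_peak(
    S: np.ndarray, cfg: ChirpConfig, f_lo: float, f_hi: float
) -> tuple[float, float]:
    return _locate_peak_grid(S, cfg.fs, f_lo, f_hi)


def _snr_db(peak_power: float, floor: float, N: int) -> float:
    # real-signal per-speaker time-domain SNR from the dechirped spectrum:
    # a tone of amplitude alpha contributes a complex exponential of
    # amplitude alpha/2 -> mainlobe power ~ (alpha N / 2)^2, while white
    # noise of power sigma^2 gives N sigma^2 per bin (3 bins summed);
    # SNR = (alpha^2/2)/sigma^2.
    sig = max(peak_power - 3.0 * floor, 1e-300)
    return 10.0 * np.log10(2.0 * sig / (N * floor) + 1e-300)


@dataclass
class DechirpResult:
    """Per-frame output of Step 1."""

    spectrum: np.ndarray
    freqs: np.ndarray
    peak_freq: dict[int, float]   # Hz, per active speaker
    snr_db: dict[int, float]
    valid: bool

    def component(self, speaker: int, cfg: ChirpConfig) -> np.ndarray:
        """Band-passed narrowband time series for one speaker (zero phase)."""
        if not self.valid:
            raise ValueError("frame is invalid (no signal)")
        N = cfg.n_samples
        center_bin = int(round(self.peak_freq[speaker] / (cfg.fs / N)))
        low = self.snr_db[speaker] <= SNR_SWITCH_DB
        snr = 0.0 if low else 20.0
        taps = _fir_taps(center_bin * cfg.fs / N, snr, cfg)
        c = (len(taps) - 1) // 2
        hpad = np.zeros(N)
        np.add.at(hpad, (np.arange(len(taps)) - c) % N, taps)
        return np.fft.ifft(self.spectrum * np.fft.fft(hpad).real)


def dechirp_and_separate(
    frame: np.ndarray, cfg: ChirpConfig, array: SpeakerArray | None = None
) -> DechirpResult:
    """Dechirp one frame and locate the per-speaker beat peaks.

    The frame must be exactly one chirp period long.  Each active speaker is
    searched in its base slot ``[i, i+1) * B * shift_fraction`` Hz.  An
    all-zero frame yields ``valid=False`` with no peaks.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.size != cfg.n_samples:
        raise ValueError(
            f"frame length {frame.size} != one chirp period ({cfg.n_samples} samples)"
        )
    active = array.active if array is not None else (0, 1, 2)
    N = cfg.n_samples
    freqs = np.arange(N) * cfg.fs / N
    if not np.any(frame):
        return DechirpResult(np.zeros(N, complex), freqs, {}, {}, False)
    S = _frame_spectrum(frame, cfg)
    floor = _noise_floor(S, cfg)
    slot = cfg.B * cfg.shift_fraction
    peaks, snrs = {}, {}
    for i in active:
        f_pk, p_pk = _locate_peak(S, cfg, i * slot, (i + 1) * slot)
        peaks[i] = f_pk
        snrs[i] = _snr_db(p_pk, floor, N)
    return DechirpResult(S, freqs, peaks, snrs, True)


# ---------------------------------------------------------------------------
# adaptive band-pass (stand-alone linear-convolution form)
# ---------------------------------------------------------------------------

def adaptive_bandpass(
    component: np.ndarray, snr_db: float, center_hz: float, cfg: ChirpConfig
) -> np.ndarray:
    """Linear-phase FIR band-pass around ``center_hz``, group delay
    compensated.  Group delay is 15 ms when ``snr_db`` > 10 dB, else 30 ms
    (filter length ``2*delay*fs + 1`` taps)."""
    if not np.isfinite(snr_db):
        raise ValueError("snr_db must be finite")
    taps = _fir_taps(center_hz, snr_db, cfg)
    g = (len(taps) - 1) // 2
    full = fftconvolve(np.asarray(component), taps, mode="full")
    return full[g : g + len(component)]


# ---------------------------------------------------------------------------
# Step 2: phase -> time of flight
# ---------------------------------------------------------------------------

def phase_to_tof(
    phase: float,
    cfg: ChirpConfig,
    prior: float | None = None,
    coarse: float = 0.0,
    t: float | None = None,
) -> float | None:
    """Invert the dechirped-phase model at in-chirp time ``t`` (default T/2).

    ``phase`` is the wrapped measured phase (radians).  The quadratic
    ``(B/2T) t_d^2 - (B t/T + f0) t_d - phi/(2pi) = 0`` is solved for each
    candidate unwrap count near the anchor (the prior estimate if given,
    else the coarse beat-peak delay) and the in-range root closest to the
    anchor is returned; ``None`` if no root falls in [0, T].
    """
    if not np.isfinite(phase):
        raise ValueError("phase must be finite")
    if t is None:
        t = 0.5 * cfg.T
    anchor = prior if prior is not None else coarse
    anchor = float(np.clip(anchor, 0.0, cfg.T))
    phi_exp = float(forward_phase(t, anchor, cfg))
    k0 = round((phi_exp - phase) / (2 * np.pi))
    b_lin = cfg.B * t / cfg.T + cfg.f0
    a = cfg.B / (2 * cfg.T)
    best, best_dist = None, np.inf
    for k in range(k0 - 2, k0 + 3):
        phi = phase + 2 * np.pi * k
        disc = b_lin**2 + 2 * (cfg.B / cfg.T) * (phi / (2 * np.pi))
        if disc < 0:
            continue
        t_large = (b_lin + np.sqrt(disc)) / (2 * a)
        for t_d in ((-phi / (2 * np.pi)) / (a * t_large), t_large):
            if 0.0 <= t_d <= cfg.T and abs(t_d - anchor) < best_dist:
                best, best_dist = float(t_d), abs(t_d - anchor)
    return best


# ---------------------------------------------------------------------------
# full per-frame tracking
# ---------------------------------------------------------------------------

@dataclass
class RangeTrack:
    """Raw per-speaker 1-D distance series d̃_i(t) at the chirp frame rate."""

    frames: np.ndarray          # frame indices
    t: np.ndarray               # transmitter-clock frame start times, s
    d_tilde: np.ndarray         # (n_frames, 3) m; held on invalid frames
    snr_db: np.ndarray          # (n_frames, 3)
    valid: np.ndarray           # (n_frames, 3) bool
    speakers: tuple[int, int, int] = (0, 1, 2)

    def to_csv(self, path: str) -> None:
        df = pd.DataFrame({"frame": self.frames, "t": self.t})
        for j in range(3):
            df[f"d{j+1}"] = self.d_tilde[:, j]
        for j in range(3):
            df[f"snr{j+1}"] = self.snr_db[:, j]
        for j in range(3):
            df[f"valid{j+1}"] = self.valid[:, j]
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str) -> "RangeTrack":
        df = pd.read_csv(path)
        return cls(
            df["frame"].to_numpy(),
            df["t"].to_numpy(),
            df[["d1", "d2", "d3"]].to_numpy(),
            df[["snr1", "snr2", "snr3"]].to_numpy(),
            df[["valid1", "valid2", "valid3"]].to_numpy(dtype=bool),
        )


def repair_cycle_slips(track: "RangeTrack", c: float = 343.0) -> "RangeTrack":
    """Re-level per-speaker phase-ambiguity slips in a tracked distance set.

    The fine time of flight is ambiguous modulo one phase cycle, ~c/20 kHz
    (= 1.7 cm) in distance.  A transient during motion can therefore step a
    single speaker's track by a whole number of cycles while the geometry
    moved smoothly — visible as a sharp per-speaker step that the other
    speakers do not share.  Steps within 4 mm of a nonzero multiple of the
    cycle, after removing the common-mode (true motion) step, are
    subtracted from the remainder of that speaker's track.
    """
    cfg_lambda = c / 20_000.0  # ambiguity step at the mid-sweep frequency
    d = track.d_tilde.copy()
    n, ns = d.shape
    if n < 9:
        return track
    # robust per-frame step estimates: median of 3 after minus 3 before
    steps = np.full((n, ns), 0.0)
    for k in range(4, n - 3):
        steps[k] = np.median(d[k : k + 3], axis=0) - np.median(d[k - 4 : k - 1], axis=0)
    common = np.median(steps, axis=1)
    resid = steps - common[:, None]
    for j in range(ns):
        k = 4
        while k < n - 3:
            cycles = np.round(resid[k, j] / cfg_lambda)
            if cycles != 0 and abs(resid[k, j] - cycles * cfg_lambda) < 0.004:
                d[k:, j] -= cycles * cfg_lambda
                # recompute local residual after the repair
                for m in range(max(k - 3, 4), min(k + 4, n - 3)):
                    s = np.median(d[m : m + 3], axis=0) - np.median(d[m - 4 : m - 1], axis=0)
                    resid[m, j] = s[j] - np.median(s)
                k += 3
            else:
                k += 1
    return RangeTrack(track.frames, track.t, d, track.snr_db, track.valid,
                      track.speakers)


def track_distances(
    wave: np.ndarray,
    mapping: TimeMapping,
    cfg: ChirpConfig,
    array: SpeakerArray,
    c: float = 343.0,
    search_halfwidth_hz: float = 150.0,
) -> RangeTrack:
    """Run the two-step ranging pipeline over a whole recording.

    Frames are segmented on the beacon-aligned timeline (the localizer knows
    its own transmit schedule): frame ``k`` starts at the receiver sample
    mapped from transmitter time ``k*T``; the sub-sample segmentation
    residual is known and folded back into the recovered time of flight.
    Emits one distance per active speaker per frame (~1/T Hz).  Invalid
    frames (no signal, no in-range root, implausible jump, SNR below the
    validity floor) hold the previous distance.
    """
    wave = np.asarray(wave, dtype=float)
    N = cfg.n_samples
    if wave.size < N:
        raise ValueError("waveform shorter than one chirp frame")
    slot = cfg.B * cfg.shift_fraction
    active = array.active
    n_max = int(wave.size)

    # frame start samples on the aligned timeline
    starts = []
    k = 0
    while True:
        n0 = float(mapping.tx_time_to_rx_sample(k * cfg.T))
        if n0 + N > n_max:
            break
        if n0 >= 0:
            starts.append((k, n0))
        k += 1
        if k > 10_000_000:  # pathological mapping guard
            break
    n_frames = len(starts)
    frames_idx = np.array([k for k, _ in starts])
    t_frames = frames_idx * cfg.T

    d = np.zeros((n_frames, 3))
    snr = np.full((n_frames, 3), np.nan)
    valid = np.zeros((n_frames, 3), dtype=bool)
    # Prior chain in the shifted-delay domain t_d' = t_d + i*s*T.  The phase
    # unwrap count is carried frame to frame (the method tracks *relative*
    # distance changes from the calibrated start), with a constant-velocity
    # prediction so smooth motion keeps the prior within half an ambiguity
    # step (~25 us, i.e. ~0.86 cm) of the truth.  Once locked, the band-pass
    # is centred on the *predicted* beat (chasing the per-frame spectral
    # argmax would let a body reflection capture the chain during motion);
    # a measurement further than ``PRED_GATE`` from the prediction is
    # rejected so a single wrong unwrap cannot cascade, and sustained
    # rejections while a healthy tone sits near the prediction trigger
    # re-acquisition from the coarse beat peak.
    prior_tau = {i: None for i in active}
    prev_tau = {i: None for i in active}
    last_d = {i: np.nan for i in active}
    reject_streak = {i: 0 for i in active}
    max_step = 25e-6   # s/frame cap on the velocity prediction (~0.2 m/s)
    PRED_GATE = 30e-6  # s; ~1 cm consistency gate on the prior chain
    REACQ_SNR_DB = 12.0
    reacq_frames = max(int(round(1.0 / cfg.T)), 2)
    df_bin = cfg.fs / N
    shift_T = cfg.shift_fraction * cfg.T

    batch = 2048
    for b0 in range(0, n_frames, batch):
        b1 = min(b0 + batch, n_frames)
        rows = []
        fracs = []
        for _, n0 in starts[b0:b1]:
            n0i = int(round(n0))
            n0i = min(max(n0i, 0), n_max - N)
            rows.append(wave[n0i : n0i + N])
            fracs.append((n0 - n0i) / cfg.fs)
        F = np.asarray(rows)
        S_all = scipy.fft.fft(F * _reference_chirp(cfg)[None, :], axis=1)

        for r in range(b1 - b0):
            g = b0 + r
            S = S_all[r]
            frame_ok = bool(np.any(F[r]))
            floor = _noise_floor(S, cfg) if frame_ok else np.inf
            for j, i in enumerate(active):
                ok = frame_ok
                pred = None
                if prior_tau[i] is not None:
                    step = 0.0
                    if prev_tau[i] is not None:
                        step = float(np.clip(prior_tau[i] - prev_tau[i], -max_step, max_step))
                    pred = prior_tau[i] + step
                s_db = np.nan
                if ok:
                    if pred is not None:
                        # locked: measure the tone at the predicted beat
                        f_pk = pred * cfg.B / cfg.T
                        b = min(max(int(round(f_pk / df_bin)), 1), N // 2 - 2)
                        p_pk = float(np.sum(np.abs(S[b - 1 : b + 2]) ** 2))
                    else:
                        f_pk, p_pk = _locate_peak(S, cfg, i * slot, (i + 1) * slot)
                    s_db = _snr_db(p_pk, floor, N)
                    snr[g, j] = s_db
                    ok = s_db > SNR_VALID_DB
                if ok:
                    idx, H = _band_response(
                        int(round(f_pk / df_bin)), s_db <= SNR_SWITCH_DB, cfg
                    )
                    if pred is None:
                        # Acquisition: refine the coarse delay on the clean
                        # contiguous stretch of the shift-aligned dechirp.
                        # The slot tone of a far-shifted speaker is split by
                        # the in-frame wrap into two phase-incoherent
                        # segments whose interference biases plain
                        # interpolation enough to mis-pick the unwrap count;
                        # the post-gap segment [tau', T] is a clean tone at
                        # (B/T) * (time of flight) near DC.
                        tau_rough = f_pk * cfg.T / cfg.B  # includes i*s*T
                        n_seg = int((tau_rough + 5e-4) * cfg.fs)
                        n_seg = min(max(n_seg, 0), N - 256)
                        seg = F[r, n_seg:] * _shifted_reference(i, cfg)[n_seg:]
                        M = seg.size
                        S_i = scipy.fft.fft(seg)
                        f_i, _ = _locate_peak_grid(S_i, cfg.fs, 3.0, slot)
                        coarse = f_i * cfg.T / cfg.B + i * shift_T
                    else:
                        coarse = pred
                    tau_ref = pred if pred is not None else coarse
                    # phase readout at the midpoint of the post-arrival span
                    # [tau', T] (t = T/2 in the small-delay limit)
                    n_read = int(round(np.clip((tau_ref + cfg.T) / 2, 0, cfg.T) * cfg.fs))
                    n_read = min(n_read, N - 1)
                    val = S[idx] @ (H * np.exp(2j * np.pi * idx * n_read / N)) / N
                    phase = -np.angle(val)  # component carries exp(-j*phi)
                    tau = phase_to_tof(
                        phase, cfg, prior=pred, coarse=coarse, t=n_read / cfg.fs
                    )
                    ok = tau is not None
                if ok and pred is not None and abs(tau - pred) > PRED_GATE:
                    ok = False  # inconsistent with the tracked chain
                if ok:
                    tau -= fracs[r]  # sub-sample segmentation residual
                    d_new = c * (tau - i * shift_T)
                    if (
                        np.isfinite(last_d[i])
                        and abs(d_new - last_d[i]) > JUMP_THRESHOLD_M
                    ):
                        ok = False  # implausible jump: occlusion artifact
                if ok:
                    d[g, j] = d_new
                    valid[g, j] = True
                    last_d[i] = d_new
                    prev_tau[i] = prior_tau[i]
                    prior_tau[i] = tau
                    reject_streak[i] = 0
                else:
                    d[g, j] = last_d[i] if np.isfinite(last_d[i]) else np.nan
                    # re-acquisition health check: is there a strong tone in
                    # the neighbourhood of where this chain is looking?
                    healthy = False
                    if frame_ok and pred is not None:
                        f_c = pred * cfg.B / cfg.T
                        _, p_h = _locate_peak(
                            S, cfg, f_c - search_halfwidth_hz, f_c + search_halfwidth_hz
                        )
                        healthy = _snr_db(p_h, floor, N) > REACQ_SNR_DB
                    if healthy:
                        reject_streak[i] += 1
                        if reject_streak[i] >= reacq_frames:
                            # a healthy tone persistently inconsistent with the
                            # chain: the geometry really changed; re-acquire
                            prior_tau[i] = None
                            prev_tau[i] = None
                            last_d[i] = np.nan
                            reject_streak[i] = 0
                    else:
                        reject_streak[i] = 0
    return RangeTrack(frames_idx, t_frames, d, snr, valid, tuple(active))
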