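"""Two-stage clock-drift correction.

Stage 1 (beacon alignment): the transmitter broadcasts its free-running
16 MHz timer value ~200 times a second.  Unwrapping the timer wraparound
and regressing receiver timer time on transmitter timer time over an
initial sync window yields an offset and a relative rate (the drift
factor); the receiver's sample index is thereafter mapped onto the
transmitter's timebase through that line.  Residual rate error is set by
tick quantization (62.5 ns) and reception jitter.

Stage 2 (regression post-processing): the residual drift shows up as a
slow linear trend in the tracked distances.  The last few minutes of
history are split into 30 s chunks; each chunk gets an ordinary
least-squares line, chunks are ranked by residual sum of squares, and the
mean slope of the better (lower-residual) half is taken as the drift
estimate — body-motion bursts inflate a chunk's residual and push it into
the discarded half, which is what makes the estimate robust to sparse
motion.

Drift-factor resampling: a sampled waveform is rebuilt on a stretched
frequency basis, x̂_t = Σ_f X_f exp(i2πα f t/N), evaluated with a chirp-z
transform (alpha = 1 is the identity up to transform round-off).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import json

import numpy as np
import pandas as pd
from scipy.signal import czt

from .scene_sim import ClockModel

__all__ = [
    "DriftEstimate",
    "TimeMapping",
    "resample_with_drift",
    "beacon_align",
    "unwrap_ticks",
    "estimate_residual_drift",
    "apply_drift_correction",
    "postprocess_drift",
]


def resample_with_drift(signal: np.ndarray, alpha: float) -> np.ndarray:
    """Resample a waveform by drift factor ``alpha`` on a frequency-shifted basis.

    Forward transform then inverse transform with every frequency scaled by
    ``alpha``; frequencies are treated as signed (negative bins scale
    symmetrically) so real inputs stay real.  Length is preserved.
    """
    if alpha <= 0:
        raise ValueError("drift factor alpha must be positive")
    if not (0.9 < alpha < 1.1):
        raise ValueError("alpha outside the supported (0.9, 1.1) drift range")
    x = np.asarray(signal)
    if not np.all(np.isfinite(x)):
        raise ValueError("signal must be finite")
    n = x.shape[-1]
    X = np.fft.fftshift(np.fft.fft(x, axis=-1), axes=-1)
    f_lo = -(n // 2)  # signed frequency of the first shifted bin
    # out[t] = sum_m X[m] exp(+i 2 pi alpha (m + f_lo) t / n), via chirp-z
    w = np.exp(-2j * np.pi * alpha / n)  # czt computes sum_m X[m] w^{-mt} for a=1
    out = czt(X, m=n, w=np.conj(w), a=1.0, axis=-1)
    t = np.arange(n)
    out = out * np.exp(2j * np.pi * alpha * f_lo * t / n) / n
    return out.real if np.isrealobj(signal) else out


def unwrap_ticks(ticks: np.ndarray, timer_max: int) -> np.ndarray:
    """Cumulatively unwrap a wrapping hardware-timer series to monotone ticks."""
    ticks = np.asarray(ticks, dtype=np.int64)
    d = np.diff(ticks)
    wraps = np.concatenate([[0], np.cumsum(d < -timer_max // 2)])
    return ticks + wraps * timer_max


@dataclass(frozen=True)
class TimeMapping:
    """Affine map between receiver clock time and transmitter clock time.

    ``rx_time ≈ offset + alpha * tx_time`` where both times are the devices'
    own timer readings in seconds.  ``alpha`` is the drift factor (1 = no
    relative drift); it is also the factor to feed `resample_with_drift`.
    """

    offset: float
    alpha: float
    fs: float

    def rx_sample_to_tx_time(self, n) -> np.ndarray:
        return (np.asarray(n, dtype=float) / self.fs - self.offset) / self.alpha

    def tx_time_to_rx_sample(self, t_tx) -> np.ndarray:
        return (self.offset + self.alpha * np.asarray(t_tx, dtype=float)) * self.fs

    @classmethod
    def identity(cls, fs: float) -> "TimeMapping":
        return cls(0.0, 1.0, fs)


def beacon_align(
    beacons: pd.DataFrame,
    clocks: ClockModel,
    fs: float,
    sync_window: float = 10.0,
) -> TimeMapping:
    """Fit the receiver→transmitter timeline from a sync-beacon log.

    Uses beacons within the first ``sync_window`` seconds (or all of them if
    the log is shorter): both tick series are unwrapped at ``timer_max``,
    converted to seconds of their own clock, and receiver time is regressed
    on transmitter time.  Needs at least 2 beacons.
    """
    if len(beacons) < 2:
        raise ValueError("beacon log must contain at least 2 beacons")
    tx = unwrap_ticks(beacons["tx_ticks"].to_numpy(), clocks.timer_max) / clocks.timer_freq
    rx = unwrap_ticks(beacons["rx_ticks"].to_numpy(), clocks.timer_max) / clocks.timer_freq
    if np.any(np.diff(tx) <= 0):
        raise ValueError("beacon transmit times are not monotonically increasing")
    # A wrapping timer only defines the clock offset modulo the wrap period;
    # anchor on the minimal offset at the first beacon (radio propagation is
    # negligible), so a first tick straddling the wrap boundary cannot shift
    # the whole timeline by 50 ms.
    wrap_s = clocks.timer_max / clocks.timer_freq
    off0 = (rx[0] - tx[0] + wrap_s / 2) % wrap_s - wrap_s / 2
    rx = tx[0] + off0 + (rx - rx[0])
    mask = tx - tx[0] <= sync_window
    if mask.sum() < 2:
        mask[:2] = True
    slope, intercept = np.polyfit(tx[mask], rx[mask], 1)
    return TimeMapping(offset=float(intercept), alpha=float(slope), fs=fs)


@dataclass(frozen=True)
class DriftEstimate:
    """Residual drift from chunked-regression post-processing.

    ``slope`` is in input units per second (distances in m give m/s); the
    equivalent sampling drift factor for `resample_with_drift` is
    ``alpha = 1 + slope/c`` for a slope expressed in m/s.
    """

    slope: float
    alpha: float
    valid: bool
    n_chunks: int
    window: float = 300.0
    chunk: float = 30.0

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def estimate_residual_drift(
    times: np.ndarray,
    values: np.ndarray,
    window: float = 300.0,
    chunk: float = 30.0,
    min_chunk_samples: int = 10,
    c: float = 343.0,
    values_in_m: bool = True,
) -> DriftEstimate:
    """Estimate residual linear drift from the trailing history window.

    The last ``window`` seconds are split into ``chunk``-second chunks; each
    chunk is fit by OLS, chunks are sorted by residual sum of squares and
    the mean slope over the lower half (floor(n/2) chunks for odd n) is
    returned.  Histories spanning fewer than two usable chunks yield an
    invalid (zero-correction) estimate rather than an error.
    """
    if window < 2 * chunk:
        raise ValueError("window must span at least 2 chunks")
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size != values.size:
        raise ValueError("times and values must have equal length")
    if times.size == 0:
        return DriftEstimate(0.0, 1.0, False, 0, window, chunk)
    t_end = times[-1]
    sel = times >= t_end - window
    t, v = times[sel], values[sel]
    t0 = t[0]
    idx = np.floor((t - t0) / chunk).astype(int)
    slopes, rss = [], []
    for k in np.unique(idx):
        m = idx == k
        if m.sum() < min_chunk_samples:
            continue  # regression degeneracy guard
        if t[m].max() - t[m].min() < 0.9 * chunk:
            continue  # partial chunk at the history edge
        coef = np.polyfit(t[m], v[m], 1)
        resid = v[m] - np.polyval(coef, t[m])
        slopes.append(coef[0])
        rss.append(float(resid @ resid))
    n = len(slopes)
    if n < 2:
        return DriftEstimate(0.0, 1.0, False, n, window, chunk)
    order = np.argsort(rss)
    keep = order[: max(1, n // 2)]
    slope = float(np.mean(np.asarray(slopes)[keep]))
    scale = 1.0 if values_in_m else 1e-2  # cm/s -> m/s for the alpha equivalence
    return DriftEstimate(slope, 1.0 + slope * scale / c, True, n, window, chunk)


def apply_drift_correction(
    times: np.ndarray, values: np.ndarray, est: DriftEstimate, t_ref: float
) -> np.ndarray:
    """Remove the estimated drift forward of ``t_ref``:
    ``corrected(t) = value(t) - slope * (t - t_ref)``."""
    return np.asarray(values, dtype=float) - est.slope * (
        np.asarray(times, dtype=float) - t_ref
    )


def postprocess_drift(
    times: np.ndarray,
    values: np.ndarray,
    window: float = 300.0,
    chunk: float = 30.0,
    update_every: float = 30.0,
    **est_kw,
) -> tuple[np.ndarray, DriftEstimate]:
    """Offline drift removal pass over a whole recorded series.

    Re-estimates the residual slope every ``update_every`` seconds from the
    already-corrected trailing ``window`` and accumulates the corrections as
    a global linear term anchored at the series start (the first estimate is
    applied retroactively, so the warm-up span does not leak drift into the
    corrected series).  Returns the corrected series and the accumulated
    drift estimate.
    """
    times = np.asarray(times, dtype=float)
    corrected = np.asarray(values, dtype=float).copy()
    if times.size == 0:
        return corrected, DriftEstimate(0.0, 1.0, False, 0, window, chunk)
    t0 = times[0]
    total_slope = 0.0
    n_chunks = 0
    any_valid = False
    first_update = t0 + 2 * chunk
    for t_up in np.arange(first_update, times[-1] + update_every, update_every):
        hist = times <= t_up
        est = estimate_residual_drift(
            times[hist], corrected[hist], window=window, chunk=chunk, **est_kw
        )
        if not est.valid:
            continue
        corrected = corrected - est.slope * (times - t0)
        total_slope += est.slope
        n_chunks = est.n_chunks
        any_valid = True
    return corrected, DriftEstimate(
        total_slope, 1.0 + total_slope / 343.0, any_valid, n_chunks, window, chunk
    )
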