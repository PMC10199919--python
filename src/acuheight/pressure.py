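"""Transducer normalization and hydrostatic mean-arterial-pressure correction.

An invasive pressure transducer reads the arterial pressure plus the
hydrostatic pressure of the blood column between the patient's reference
point (right atrium) and the transducer: every centimetre of height
offset biases the reading by 0.735 mmHg.  A stationary transducer fixed
to the IV pole therefore over-reads by 0.735 mmHg per cm the bed is
raised; subtracting the tracked height change (and the baseline
inter-transducer offset) recovers the true mean arterial pressure:

    MAP_corrected = MAP_stationary - 0.735 * Δh_cm + Δtransducer

The same formula serves a laser-measured Δh and the acoustic tracker's
Δh.  Only mean pressure is corrected: systolic/diastolic extremes are
also shaped by waveform damping, which a height model cannot fix.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
import json

import numpy as np
import pandas as pd

__all__ = [
    "MMHG_PER_CM",
    "PressureRecord",
    "transducer_offset",
    "height_to_pressure",
    "corrected_map",
    "correct_session",
    "report_round",
]


def report_round(value: float, decimals: int = 1) -> float:
    """Display rounding for reports: decimal half-up (7.35 -> 7.4).

    Internal computation is full precision; only the reporting layer
    rounds, and clinical convention rounds halves away from zero rather
    than to even.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))

#: hydrostatic conversion factor: mmHg per cm of blood column
MMHG_PER_CM = 0.735


def transducer_offset(map_c0: float, map_p0: float) -> float:
    """Baseline inter-transducer offset Δtransducer = MAP_c,0 − MAP_p,0.

    Both baselines are mean readings taken at the lowest bed height: the
    clinical transducer taped at heart level and the stationary transducer
    on the pole.  Two transducers at the same height routinely disagree by
    a device-specific constant; this removes it.
    """
    if map_c0 is None or map_p0 is None:
        raise ValueError("both baseline measurements are required")
    return float(map_c0) - float(map_p0)


def height_to_pressure(delta_h_cm) -> float | np.ndarray:
    """Convert a height difference in cm to mmHg of blood-column pressure."""
    dh = np.asarray(delta_h_cm, dtype=float)
    if not np.all(np.isfinite(dh)):
        raise ValueError("height difference must be finite")
    out = MMHG_PER_CM * dh
    return float(out) if np.isscalar(delta_h_cm) else out


def corrected_map(map_s, delta_h_cm, delta_transducer) -> float | np.ndarray:
    """Height-corrected mean arterial pressure.

    ``MAP = MAP_s − 0.735 × Δh + Δtransducer`` with Δh in cm.  Works
    elementwise on arrays.
    """
    out = (
        np.asarray(map_s, dtype=float)
        - MMHG_PER_CM * np.asarray(delta_h_cm, dtype=float)
        + np.asarray(delta_transducer, dtype=float)
    )
    return float(out) if out.ndim == 0 else out


@dataclass
class PressureRecord:
    """One height level's pressure bookkeeping (all pressures in mmHg, heights cm)."""

    MAP_s: float
    delta_transducer: float
    h_l_x: float | None = None
    h_l_0: float = 0.0
    h_a_x: float | None = None
    h_a_0: float = 0.0

    @property
    def MAP_l(self) -> float | None:
        """Laser-corrected MAP (None without a laser height)."""
        if self.h_l_x is None:
            return None
        return corrected_map(self.MAP_s, self.h_l_x - self.h_l_0, self.delta_transducer)

    @property
    def MAP_a(self) -> float | None:
        """Tracker-corrected MAP (None without a tracker height)."""
        if self.h_a_x is None:
            return None
        return corrected_map(self.MAP_s, self.h_a_x - self.h_a_0, self.delta_transducer)

    def summary_json(self) -> str:
        return json.dumps(
            {"MAP_s": self.MAP_s, "delta_transducer": self.delta_transducer,
             "MAP_l": self.MAP_l, "MAP_a": self.MAP_a}
        )


def correct_session(
    pressures: pd.DataFrame,
    t_height: np.ndarray,
    h_cm: np.ndarray,
    baseline_t: tuple[float, float],
) -> pd.DataFrame:
    """Apply the tracker height correction to a stationary-transducer series.

    ``pressures`` needs columns ``t``, ``MAP_c`` (clinical transducer) and
    ``MAP_s`` (stationary transducer).  The tracker height series
    ``(t_height, h_cm)`` is interpolated onto the pressure timestamps;
    ``baseline_t`` is the (start, end) of the lowest-height baseline window
    used for Δtransducer and h_a,0.  Returns the input frame with added
    columns ``h_a_cm``, ``delta_h_a_cm`` and ``MAP_a``.
    """
    req = {"t", "MAP_c", "MAP_s"}
    if not req.issubset(pressures.columns):
        raise ValueError(f"pressure session needs columns {sorted(req)}")
    out = pressures.copy()
    tp = out["t"].to_numpy(dtype=float)
    h_at_p = np.interp(tp, np.asarray(t_height, float), np.asarray(h_cm, float))
    base = (tp >= baseline_t[0]) & (tp <= baseline_t[1])
    if not np.any(base):
        raise ValueError("no pressure readings inside the baseline window")
    d_trans = transducer_offset(
        out.loc[base, "MAP_c"].mean(), out.loc[base, "MAP_s"].mean()
    )
    h_a0 = float(h_at_p[base].mean())
    out["h_a_cm"] = h_at_p
    out["delta_h_a_cm"] = h_at_p - h_a0
    out["MAP_a"] = corrected_map(out["MAP_s"].to_numpy(), out["delta_h_a_cm"].to_numpy(), d_trans)
    out.attrs["delta_transducer"] = d_trans
    return out
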