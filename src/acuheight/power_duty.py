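"""Wearable power budget and duty-cycled battery-life model.

The wearable alternates between a fully-on state (Bluetooth streaming,
microphone and accelerometer enabled, ~6 mA) and an accelerometer-only
low-power state (~17.53 µA); a motion interrupt wakes the device.  With a
coin-cell capacity C (mAh) and duty fraction ``delta`` of time awake,

    life_hours = C / (delta * I_active + (1 - delta) * I_idle)
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np
import pandas as pd

__all__ = ["PowerBudget", "total_power", "battery_life", "duty_curve",
           "REFERENCE_COMPONENTS"]

#: reference bill of power for the wearable, mW
REFERENCE_COMPONENTS: list[tuple[str, float]] = [
    ("BLE SoC (nRF52840)", 12.02),
    ("Microphone (ICS-41350)", 0.77),
    ("Accelerometer (BMA400)", 0.0063),
    ("Ideal diode (LM66100DCKT)", 0.00027),
    ("Buck efficiency loss (MAX38640)", 1.75),
]


def total_power(components: list[tuple[str, float]]) -> float:
    """Sum of component powers in mW (report rounded to 2 decimals)."""
    if not components:
        raise ValueError("component list must be nonempty")
    powers = [p for _, p in components]
    if any(p < 0 for p in powers):
        raise ValueError("component powers must be nonnegative")
    return float(np.sum(powers))


@dataclass
class PowerBudget:
    """Device power/current budget.

    Currents are in the units the datasheets quote: active in mA, idle in
    µA.  The coin-cell capacity is configurable (a CR2032 is nominally
    ~220 mAh, varying with load and manufacturer).
    """

    components: list[tuple[str, float]] = field(
        default_factory=lambda: list(REFERENCE_COMPONENTS)
    )
    I_active_ma: float = 6.0
    I_idle_ua: float = 17.53
    capacity_mah: float = 220.0

    @property
    def total_mw(self) -> float:
        return total_power(self.components)

    def to_json(self) -> str:
        return json.dumps(
            {"components": self.components, "I_active_ma": self.I_active_ma,
             "I_idle_ua": self.I_idle_ua, "capacity_mah": self.capacity_mah}
        )

    @classmethod
    def from_json(cls, s: str) -> "PowerBudget":
        d = json.loads(s)
        d["components"] = [tuple(c) for c in d["components"]]
        return cls(**d)


def battery_life(duty: float, budget: PowerBudget | None = None) -> float:
    """Battery life in hours at the given active-duty fraction."""
    if not 0.0 <= duty <= 1.0:
        raise ValueError("duty must lie in [0, 1]")
    if budget is None:
        budget = PowerBudget()
    i_avg_ma = duty * budget.I_active_ma + (1.0 - duty) * budget.I_idle_ua * 1e-3
    return budget.capacity_mah / i_avg_ma


def duty_curve(duties, budget: PowerBudget | None = None) -> pd.DataFrame:
    """Battery life across duty fractions, as a (duty, hours) table."""
    duties = np.asarray(duties, dtype=float)
    hours = np.array([battery_life(d, budget) for d in duties])
    return pd.DataFrame({"duty": duties, "hours": hours})
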