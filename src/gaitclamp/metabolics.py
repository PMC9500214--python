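"""Breath-by-breath gas exchange to net metabolic power and cost of transport.

Whole-body metabolic power is estimated from oxygen consumption and carbon
dioxide production with the standard linear regression coefficients
(16.58 kJ/L O2, 4.51 kJ/L CO2).  Walking power minus the standing baseline,
normalized by body mass, gives net metabolic power (W/kg); dividing by mean
speed gives the cost of transport (J/(kg*m)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BreathSample",
    "MetabolicResult",
    "BROCKWAY_O2_KJ_PER_L",
    "BROCKWAY_CO2_KJ_PER_L",
    "brockway_power",
    "steady_state_average",
    "net_metabolic_power",
    "cost_of_transport",
    "process_breaths",
]

#: kJ per liter of O2 consumed / CO2 produced (standard regression values;
#: configurable at call sites that need alternates).
BROCKWAY_O2_KJ_PER_L = 16.58
BROCKWAY_CO2_KJ_PER_L = 4.51


@dataclass(frozen=True)
class BreathSample:
    """One breath: timestamp (s) and gas exchange rates (L/min)."""

    t: float
    vo2: float
    vco2: float


@dataclass(frozen=True)
class MetabolicResult:
    gross_power: float  # W
    net_power_per_kg: float  # W/kg
    cot: float | None  # J/(kg*m); None when no speed given
    window_used: float  # s
    respiratory_exchange_ratio: float
    flags: tuple[str, ...] = field(default=())


def brockway_power(
    vo2: float,
    vco2: float,
    c_o2: float = BROCKWAY_O2_KJ_PER_L,
    c_co2: float = BROCKWAY_CO2_KJ_PER_L,
) -> float:
    """Metabolic power (W) from V̇O2 and V̇CO2 in L/min."""
    if vo2 < 0 or vco2 < 0:
        raise ValueError("gas exchange rates must be >= 0")
    return (c_o2 * vo2 + c_co2 * vco2) * 1000.0 / 60.0


def steady_state_average(
    breaths: list[BreathSample],
    trial_end: float | None = None,
    window: float = 120.0,
    min_breaths: int = 5,
) -> tuple[float, float]:
    """Time-weighted (vo2, vco2) means over breaths in the final window.

    Each breath is weighted by the interval since the previous breath in the
    window (the first breath carries the median interval), which is robust to
    irregular breath spacing.
    """
    if not breaths:
        raise ValueError("no breaths supplied")
    t = np.array([b.t for b in breaths])
    if np.any(np.diff(t) <= 0):
        raise ValueError("breath timestamps must be strictly increasing")
    end = float(t[-1]) if trial_end is None else float(trial_end)
    mask = (t >= end - window) & (t <= end)
    if int(mask.sum()) < min_breaths:
        raise ValueError(
            f"only {int(mask.sum())} breaths in final {window:g} s window "
            f"(need >= {min_breaths})"
        )
    tw = t[mask]
    vo2 = np.array([b.vo2 for b in breaths])[mask]
    vco2 = np.array([b.vco2 for b in breaths])[mask]
    dt = np.diff(tw)
    weights = np.concatenate([[np.median(dt)], dt]) if dt.size else np.ones(1)
    weights = weights / weights.sum()
    return float(np.sum(weights * vo2)), float(np.sum(weights * vco2))


def net_metabolic_power(walking_power: float, standing_power: float, mass: float) -> float:
    """Net metabolic power (W/kg): (walking - standing) / mass; inputs in W, kg."""
    if mass <= 0:
        raise ValueError("mass must be > 0")
    return (walking_power - standing_power) / mass


def cost_of_transport(net_power_per_kg: float, mean_speed: float) -> float:
    """Cost of transport (J/(kg*m)) = net power per kg / mean speed."""
    if mean_speed <= 0:
        raise ValueError("mean_speed must be > 0")
    return net_power_per_kg / mean_speed


def process_breaths(
    breaths: list[BreathSample],
    mass: float,
    standing_power: float,
    mean_speed: float | None = None,
    trial_end: float | None = None,
    window: float = 120.0,
) -> MetabolicResult:
    """Full per-trial chain: steady-state average -> power -> net -> CoT."""
    vo2, vco2 = steady_state_average(breaths, trial_end=trial_end, window=window)
    gross = brockway_power(vo2, vco2)
    net = net_metabolic_power(gross, standing_power, mass)
    flags: tuple[str, ...] = ("negative_net_power",) if net < 0 else ()
    cot = cost_of_transport(net, mean_speed) if mean_speed is not None else None
    rer = vco2 / vo2 if vo2 > 0 else float("nan")
    return MetabolicResult(
        gross_power=gross,
        net_power_per_kg=net,
        cot=cot,
        window_used=window,
        respiratory_exchange_ratio=rer,
        flags=flags,
    )
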