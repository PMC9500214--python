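"""Dead-zone proportional treadmill speed controller and force-target biofeedback.

The controller reads the walker's average anterior-posterior center-of-pressure
(CoP) position during each double-support phase.  Inside a dead zone centered
on the treadmill midline the belt speed is held; outside it the speed changes
by ``delta = R * D * L`` where ``R`` is the sign of the CoP offset, ``D`` its
distance from the treadmill center (meters) and ``L`` a dimensionless gain.
The biofeedback state tracks the mean peak propulsive force of the previous
two steps (one per side) against a prescribed target with a relative tolerance
and a consecutive on-target streak counter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ControllerState",
    "FeedbackState",
    "cop_double_support_average",
    "speed_update",
    "feedback_update",
]


@dataclass(frozen=True)
class ControllerState:
    """Belt-speed controller state (speeds in m/s, distances in m)."""

    belt_speed: float
    dead_zone_halfwidth: float = 0.10
    gain_l: float = 0.1
    speed_min: float = 0.2
    speed_max: float = 3.0
    last_update_time: float = 0.0

    def __post_init__(self) -> None:
        if self.dead_zone_halfwidth <= 0:
            raise ValueError("dead_zone_halfwidth must be > 0")
        if self.gain_l <= 0:
            raise ValueError("gain_l must be > 0")
        if not 0 <= self.speed_min <= self.speed_max:
            raise ValueError("require 0 <= speed_min <= speed_max")
        if not self.speed_min <= self.belt_speed <= self.speed_max:
            raise ValueError(
                f"belt_speed {self.belt_speed} outside "
                f"[{self.speed_min}, {self.speed_max}]"
            )


@dataclass(frozen=True)
class FeedbackState:
    """Propulsive-force biofeedback display state (forces in N)."""

    target_fp: float
    tolerance_frac: float = 0.05
    displayed_fp: float | None = None
    on_target: bool = False
    streak: int = 0

    def __post_init__(self) -> None:
        if self.target_fp <= 0:
            raise ValueError("target_fp must be > 0")
        if self.streak < 0:
            raise ValueError("streak must be >= 0")


def cop_double_support_average(cop_series: np.ndarray, window: slice | np.ndarray) -> float:
    """Mean anterior-posterior CoP position over one double-support window.

    Parameters
    ----------
    cop_series : array of CoP positions, anterior positive, meters.
    window : slice or boolean/index array selecting the double-support samples.
    """
    vals = np.asarray(cop_series)[window]
    if vals.size == 0:
        raise ValueError("empty double-support window")
    return float(np.mean(vals))


def speed_update(state: ControllerState, cop_avg: float) -> ControllerState:
    """Apply one double-support speed update ``delta = R * D * L``.

    ``D`` is the CoP distance from the treadmill *center* (not from the dead
    zone edge), so the identity holds inside the dead zone and the update is
    odd-symmetric and clipped to the state's speed bounds outside it.
    """
    if not math.isfinite(cop_avg):
        raise ValueError("cop_avg must be finite")
    if abs(cop_avg) <= state.dead_zone_halfwidth:
        return state
    r = 1.0 if cop_avg > 0 else -1.0
    d = abs(cop_avg)
    new_speed = state.belt_speed + r * d * state.gain_l
    new_speed = min(max(new_speed, state.speed_min), state.speed_max)
    return replace(state, belt_speed=new_speed)


def feedback_update(
    fb: FeedbackState,
    new_step_peaks: tuple[float | None, float | None],
) -> FeedbackState:
    """Update the display with the last two per-side propulsive peaks (N).

    The displayed value is the mean of the two peaks; it is on target when
    within ``tolerance_frac`` of the target (inclusive).  A missing side
    withholds the display and leaves the streak unchanged.
    """
    left, right = new_step_peaks
    if left is None or right is None:
        return fb
    displayed = 0.5 * (float(left) + float(right))
    on_target = abs(displayed - fb.target_fp) <= fb.tolerance_frac * fb.target_fp
    streak = fb.streak + 1 if on_target else 0
    return replace(fb, displayed_fp=displayed, on_target=on_target, streak=streak)
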