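"""Raw trial time series -> per-stance step records and per-trial summaries.

Gait events come from 20 N threshold crossings of the vertical ground reaction
force: an upward crossing marks heel strike, the following downward crossing
marks toe off.  Peak propulsive force (F_P) is the maximum anterior AP force
over the full stance; peak braking force (F_B) is the largest-magnitude
posterior AP force restricted to the first (temporal) half of stance.  Stride
duration is the time between consecutive ipsilateral heel strikes and stride
length the heel-marker displacement between them plus the belt travel over the
stride (treadmill-frame correction).  Trial summaries average all step, stride,
speed and metabolic outcomes over the final analysis window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .metabolics import MetabolicResult

__all__ = [
    "GRAVITY",
    "StepRecord",
    "TrialSummary",
    "detect_gait_events",
    "extract_step_peaks",
    "stride_metrics",
    "summarize_trial",
    "process_trial",
]

GRAVITY = 9.81  # m/s^2, for %BW normalization

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StepRecord:
    """One stance phase of one foot."""

    side: str  # "L" or "R"
    heel_strike: float  # s
    toe_off: float  # s
    peak_fp: float  # N, anterior maximum over stance
    peak_fp_time: float  # s
    peak_fb: float  # N, magnitude of posterior minimum in first half
    peak_fb_time: float  # s
    flags: tuple[str, ...] = field(default=())

    @property
    def stance_dur(self) -> float:
        return self.toe_off - self.heel_strike


@dataclass(frozen=True)
class TrialSummary:
    """Final-window averages for one trial."""

    participant_id: str
    clamp_type: str  # "speed" or "fp"
    intensity: float  # relative level, e.g. -0.2 .. +0.2
    mean_speed: float  # m/s
    mean_fp: float  # %BW
    mean_fb: float  # %BW
    stride_length: float  # m
    stride_duration: float  # s
    speed_sd_within: float  # m/s over the window
    net_power: float  # W/kg
    cot: float  # J/(kg*m)
    n_steps: int
    n_strides: int
    flags: tuple[str, ...] = field(default=())


def lowpass_filter(
    series: np.ndarray, rate: float, cutoff: float | None = None, order: int = 4
) -> np.ndarray:
    """Optional zero-phase Butterworth low-pass for measured force data.

    Synthetic waveforms are already smooth and are processed unfiltered
    (``cutoff=None`` returns the input unchanged); real force-plate data can
    be conditioned here before event detection.
    """
    if cutoff is None:
        return series
    if not 0 < cutoff < rate / 2:
        raise ValueError("cutoff must be in (0, Nyquist)")
    from scipy.signal import butter, filtfilt

    b, a = butter(order, cutoff / (rate / 2))
    return filtfilt(b, a, np.asarray(series, dtype=float))


def detect_gait_events(
    time: np.ndarray,
    vgrf: np.ndarray,
    threshold: float = 20.0,
    debounce: float = 0.05,
) -> list[tuple[float, float]]:
    """(heel_strike, toe_off) pairs from vertical GRF threshold crossings.

    Above-threshold segments separated by gaps shorter than ``debounce``
    seconds are merged, and merged segments shorter than ``debounce`` are
    dropped, which suppresses chatter from force noise near the threshold.
    Leading/trailing partial stances (series starting above threshold or
    ending mid-stance) are discarded.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    time = np.asarray(time, dtype=float)
    vgrf = np.asarray(vgrf, dtype=float)
    if time.shape != vgrf.shape:
        raise ValueError("time and vgrf must have the same shape")
    above = vgrf >= threshold
    if not above.any():
        logger.info("vertical GRF never crosses %.1f N; no events", threshold)
        return []
    edges = np.diff(above.astype(np.int8))
    rises = np.flatnonzero(edges == 1) + 1  # first sample above
    falls = np.flatnonzero(edges == -1) + 1  # first sample below
    if above[0]:  # drop leading partial stance
        falls = falls[1:] if falls.size and (not rises.size or falls[0] < rises[0]) else falls
    segments = []
    for r in rises:
        f = falls[falls > r]
        if not f.size:
            break  # trailing partial stance
        segments.append((r, int(f[0])))
    # merge segments separated by < debounce
    merged: list[list[int]] = []
    for r, f in segments:
        if merged and time[r] - time[merged[-1][1]] < debounce:
            merged[-1][1] = f
        else:
            merged.append([r, f])
    events = [
        (float(time[r]), float(time[f]))
        for r, f in merged
        if time[f] - time[r] >= debounce
    ]
    return events


def extract_step_peaks(
    time: np.ndarray,
    apgrf: np.ndarray,
    events: list[tuple[float, float]],
    side: str,
) -> list[StepRecord]:
    """Per-stance F_P / F_B peaks from the anterior-positive AP force series."""
    time = np.asarray(time, dtype=float)
    apgrf = np.asarray(apgrf, dtype=float)
    records: list[StepRecord] = []
    for hs, to in events:
        if to <= hs:
            raise ValueError("toe off must follow heel strike")
        stance = (time >= hs) & (time <= to)
        if not stance.any():
            continue
        ap = apgrf[stance]
        ts = time[stance]
        flags: tuple[str, ...] = ()
        if np.max(ap) > 0:
            i_fp = int(np.argmax(ap))
            peak_fp, t_fp = float(ap[i_fp]), float(ts[i_fp])
        else:
            peak_fp, t_fp = 0.0, float(hs)
            flags = ("no_propulsion",)
        mid = 0.5 * (hs + to)
        first = ts <= mid
        ap1 = ap[first]
        if ap1.size and np.min(ap1) < 0:
            i_fb = int(np.argmin(ap1))
            peak_fb, t_fb = float(-ap1[i_fb]), float(ts[first][i_fb])
        else:
            peak_fb, t_fb = 0.0, float(hs)
            flags = flags + ("no_braking",)
        records.append(
            StepRecord(side, float(hs), float(to), peak_fp, t_fp, peak_fb, t_fb, flags)
        )
    return records


def stride_metrics(
    time: np.ndarray,
    heel_ap: np.ndarray,
    heel_strikes: list[float],
    belt_speed: np.ndarray,
) -> list[tuple[float, float, float]]:
    """(stride_start, stride_length, stride_duration) for one side.

    Stride duration is the interval between consecutive ipsilateral heel
    strikes.  Stride length is the lab-frame heel displacement between those
    events plus the belt travel over the stride; on a treadmill the belt
    travel dominates and the marker term corrects for fore-aft drift.
    """
    time = np.asarray(time, dtype=float)
    heel_ap = np.asarray(heel_ap, dtype=float)
    belt_speed = np.asarray(belt_speed, dtype=float)
    if len(heel_strikes) < 2:
        if len(heel_strikes) == 1:
            logger.info("single heel strike: no stride metrics")
        return []
    dt = np.diff(time)
    belt_travel = np.concatenate([[0.0], np.cumsum(0.5 * (belt_speed[1:] + belt_speed[:-1]) * dt)])
    out = []
    for t1, t2 in zip(heel_strikes[:-1], heel_strikes[1:]):
        dur = t2 - t1
        x1, x2 = np.interp([t1, t2], time, heel_ap)
        travel = np.interp(t2, time, belt_travel) - np.interp(t1, time, belt_travel)
        out.append((float(t1), float(x2 - x1 + travel), float(dur)))
    return out


def summarize_trial(
    participant_id: str,
    clamp_type: str,
    intensity: float,
    mass: float,
    time: np.ndarray,
    belt_speed: np.ndarray,
    steps: list[StepRecord],
    strides: list[tuple[float, float, float]],
    metabolic: MetabolicResult,
    window: float = 120.0,
    min_steps: int = 10,
) -> TrialSummary:
    """Average everything over events falling in the final ``window`` seconds.

    Steps/strides contribute only if they *begin* inside the window; F_P and
    F_B are normalized to %BW with g = 9.81 m/s^2.
    """
    if mass <= 0:
        raise ValueError("mass must be > 0")
    time = np.asarray(time, dtype=float)
    t_end = float(time[-1])
    if t_end - float(time[0]) < window:
        raise ValueError("trial shorter than analysis window")
    t0 = t_end - window
    in_win = [s for s in steps if s.heel_strike >= t0]
    flags: list[str] = []
    if len(in_win) < min_steps:
        flags.append("low_confidence_few_steps")
    bw = mass * GRAVITY
    mean_fp = 100.0 * float(np.mean([s.peak_fp for s in in_win])) / bw if in_win else float("nan")
    mean_fb = 100.0 * float(np.mean([s.peak_fb for s in in_win])) / bw if in_win else float("nan")
    win_mask = time >= t0
    mean_speed = float(np.mean(np.asarray(belt_speed)[win_mask]))
    speed_sd = float(np.std(np.asarray(belt_speed)[win_mask]))
    strides_in = [s for s in strides if s[0] >= t0]
    stride_len = float(np.mean([s[1] for s in strides_in])) if strides_in else float("nan")
    stride_dur = float(np.mean([s[2] for s in strides_in])) if strides_in else float("nan")
    if metabolic.cot is not None:
        cot = metabolic.cot
    else:
        cot = metabolic.net_power_per_kg / mean_speed
    flags.extend(metabolic.flags)
    return TrialSummary(
        participant_id=participant_id,
        clamp_type=clamp_type,
        intensity=float(intensity),
        mean_speed=mean_speed,
        mean_fp=mean_fp,
        mean_fb=mean_fb,
        stride_length=stride_len,
        stride_duration=stride_dur,
        speed_sd_within=speed_sd,
        net_power=metabolic.net_power_per_kg,
        cot=cot,
        n_steps=len(in_win),
        n_strides=len(strides_in),
        flags=tuple(flags),
    )


def process_trial(raw, mass: float, standing_power_w: float, window: float = 120.0) -> TrialSummary:
    """Full chain on one TrialRaw: events -> peaks -> strides -> metabolics -> summary.

    ``raw`` is a :class:`gaitclamp.synthetic_gait.TrialRaw` (or any object with
    the same columnar attributes).  ``standing_power_w`` is the measured
    standing baseline in watts.
    """
    from .metabolics import process_breaths

    steps: list[StepRecord] = []
    strides: list[tuple[float, float, float]] = []
    for side in ("L", "R"):
        vgrf = raw.grf_vertical_l if side == "L" else raw.grf_vertical_r
        ap = raw.grf_ap_l if side == "L" else raw.grf_ap_r
        heel = raw.heel_ap_l if side == "L" else raw.heel_ap_r
        events = detect_gait_events(raw.time, vgrf)
        steps.extend(extract_step_peaks(raw.time, ap, events, side))
        strides.extend(stride_metrics(raw.time, heel, [hs for hs, _ in events], raw.belt_speed))
    steps.sort(key=lambda s: s.heel_strike)
    strides.sort(key=lambda s: s[0])
    t0 = float(raw.time[-1]) - window
    win_mask = raw.time >= t0
    mean_speed = float(np.mean(raw.belt_speed[win_mask]))
    metabolic = process_breaths(
        raw.breaths, mass=mass, standing_power=standing_power_w,
        mean_speed=mean_speed, trial_end=float(raw.time[-1]), window=window,
    )
    return summarize_trial(
        raw.participant_id, raw.clamp_type, raw.intensity, mass,
        raw.time, raw.belt_speed, steps, strides, metabolic, window=window,
    )
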