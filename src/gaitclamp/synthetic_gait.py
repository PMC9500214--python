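"""Synthetic cohort and raw-trial generator for the clamp experiment.

Generates virtual participants and per-trial raw time series (bilateral
vertical and anterior-posterior ground reaction forces, center of pressure,
heel markers, belt speed, breath-by-breath gas exchange) for two trial kinds:

* fixed-speed trials ("speed clamp"): the belt holds the participant's
  preferred speed scaled by a condition intensity while the propulsive force
  follows the participant's calibrated speed-force response;
* self-paced trials ("fp clamp"): the walker targets a prescribed peak
  propulsive force, walks at the speed its force response implies, and the
  dead-zone treadmill controller closes the loop through the center of
  pressure.

The generator is calibrated so that the downstream pipeline (event detection,
peak extraction, stride metrics, indirect calorimetry, pooled regressions)
recovers a target set of group statistics.  Residual standard deviations are
derived from target pooled R-squared values by variance decomposition
(``residual_sd_for_r2``); remaining coefficients are fixed calibration
constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np

from .metabolics import (
    BROCKWAY_CO2_KJ_PER_L,
    BROCKWAY_O2_KJ_PER_L,
    BreathSample,
)
from .selfpace_controller import (
    ControllerState,
    FeedbackState,
    cop_double_support_average,
    feedback_update,
    speed_update,
)

__all__ = [
    "GRAVITY",
    "NoiseScales",
    "EconCoeffs",
    "CalibrationParams",
    "DerivedResiduals",
    "CohortConfig",
    "ParticipantProfile",
    "TrialRaw",
    "residual_sd_for_r2",
    "make_cohort",
    "generate_stance_waveforms",
    "simulate_fixed_speed_trial",
    "simulate_selfpaced_trial",
    "generate_breath_series",
    "generate_standing_breaths",
    "net_power_surface",
]

GRAVITY = 9.81

# stream tags for per-purpose child RNGs under one root seed
_STREAM_COHORT = 0
_STREAM_TRIAL = 1
_STREAM_STANDING = 2

# gait geometry: stance occupies 60% of the stride, each double support 10%
_STANCE_FRAC = 0.60
_DS_FRAC = 0.10
_HEEL_AT_STRIKE = 0.20  # m anterior of treadmill center, lab frame


def residual_sd_for_r2(signal_var: float, r2: float) -> float:
    """Residual SD so that signal_var/(signal_var + sd^2) equals ``r2``.

    Inverts the pooled variance decomposition R^2 = var(signal) /
    (var(signal) + var(residual)).  Zero signal variance maps to zero
    residual (the zero-noise limit).
    """
    if not 0 < r2 <= 1:
        raise ValueError("r2 must be in (0, 1]")
    if signal_var < 0:
        raise ValueError("signal_var must be >= 0")
    return math.sqrt(signal_var * (1.0 - r2) / r2)


@dataclass(frozen=True)
class NoiseScales:
    """Per-channel noise SDs attached to a participant (all >= 0)."""

    fp_step_rel: float = 0.03  # step-to-step F_P noise, relative
    fb_step_rel: float = 0.03
    vgrf_peak_rel: float = 0.03
    stride_jitter: float = 0.012  # s, stride-to-stride
    cop_noise: float = 0.05  # m, walker positional noise per double support
    breath_rel: float = 0.02  # per-breath multiplicative

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be >= 0")


@dataclass(frozen=True)
class EconCoeffs:
    """Participant-level net-power response surface coefficients.

    ``cot(v) = cot_norm * (1 + curvature*(v/v_pref - 1)^2 + tilt*(v/v_pref - 1))``
    and ``net_power = cot(v) * v + fp_coupling * fp_resid`` where ``fp_resid``
    is the trial's propulsive-force deviation from the speed-implied value.
    """

    cot_norm: float  # J/(kg*m) at preferred speed
    curvature: float
    tilt: float
    fp_coupling: float  # W/kg per BW-fraction of F_P deviation


@dataclass(frozen=True)
class CalibrationParams:
    """Population statistics, response slopes and noise calibration.

    Residual SDs that control the pooled R-squared values are not stored
    directly; they are derived from the ``r2_*`` targets by variance
    decomposition (see :meth:`derived`).
    """

    # population anthropometrics / behavior
    pop_mean_speed: float = 1.41  # m/s
    pop_sd_speed: float = 0.09
    pop_mean_fp_frac: float = 0.220  # peak F_P as fraction of body weight
    pop_sd_fp_frac: float = 0.023
    pop_mean_fb_frac: float = 0.210
    mass_mean: float = 75.6  # kg
    mass_sd: float = 13.7
    height_mean: float = 1.77  # m
    height_sd: float = 0.11
    standing_power_mean: float = 1.4  # W/kg
    standing_power_sd: float = 0.15

    # speed <-> force response (BW fraction per m/s).  The F_P slope equals
    # pop_sd_fp_frac / pop_sd_speed so habitual F_P sits on the common line
    # with the stated marginal SDs; the F_B slope is shallower by the ratio
    # of the two calibrated speed regressions.
    fp_frac_per_speed: float = 0.2556
    fb_frac_per_speed: float = 0.2218

    # stride timing: linear stride-duration response to speed
    stride_dur_base: float = 1.08  # s at preferred speed
    stride_dur_subject_sd: float = 0.05
    stride_dur_slope: float = -0.29  # s per m/s

    # metabolic response surface
    cot_norm_mean: float = 2.8  # J/(kg*m)
    cot_norm_sd: float = 0.18
    cot_curvature: float = 1.9
    cot_tilt: float = 0.32
    fp_power_coupling: float = 30.0  # W/kg per BW fraction
    power_trial_sd: float = 0.60  # W/kg
    fp_clamp_power_sd_extra: float = 0.25  # extra trial SD, fp clamp only

    # target pooled R^2 values driving the residual decomposition
    r2_speed_fp_speed_clamp: float = 0.85
    r2_speed_fp_fp_clamp: float = 0.76
    r2_speed_fb: float = 0.575
    r2_speed_stride_dur: float = 0.47

    # fp-clamp offsets relative to the speed clamp (multiplicative).  The
    # speed offset is applied on top of the speed increase the F_P offset
    # already implies through the force-speed line, and the power multiplier
    # on top of the speed-mediated power increase.
    clamp_speed_offset: float = 1.017
    clamp_fp_offset: float = 1.016
    clamp_power_mult: float = 1.015
    clamp_speed_offset_sd_rel: float = 0.090  # trial-level, fp clamp only
    clamp_fp_track_sd_rel: float = 0.05  # force-tracking deviation, fp clamp

    # waveform / physiology constants
    vertical_peak_bw: float = 1.15
    cop_gain: float = 1.42  # s: CoP offset per unit speed-intent mismatch
    breath_tau: float = 30.0  # s, onset time constant
    rer: float = 0.85
    zero_noise: bool = False
    noise: NoiseScales = field(default_factory=NoiseScales)

    def derived(self, intensities: tuple[float, ...]) -> "DerivedResiduals":
        """Residual SDs implied by the R^2 targets for a given design."""
        if self.zero_noise:
            return DerivedResiduals(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
        var_delta = float(np.var(np.asarray(intensities)))
        v = self.pop_mean_speed
        pooled_speed_var = v * v * var_delta + self.pop_sd_speed**2 * (1 + var_delta)
        beta = self.fp_frac_per_speed
        fp_total = residual_sd_for_r2(
            beta**2 * pooled_speed_var, self.r2_speed_fp_speed_clamp
        )
        fp_subj = math.sqrt(
            max(0.0, self.pop_sd_fp_frac**2 - (beta * self.pop_sd_speed) ** 2)
        )
        fp_trial = math.sqrt(max(0.0, fp_total**2 - fp_subj**2))
        beta_b = self.fb_frac_per_speed
        fb_total = residual_sd_for_r2(beta_b**2 * pooled_speed_var, self.r2_speed_fb)
        fb_subj = fb_trial = fb_total / math.sqrt(2.0)
        st_total = residual_sd_for_r2(
            self.stride_dur_slope**2 * pooled_speed_var, self.r2_speed_stride_dur
        )
        st_trial = math.sqrt(max(0.0, st_total**2 - self.stride_dur_subject_sd**2))
        return DerivedResiduals(
            pooled_speed_var=pooled_speed_var,
            fp_subject_sd=fp_subj,
            fp_trial_sd=fp_trial,
            fb_subject_sd=fb_subj,
            fb_trial_sd=fb_trial,
            stride_trial_sd=st_trial,
        )

    def zeroed(self) -> "CalibrationParams":
        """Copy with every noise source and population SD set to zero.

        With zero SDs the derived residuals also vanish, so the pipeline must
        recover R^2 = 1 and the calibration slopes exactly (zero-noise
        closure).  Offsets and slopes are preserved.
        """
        zeros = {f.name: 0.0 for f in fields(self) if "_sd" in f.name}
        zeros["noise"] = NoiseScales(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
        zeros["zero_noise"] = True
        return replace(self, **zeros)


@dataclass(frozen=True)
class DerivedResiduals:
    pooled_speed_var: float
    fp_subject_sd: float
    fp_trial_sd: float
    fb_subject_sd: float
    fb_trial_sd: float
    stride_trial_sd: float


@dataclass(frozen=True)
class CohortConfig:
    n_participants: int = 20
    intensities: tuple[float, ...] = (-0.20, -0.10, 0.0, 0.10, 0.20)
    trial_duration: float = 300.0  # s
    analysis_window: float = 120.0  # s
    packet_rate: float = 20.0  # Hz (packets carry the analog samples)
    analog_rate: float = 100.0  # Hz
    seed: int = 0
    calibration: CalibrationParams = field(default_factory=CalibrationParams)

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        if self.trial_duration <= self.analysis_window:
            raise ValueError("trial_duration must exceed analysis_window")
        if not any(abs(i) < 1e-12 for i in self.intensities):
            raise ValueError("intensities must include 0 (Norm)")
        if self.analog_rate <= 0:
            raise ValueError("analog_rate must be > 0")


@dataclass(frozen=True)
class ParticipantProfile:
    id: str
    index: int
    mass: float  # kg
    height: float  # m
    preferred_speed: float  # m/s
    habitual_fp_frac: float  # peak F_P / body weight
    habitual_fb_frac: float
    fp_speed_slope: float  # m/s per BW fraction (speed implied by F_P)
    cadence_base: float  # strides/s at preferred speed
    stride_dur_base: float  # s
    standing_power: float  # W/kg
    econ_coeffs: EconCoeffs
    noise_scales: NoiseScales

    def __post_init__(self) -> None:
        if self.mass <= 0 or self.preferred_speed <= 0:
            raise ValueError("mass and preferred_speed must be > 0")
        if not 0 < self.habitual_fp_frac < 1:
            raise ValueError("habitual_fp_frac must be in (0, 1)")


@dataclass
class TrialRaw:
    """One trial's raw series; all force/position series share ``time``."""

    participant_id: str
    clamp_type: str  # "speed" | "fp"
    intensity: float
    time: np.ndarray
    grf_vertical_l: np.ndarray
    grf_vertical_r: np.ndarray
    grf_ap_l: np.ndarray
    grf_ap_r: np.ndarray
    cop_ap: np.ndarray
    heel_ap_l: np.ndarray
    heel_ap_r: np.ndarray
    belt_speed: np.ndarray
    breaths: list[BreathSample]
    meta: dict = field(default_factory=dict)


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed)] + [int(s) for s in stream])


def make_cohort(config: CohortConfig) -> list[ParticipantProfile]:
    """Draw ``n_participants`` profiles from the calibrated population.

    Habitual F_P lies on the common speed-F_P line plus any subject-level
    deviation the calibrated marginal SD leaves room for, so that the cohort
    SD of habitual F_P matches ``pop_sd_fp_frac``.
    """
    cal = config.calibration
    der = cal.derived(config.intensities)
    rng = _rng(config.seed, _STREAM_COHORT)
    profiles = []
    for i in range(config.n_participants):
        v = float(np.clip(rng.normal(cal.pop_mean_speed, cal.pop_sd_speed), 0.8, 2.2))
        fp = cal.pop_mean_fp_frac + cal.fp_frac_per_speed * (v - cal.pop_mean_speed)
        fp += rng.normal(0.0, der.fp_subject_sd)
        fb = cal.pop_mean_fb_frac + cal.fb_frac_per_speed * (v - cal.pop_mean_speed)
        fb += rng.normal(0.0, der.fb_subject_sd)
        mass = float(np.clip(rng.normal(cal.mass_mean, cal.mass_sd), 45.0, 120.0))
        height = float(np.clip(rng.normal(cal.height_mean, cal.height_sd), 1.45, 2.10))
        t_stride = float(
            np.clip(rng.normal(cal.stride_dur_base, cal.stride_dur_subject_sd), 0.8, 1.4)
        )
        standing = float(
            np.clip(rng.normal(cal.standing_power_mean, cal.standing_power_sd), 0.8, 2.2)
        )
        cot_norm = float(np.clip(rng.normal(cal.cot_norm_mean, cal.cot_norm_sd), 1.5, 4.5))
        profiles.append(
            ParticipantProfile(
                id=f"P{i:02d}",
                index=i,
                mass=mass,
                height=height,
                preferred_speed=v,
                habitual_fp_frac=float(np.clip(fp, 0.08, 0.42)),
                habitual_fb_frac=float(np.clip(fb, 0.06, 0.40)),
                fp_speed_slope=1.0 / cal.fp_frac_per_speed,
                cadence_base=1.0 / t_stride,
                stride_dur_base=t_stride,
                standing_power=standing,
                econ_coeffs=EconCoeffs(
                    cot_norm=cot_norm,
                    curvature=cal.cot_curvature,
                    tilt=cal.cot_tilt,
                    fp_coupling=cal.fp_power_coupling,
                ),
                noise_scales=cal.noise,
            )
        )
    return profiles


def _hann_lobe(tau: np.ndarray, center: float, width: float) -> np.ndarray:
    out = np.zeros_like(tau)
    m = np.abs(tau - center) <= width / 2.0
    out[m] = np.cos(np.pi * (tau[m] - center) / width) ** 2
    return out


def generate_stance_waveforms(
    profile: ParticipantProfile,
    speed: float,
    fp_peak: float,
    stance_dur: float,
    rate: float,
    fb_peak: float | None = None,
    vertical_peak_bw: float = 1.15,
) -> tuple[np.ndarray, np.ndarray]:
    """Vertical and AP ground-reaction waveforms for one stance.

    The vertical force is a double-humped sum of two Hann lobes rising from
    and returning to zero; the AP force has one posterior (braking) lobe in
    the first half of stance and one anterior (propulsive) lobe peaking at
    exactly ``fp_peak`` in the second half.  The braking lobe width is set so
    its impulse balances the propulsive impulse (steady-speed walking);
    its peak defaults to the profile's habitual braking/propulsion ratio.
    """
    if fp_peak <= 0 or stance_dur <= 0:
        raise ValueError("fp_peak and stance_dur must be > 0")
    n = int(round(stance_dur * rate))
    if n < 4:
        raise ValueError("stance_dur shorter than 4 samples at this rate")
    tau = np.linspace(0.0, 1.0, n)
    amp = vertical_peak_bw * profile.mass * GRAVITY
    vertical = amp * (_hann_lobe(tau, 0.30, 0.60) + _hann_lobe(tau, 0.70, 0.60))
    if fb_peak is None:
        fb_peak = fp_peak * profile.habitual_fb_frac / profile.habitual_fp_frac
    w_prop = 0.35
    prop = _hann_lobe(tau, 0.80, w_prop)
    prop *= fp_peak / prop.max()
    # braking lobe width balances the propulsive impulse; keep at least a few
    # samples on the grid and inside the first half of stance
    w_brake = float(np.clip(w_prop * fp_peak / fb_peak, 4.0 / n, 0.39))
    brake = _hann_lobe(tau, 0.20, w_brake)
    peak = brake.max()
    if peak > 0:
        brake *= -fb_peak / peak
    return vertical, brake + prop


@dataclass(frozen=True)
class _Step:
    side: str
    hs: float  # s
    stance_dur: float
    stride_dur: float
    fp_peak: float  # N
    fb_peak: float  # N
    vpeak_bw: float


def _plan_steps(
    profile: ParticipantProfile,
    stride_dur: float,
    duration: float,
    fp_frac: float,
    fb_frac: float,
    cal: CalibrationParams,
    rng: np.random.Generator,
    start: float = 0.5,
) -> list[_Step]:
    """Alternating L/R stances with per-stride jitter and per-step peak noise."""
    ns = profile.noise_scales
    bw = profile.mass * GRAVITY
    steps: list[_Step] = []
    t = start
    while t < duration:
        t_k = stride_dur + rng.normal(0.0, ns.stride_jitter)
        t_k = max(t_k, 0.5)
        for side, offset in (("L", 0.0), ("R", 0.5 * t_k)):
            hs = t + offset
            if hs >= duration:
                continue
            fp = fp_frac * bw * (1.0 + rng.normal(0.0, ns.fp_step_rel))
            fb = fb_frac * bw * (1.0 + rng.normal(0.0, ns.fb_step_rel))
            vp = cal.vertical_peak_bw * (1.0 + rng.normal(0.0, ns.vgrf_peak_rel))
            steps.append(
                _Step(side, hs, _STANCE_FRAC * t_k, t_k, max(fp, 1.0), max(fb, 1.0),
                      float(np.clip(vp, 0.85, 1.45)))
            )
        t += t_k
    steps.sort(key=lambda s: s.hs)
    return steps


def _fill_forces_and_heels(
    raw: TrialRaw, steps: list[_Step], profile: ParticipantProfile, rate: float
) -> None:
    t = raw.time
    n = t.size
    dt = 1.0 / rate
    belt = raw.belt_speed
    travel = np.concatenate([[0.0], np.cumsum(0.5 * (belt[1:] + belt[:-1]) * np.diff(t))])
    heel = {"L": np.full(n, _HEEL_AT_STRIKE), "R": np.full(n, _HEEL_AT_STRIKE)}
    last_end = {"L": 0, "R": 0}
    last_val = {"L": _HEEL_AT_STRIKE, "R": _HEEL_AT_STRIKE}
    for s in steps:
        i0 = int(round(s.hs * rate))
        i1 = min(int(round((s.hs + s.stance_dur) * rate)), n)
        if i1 - i0 < 4 or i0 >= n:
            continue
        vert, ap = generate_stance_waveforms(
            profile, float(belt[i0]), s.fp_peak, (i1 - i0) * dt, rate,
            fb_peak=s.fb_peak, vertical_peak_bw=s.vpeak_bw,
        )
        m = min(len(vert), i1 - i0)
        if s.side == "L":
            raw.grf_vertical_l[i0:i0 + m] = vert[:m]
            raw.grf_ap_l[i0:i0 + m] = ap[:m]
        else:
            raw.grf_vertical_r[i0:i0 + m] = vert[:m]
            raw.grf_ap_r[i0:i0 + m] = ap[:m]
        # heel: swing blend from previous stance end to strike position,
        # then ride backwards with the belt during stance
        h = heel[s.side]
        j0 = last_end[s.side]
        if i0 > j0:
            frac = 0.5 * (1 - np.cos(np.pi * np.linspace(0, 1, i0 - j0)))
            h[j0:i0] = last_val[s.side] + (_HEEL_AT_STRIKE - last_val[s.side]) * frac
        h[i0:i0 + m] = _HEEL_AT_STRIKE - (travel[i0:i0 + m] - travel[i0])
        last_end[s.side] = i0 + m
        last_val[s.side] = h[i0 + m - 1]
    for side in ("L", "R"):
        heel[side][last_end[side]:] = last_val[side]
    raw.heel_ap_l[:] = heel["L"]
    raw.heel_ap_r[:] = heel["R"]


def _measured_mean_fp_frac(steps: list[_Step], profile: ParticipantProfile,
                           t0: float, t1: float) -> float:
    bw = profile.mass * GRAVITY
    peaks = [s.fp_peak for s in steps if t0 <= s.hs <= t1]
    return float(np.mean(peaks)) / bw if peaks else float("nan")


def simulate_fixed_speed_trial(
    profile: ParticipantProfile,
    intensity: float,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
) -> TrialRaw:
    """One 'speed clamp' trial: constant belt at preferred*(1+intensity)."""
    if not any(abs(intensity - i) < 1e-12 for i in config.intensities):
        raise ValueError(f"intensity {intensity} not in config.intensities")
    cal = config.calibration
    der = cal.derived(config.intensities)
    if rng is None:
        idx = config.intensities.index(intensity) if intensity in config.intensities else 0
        rng = _rng(config.seed, _STREAM_TRIAL, profile.index, 0, idx)
    v = profile.preferred_speed * (1.0 + intensity)
    beta = cal.fp_frac_per_speed
    fp_resid = float(rng.normal(0.0, der.fp_trial_sd))
    fp_frac = float(np.clip(
        profile.habitual_fp_frac + beta * profile.preferred_speed * intensity + fp_resid,
        0.06, 0.44,
    ))
    fb_frac = float(np.clip(
        profile.habitual_fb_frac
        + cal.fb_frac_per_speed * profile.preferred_speed * intensity
        + rng.normal(0.0, der.fb_trial_sd),
        0.05, 0.42,
    ))
    stride = float(np.clip(
        profile.stride_dur_base
        + cal.stride_dur_slope * (v - profile.preferred_speed)
        + rng.normal(0.0, der.stride_trial_sd),
        0.7, 1.6,
    ))
    rate = config.analog_rate
    n = int(round(config.trial_duration * rate))
    time = np.arange(n) / rate
    raw = TrialRaw(
        participant_id=profile.id,
        clamp_type="speed",
        intensity=float(intensity),
        time=time,
        grf_vertical_l=np.zeros(n),
        grf_vertical_r=np.zeros(n),
        grf_ap_l=np.zeros(n),
        grf_ap_r=np.zeros(n),
        cop_ap=rng.normal(0.0, 0.01 if profile.noise_scales.cop_noise > 0 else 0.0, n),
        heel_ap_l=np.zeros(n),
        heel_ap_r=np.zeros(n),
        belt_speed=np.full(n, v),
        breaths=[],
        meta={"fp_frac_planned": fp_frac, "stride_planned": stride},
    )
    steps = _plan_steps(profile, stride, config.trial_duration, fp_frac, fb_frac, cal, rng)
    _fill_forces_and_heels(raw, steps, profile, rate)
    t_end = config.trial_duration
    f_meas = _measured_mean_fp_frac(steps, profile, t_end - config.analysis_window, t_end)
    raw.breaths = generate_breath_series(
        profile, v, f_meas, "speed", config.trial_duration, rng=rng, calibration=cal,
        fp_resid=fp_resid,
    )
    return raw


def simulate_selfpaced_trial(
    profile: ParticipantProfile,
    fp_target: float,
    controller: ControllerState,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
    intensity: float = 0.0,
) -> TrialRaw:
    """One self-paced 'fp clamp' trial targeting ``fp_target`` newtons.

    The walker attempts the target with trial-level bias and tracking noise;
    its intended speed is the speed its own force-speed line implies for the
    realized force, times the fp-clamp speed offset.  Its CoP during each
    double support sits ``cop_gain * (intended - belt speed)`` from the
    treadmill center (plus positional noise) and the dead-zone controller
    updates the belt once per double support.
    """
    if fp_target <= 0:
        raise ValueError("fp_target must be > 0")
    cal = config.calibration
    der = cal.derived(config.intensities)
    if rng is None:
        idxs = [i for i, x in enumerate(config.intensities) if abs(x - intensity) < 1e-12]
        rng = _rng(config.seed, _STREAM_TRIAL, profile.index, 1, idxs[0] if idxs else 9)
    ns = profile.noise_scales
    bw = profile.mass * GRAVITY
    beta = cal.fp_frac_per_speed
    target_frac = fp_target / bw
    intent_frac = float(np.clip(target_frac * cal.clamp_fp_offset, 0.06, 0.44))
    track = float(rng.normal(0.0, cal.clamp_fp_track_sd_rel))
    fp_frac = float(np.clip(intent_frac * (1.0 + track), 0.06, 0.44))
    mult = cal.clamp_speed_offset * (1.0 + rng.normal(0.0, cal.clamp_speed_offset_sd_rel))
    v_intent_base = (
        profile.preferred_speed + (intent_frac - profile.habitual_fp_frac) / beta
    ) * mult
    v_intent_base = float(np.clip(v_intent_base, controller.speed_min + 0.05,
                                  controller.speed_max - 0.05))
    fb_frac = float(np.clip(
        profile.habitual_fb_frac
        + cal.fb_frac_per_speed * (v_intent_base - profile.preferred_speed)
        + rng.normal(0.0, der.fb_trial_sd),
        0.05, 0.42,
    ))
    stride = float(np.clip(
        profile.stride_dur_base
        + cal.stride_dur_slope * (v_intent_base - profile.preferred_speed)
        + rng.normal(0.0, der.stride_trial_sd),
        0.7, 1.6,
    ))
    rate = config.analog_rate
    n = int(round(config.trial_duration * rate))
    time = np.arange(n) / rate
    raw = TrialRaw(
        participant_id=profile.id,
        clamp_type="fp",
        intensity=float(intensity),
        time=time,
        grf_vertical_l=np.zeros(n),
        grf_vertical_r=np.zeros(n),
        grf_ap_l=np.zeros(n),
        grf_ap_r=np.zeros(n),
        cop_ap=np.zeros(n),
        heel_ap_l=np.zeros(n),
        heel_ap_r=np.zeros(n),
        belt_speed=np.zeros(n),
        breaths=[],
        meta={"fp_target": fp_target, "v_intent_base": v_intent_base, "events": []},
    )
    steps = _plan_steps(profile, stride, config.trial_duration, fp_frac, fb_frac, cal, rng)
    # closed loop: one controller update per double support (at each heel strike)
    state = controller
    fb_state = FeedbackState(target_fp=fp_target)
    on_target = 0
    belt = raw.belt_speed
    cop = raw.cop_ap
    trace = []
    last_idx = 0
    last_peaks: dict[str, float | None] = {"L": None, "R": None}
    for s in steps:
        i_ds0 = int(round(s.hs * rate))
        i_ds1 = min(int(round((s.hs + _DS_FRAC * s.stride_dur) * rate)), n)
        if i_ds0 >= n:
            break
        belt[last_idx:max(i_ds1, i_ds0 + 1)] = state.belt_speed
        last_idx = max(i_ds1, i_ds0 + 1)
        # walker model: step-level speed intent follows the *intended* force
        # (the tracking deviation of the realized force does not steer speed)
        step_frac = s.fp_peak / bw / (1.0 + track)
        v_int = (
            profile.preferred_speed + (step_frac - profile.habitual_fp_frac) / beta
        ) * mult
        cop_val = cal.cop_gain * (v_int - state.belt_speed)
        cop_val += rng.normal(0.0, ns.cop_noise)
        cop_val = float(np.clip(cop_val, -0.9, 0.9))
        if i_ds1 > i_ds0:
            cop[i_ds0:i_ds1] = cop_val
            avg = cop_double_support_average(cop, slice(i_ds0, i_ds1))
        else:
            avg = cop_val
        prev = state.belt_speed
        state = speed_update(state, avg)
        if state.belt_speed in (state.speed_min, state.speed_max) and prev != state.belt_speed:
            raw.meta["events"].append(("speed_bound", s.hs, state.belt_speed))
        trace.append((s.hs, avg, state.belt_speed - prev, state.belt_speed))
        last_peaks[s.side] = s.fp_peak
        fb_state = feedback_update(fb_state, (last_peaks["L"], last_peaks["R"]))
        on_target += int(fb_state.on_target)
    belt[last_idx:] = state.belt_speed
    raw.meta["controller_trace"] = trace
    raw.meta["on_target_steps"] = on_target
    _fill_forces_and_heels(raw, steps, profile, rate)
    t_end = config.trial_duration
    win = config.analysis_window
    mask = time >= t_end - win
    v_real = float(np.mean(belt[mask]))
    f_meas = _measured_mean_fp_frac(steps, profile, t_end - win, t_end)
    # force deviation orthogonal to the walker's own speed choice
    fp_resid = fp_frac - intent_frac
    raw.breaths = generate_breath_series(
        profile, v_real, f_meas, "fp", config.trial_duration, rng=rng,
        calibration=cal, fp_resid=fp_resid,
    )
    return raw


def net_power_surface(
    profile: ParticipantProfile,
    speed: float,
    fp_resid: float,
    clamp_type: str,
    calibration: CalibrationParams,
) -> float:
    """Deterministic net metabolic power (W/kg) for a trial.

    Cost of transport is U-shaped in relative speed around the participant's
    preferred speed with a linear tilt (minimum slightly below preferred, so
    the -20% condition returns to the Norm cost); net power adds a coupling
    to the trial's propulsive-force deviation and, for fp-clamp trials, the
    clamp multiplier.
    """
    e = profile.econ_coeffs
    vr = speed / profile.preferred_speed - 1.0
    cot = e.cot_norm * (1.0 + e.curvature * vr * vr + e.tilt * vr)
    power = cot * speed + e.fp_coupling * fp_resid
    if clamp_type == "fp":
        power *= calibration.clamp_power_mult
    return power


def generate_breath_series(
    profile: ParticipantProfile,
    mean_speed: float,
    mean_fp_frac: float,
    clamp_type: str,
    duration: float,
    rng: np.random.Generator,
    calibration: CalibrationParams,
    fp_resid: float = 0.0,
) -> list[BreathSample]:
    """Breath-by-breath V̇O2/V̇CO2 realizing the calibrated net power.

    Steady-state gas exchange is set by inverting the Brockway conversion so
    that the processing chain (time-weighted final-window average, Brockway
    power, standing subtraction, mass normalization) recovers the surface
    value plus trial noise.  A single-exponential onset from the standing
    level occupies the early minutes; breath spacing is irregular (2-5 s).
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    cal = calibration
    power = net_power_surface(profile, mean_speed, fp_resid, clamp_type, cal)
    sd = cal.power_trial_sd
    if clamp_type == "fp":
        sd = math.hypot(sd, cal.fp_clamp_power_sd_extra)
    power = max(power + rng.normal(0.0, sd), 0.4)
    standing_w = profile.standing_power * profile.mass
    gross_ss = standing_w + power * profile.mass
    w_per_lmin = (BROCKWAY_O2_KJ_PER_L + BROCKWAY_CO2_KJ_PER_L * cal.rer) * 1000.0 / 60.0
    breaths: list[BreathSample] = []
    t = float(rng.uniform(1.0, 3.0)) if profile.noise_scales.breath_rel > 0 else 2.0
    while t < duration:
        w = standing_w + (gross_ss - standing_w) * (1.0 - math.exp(-t / cal.breath_tau))
        vo2 = w / w_per_lmin * (1.0 + rng.normal(0.0, profile.noise_scales.breath_rel))
        vo2 = max(vo2, 0.0)
        breaths.append(BreathSample(t=t, vo2=vo2, vco2=cal.rer * vo2))
        t += float(rng.uniform(2.0, 5.0))
    return breaths


def generate_standing_breaths(
    profile: ParticipantProfile,
    duration: float,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
) -> list[BreathSample]:
    """Quiet-standing baseline collection at the profile's standing power."""
    if rng is None:
        rng = _rng(config.seed, _STREAM_STANDING, profile.index)
    cal = config.calibration
    standing_w = profile.standing_power * profile.mass
    w_per_lmin = (BROCKWAY_O2_KJ_PER_L + BROCKWAY_CO2_KJ_PER_L * cal.rer) * 1000.0 / 60.0
    breaths = []
    t = 2.0
    while t < duration:
        vo2 = standing_w / w_per_lmin * (1.0 + rng.normal(0.0, profile.noise_scales.breath_rel))
        breaths.append(BreathSample(t=t, vo2=max(vo2, 0.0), vco2=cal.rer * vo2))
        t += float(rng.uniform(2.0, 5.0))
    return breaths
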