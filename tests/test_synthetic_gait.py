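import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gaitclamp.gait_processing import detect_gait_events, process_trial
from gaitclamp.selfpace_controller import ControllerState
from gaitclamp.synthetic_gait import (
    GRAVITY,
    CalibrationParams,
    CohortConfig,
    generate_breath_series,
    generate_stance_waveforms,
    make_cohort,
    residual_sd_for_r2,
    simulate_fixed_speed_trial,
    simulate_selfpaced_trial,
)


class TestResidualDecomposition:
    def test_inverts_r2(self):
        sd = residual_sd_for_r2(2.0, 0.8)
        assert 2.0 / (2.0 + sd**2) == pytest.approx(0.8, rel=1e-12)

    def test_zero_signal_zero_residual(self):
        assert residual_sd_for_r2(0.0, 0.5) == 0.0

    def test_bad_r2_rejected(self):
        with pytest.raises(ValueError):
            residual_sd_for_r2(1.0, 0.0)


class TestMakeCohort:
    def test_population_means_recovered(self):
        cfg = CohortConfig(n_participants=20, seed=1)
        profiles = make_cohort(cfg)
        assert len(profiles) == 20
        speeds = [p.preferred_speed for p in profiles]
        fps = [p.habitual_fp_frac for p in profiles]
        assert np.mean(speeds) == pytest.approx(1.41, abs=0.06)
        assert np.mean(fps) == pytest.approx(0.220, abs=0.016)

    def test_zero_variance_profiles_identical(self):
        cfg = CohortConfig(n_participants=2, seed=9,
                           calibration=CalibrationParams().zeroed())
        a, b = make_cohort(cfg)
        assert a.preferred_speed == b.preferred_speed == 1.41
        assert a.habitual_fp_frac == b.habitual_fp_frac == 0.220
        assert a.mass == b.mass == 75.6
        assert dataclasses.asdict(a) == {**dataclasses.asdict(b), "id": a.id,
                                         "index": a.index}

    def test_seed_reproducibility(self):
        cfg = CohortConfig(n_participants=5, seed=11)
        assert make_cohort(cfg) == make_cohort(cfg)

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError, match="n_participants"):
            CohortConfig(n_participants=1)

    def test_norm_required(self):
        with pytest.raises(ValueError, match="Norm"):
            CohortConfig(intensities=(-0.2, 0.2))


class TestStanceWaveforms:
    def test_propulsive_peak_exact_and_in_second_half(self, profile):
        vert, ap = generate_stance_waveforms(profile, 1.4, 160.0, 0.7, 100.0)
        assert ap.max() == pytest.approx(160.0, rel=1e-12)
        assert np.argmax(ap) > ap.size / 2

    def test_braking_minimum_in_first_half(self, profile):
        _, ap = generate_stance_waveforms(profile, 1.4, 160.0, 0.7, 100.0)
        assert np.argmin(ap) < ap.size / 2
        assert ap.min() < 0

    def test_vertical_double_humped_above_threshold(self, profile):
        vert, _ = generate_stance_waveforms(profile, 1.4, 160.0, 0.7, 100.0)
        assert vert[0] == pytest.approx(0.0, abs=1e-9)
        assert vert[-1] == pytest.approx(0.0, abs=1e-9)
        assert vert.min() >= 0
        inner = vert[int(0.1 * vert.size):int(0.9 * vert.size)]
        assert inner.min() > 20.0
        mid = vert[int(0.45 * vert.size):int(0.55 * vert.size)].max()
        assert mid < vert.max()  # valley between the two humps

    def test_impulse_balance_within_two_percent(self, profile):
        for stance, rate in [(0.7, 100.0), (0.62, 100.0), (0.7, 1000.0)]:
            _, ap = generate_stance_waveforms(profile, 1.4, 170.0, stance, rate)
            prop = np.trapezoid(np.clip(ap, 0, None))
            brake = -np.trapezoid(np.clip(ap, None, 0))
            assert abs(prop - brake) <= 0.02 * prop

    def test_too_short_stance_rejected(self, profile):
        with pytest.raises(ValueError, match="4 samples"):
            generate_stance_waveforms(profile, 1.4, 160.0, 0.02, 100.0)

    @settings(max_examples=30, deadline=None)
    @given(fp=st.floats(60.0, 320.0), stance=st.floats(0.45, 0.95))
    def test_force_plausibility(self, profile, fp, stance):
        vert, ap = generate_stance_waveforms(profile, 1.4, fp, stance, 100.0)
        bw = profile.mass * GRAVITY
        assert 0.8 * bw <= vert.max() <= 1.5 * bw
        assert ap.max() == pytest.approx(fp, rel=1e-9)


class TestFixedSpeedTrial:
    def test_norm_belt_speed_exact(self, small_config, profile):
        raw = simulate_fixed_speed_trial(profile, 0.0, small_config)
        assert np.all(raw.belt_speed == profile.preferred_speed)

    def test_zero_noise_step_peaks_identical_and_monotone(self):
        cfg = CohortConfig(n_participants=2, trial_duration=180.0, seed=2,
                           calibration=CalibrationParams().zeroed())
        p = make_cohort(cfg)[0]
        peaks = {}
        for inten in (0.0, 0.2):
            raw = simulate_fixed_speed_trial(p, inten, cfg)
            events = detect_gait_events(raw.time, raw.grf_vertical_l)
            vals = [raw.grf_ap_l[(raw.time >= hs) & (raw.time <= to)].max()
                    for hs, to in events]
            assert np.ptp(vals) < 1e-9  # all steps identical
            peaks[inten] = vals[0]
        assert peaks[0.2] > peaks[0.0]

    def test_unknown_intensity_rejected(self, small_config, profile):
        with pytest.raises(ValueError, match="intensity"):
            simulate_fixed_speed_trial(profile, 0.33, small_config)

    def test_trial_invariants(self, small_config, profile):
        raw = simulate_fixed_speed_trial(profile, -0.2, small_config)
        assert np.all(raw.grf_vertical_l >= 0)
        assert np.all(raw.grf_vertical_r >= 0)
        assert np.all(raw.belt_speed >= 0)
        assert raw.time.shape == raw.grf_ap_l.shape == raw.cop_ap.shape

    def test_determinism_byte_identical(self, small_config, profile):
        a = simulate_fixed_speed_trial(profile, 0.1, small_config)
        b = simulate_fixed_speed_trial(profile, 0.1, small_config)
        for name in ("time", "grf_vertical_l", "grf_ap_r", "heel_ap_l", "belt_speed"):
            assert getattr(a, name).tobytes() == getattr(b, name).tobytes()
        assert [x.vo2 for x in a.breaths] == [x.vo2 for x in b.breaths]

    def test_measured_force_plausibility(self, small_config):
        for p in make_cohort(small_config):
            raw = simulate_fixed_speed_trial(p, 0.2, small_config)
            bw = p.mass * GRAVITY
            for vgrf in (raw.grf_vertical_l, raw.grf_vertical_r):
                for hs, to in detect_gait_events(raw.time, vgrf):
                    m = (raw.time >= hs) & (raw.time <= to)
                    assert 0.8 * bw < vgrf[m].max() < 1.5 * bw
            for ap in (raw.grf_ap_l, raw.grf_ap_r):
                assert 0.05 * bw < ap.max() < 0.45 * bw


class TestSelfPacedTrial:
    def _controller(self, p):
        return ControllerState(belt_speed=p.preferred_speed)

    def test_zero_noise_converges_into_dead_zone_band(self):
        cfg = CohortConfig(n_participants=2, trial_duration=300.0, seed=4,
                           calibration=CalibrationParams().zeroed())
        p = make_cohort(cfg)[0]
        cal = cfg.calibration
        target = p.habitual_fp_frac * p.mass * GRAVITY
        raw = simulate_selfpaced_trial(p, target, self._controller(p), cfg)
        band = ControllerState(belt_speed=1.0).dead_zone_halfwidth / cal.cop_gain
        intent = raw.meta["v_intent_base"]
        tail = raw.belt_speed[raw.time >= 200.0]
        assert np.ptp(tail) == pytest.approx(0.0, abs=1e-12)  # frozen in band
        assert abs(tail[0] - intent) <= band + 1e-6
        # equilibrium band sits around preferred speed for the Norm target
        assert abs(tail[0] - p.preferred_speed) < 0.12

    def test_monotone_approach_to_faster_intent(self):
        cfg = CohortConfig(n_participants=2, trial_duration=180.0, seed=4,
                           calibration=CalibrationParams().zeroed())
        p = make_cohort(cfg)[0]
        target = 1.3 * p.habitual_fp_frac * p.mass * GRAVITY  # persistently faster
        raw = simulate_selfpaced_trial(p, target, self._controller(p), cfg)
        diffs = np.diff(raw.belt_speed)
        assert raw.belt_speed[-1] > p.preferred_speed
        assert np.all(diffs >= 0)  # strictly non-decreasing approach

    def test_speed_bound_hit_logged_and_clipped(self, small_config):
        p = make_cohort(small_config)[0]
        controller = ControllerState(belt_speed=p.preferred_speed, speed_max=1.5)
        target = 2.0 * p.habitual_fp_frac * p.mass * GRAVITY
        raw = simulate_selfpaced_trial(p, target, controller, small_config)
        assert raw.belt_speed.max() <= 1.5
        assert any(e[0] == "speed_bound" for e in raw.meta["events"])

    def test_bad_target_rejected(self, small_config, profile):
        with pytest.raises(ValueError):
            simulate_selfpaced_trial(profile, -5.0, self._controller(profile),
                                     small_config)

    def test_group_relative_speed_stabilizes_after_transient(self, small_config):
        """Group-averaged relative speed varies early, settles after ~60 s."""
        traces = []
        for p in make_cohort(small_config):
            target = 1.15 * p.habitual_fp_frac * p.mass * GRAVITY
            raw = simulate_selfpaced_trial(p, target, self._controller(p), small_config)
            traces.append(raw.belt_speed / p.preferred_speed)
        group = np.mean(traces, axis=0)
        t = np.arange(group.size) / small_config.analog_rate
        final = group[t >= 120.0].mean()
        dev_transient = np.abs(group[t < 15.0] - final).mean()
        dev_late = np.abs(group[t >= 60.0] - final).mean()
        assert dev_late < dev_transient / 3  # settled well before 60 s
        assert np.abs(group[t >= 60.0] - final).max() < 0.1  # no divergence

    def test_biofeedback_on_target_when_tracking_clean(self):
        cfg = CohortConfig(n_participants=2, trial_duration=180.0, seed=6,
                           calibration=CalibrationParams().zeroed())
        p = make_cohort(cfg)[0]
        target = p.habitual_fp_frac * p.mass * GRAVITY
        raw = simulate_selfpaced_trial(p, target, self._controller(p), cfg)
        trace = raw.meta["controller_trace"]
        # 1.6% overshoot is inside the 5% tolerance: nearly every step on target
        assert raw.meta["on_target_steps"] > 0.9 * len(trace)


class TestBreathSeries:
    def test_zero_noise_round_trip(self):
        from gaitclamp.metabolics import process_breaths

        cfg = CohortConfig(n_participants=2, seed=8,
                           calibration=CalibrationParams().zeroed())
        p = make_cohort(cfg)[0]
        rng = np.random.default_rng(0)
        breaths = generate_breath_series(p, p.preferred_speed, p.habitual_fp_frac,
                                         "speed", 300.0, rng, cfg.calibration)
        res = process_breaths(breaths, p.mass, p.standing_power * p.mass,
                              mean_speed=p.preferred_speed, trial_end=300.0)
        expected = p.econ_coeffs.cot_norm * p.preferred_speed
        assert res.net_power_per_kg == pytest.approx(expected, rel=5e-3)

    def test_fp_clamp_power_multiplier(self):
        cfg = CohortConfig(n_participants=2, seed=8,
                           calibration=CalibrationParams().zeroed())
        cal = cfg.calibration
        p = make_cohort(cfg)[0]
        out = {}
        for clamp in ("speed", "fp"):
            rng = np.random.default_rng(1)
            breaths = generate_breath_series(p, p.preferred_speed, p.habitual_fp_frac,
                                             clamp, 300.0, rng, cal)
            from gaitclamp.metabolics import process_breaths

            out[clamp] = process_breaths(breaths, p.mass, p.standing_power * p.mass,
                                         trial_end=300.0).net_power_per_kg
        assert out["fp"] / out["speed"] == pytest.approx(cal.clamp_power_mult, rel=1e-3)

    def test_onset_transient_rises_toward_steady_state(self, profile, calib, rng):
        breaths = generate_breath_series(profile, 1.4, 0.22, "speed", 300.0, rng, calib)
        t = np.array([b.t for b in breaths])
        vo2 = np.array([b.vo2 for b in breaths])
        assert vo2[t < 60].mean() < vo2[t >= 180].mean()

    def test_irregular_breath_intervals(self, profile, calib, rng):
        breaths = generate_breath_series(profile, 1.4, 0.22, "speed", 300.0, rng, calib)
        dts = np.diff([b.t for b in breaths])
        assert np.all(dts >= 2.0) and np.all(dts <= 5.0)
        assert np.std(dts) > 0
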