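"""Paste detection, PID behavior, plant physics, closed loop, scan scenario."""

import numpy as np
import pytest

from nanosolder.control import (
    ControllerConfig,
    ControlState,
    ControlTrace,
    PasteLayout,
    PlantModel,
    control_step,
    detect_paste,
    plant_advance,
    plant_emitted_spectrum,
    reference_plant,
    run_closed_loop,
    scan_scenario,
    step_response_metrics,
)
from nanosolder.errors import ParameterError
from nanosolder.spectra import EmissionSpectrum


def flat(level, lo=780.0, hi=960.0):
    wl = np.arange(lo, hi + 0.25, 0.5)
    return EmissionSpectrum(wl, np.full(wl.size, float(level)))


class TestDetectPaste:
    def test_below_threshold_counts(self):
        assert detect_paste(flat(130.0), flat(30.0), threshold_counts=150.0) is False

    def test_above_threshold_counts(self):
        assert detect_paste(flat(230.0), flat(30.0), threshold_counts=150.0) is True

    def test_spectrum_equal_to_background_never_detects(self):
        assert detect_paste(flat(500.0), flat(500.0), threshold_counts=1.0) is False

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            detect_paste(flat(200.0), flat(30.0, lo=700.0, hi=960.0))


class TestControlStep:
    def _state(self):
        return ControlState(background=flat(30.0))

    def test_off_paste_commands_minimum_power(self):
        cfg = ControllerConfig(setpoint_c=60.0)
        power, state = control_step(flat(100.0), cfg, self._state())
        assert power == cfg.min_power == 0.20
        assert state.on_paste is False

    def test_at_setpoint_with_zero_state_clamps_to_floor(self, wide_db):
        from nanosolder.control import plant_emitted_spectrum

        plant = reference_plant()
        plant.temperature_c = 60.0
        cfg = ControllerConfig(setpoint_c=60.0, kp=0.1, ki=0.0, kd=0.0)
        spec = plant_emitted_spectrum(plant, 0.5)
        power, _ = control_step(spec, cfg, ControlState(background=plant.background_spectrum()))
        assert power == cfg.min_power

    def test_large_error_clamps_to_ceiling(self):
        plant = reference_plant()
        plant.temperature_c = 30.0
        cfg = ControllerConfig(setpoint_c=60.0, kp=0.1, ki=0.0, kd=0.0)
        spec = plant_emitted_spectrum(plant, 0.5)
        power, _ = control_step(spec, cfg, ControlState(background=plant.background_spectrum()))
        assert power == cfg.max_power  # error 30 degC * 0.1 = 3.0, clamped

    def test_integrator_frozen_off_paste(self):
        cfg = ControllerConfig(setpoint_c=60.0, ki=0.5)
        state = self._state()
        state.integral = 0.37
        _, state = control_step(flat(50.0), cfg, state)
        assert state.integral == 0.37

    def test_acquisition_time_bounds(self):
        with pytest.raises(ParameterError):
            ControllerConfig(acquisition_time_ms=100.0)


class TestPlant:
    def test_free_decay_matches_exponential(self):
        plant = reference_plant()
        plant.temperature_c = 80.0
        for _ in range(10):
            plant_advance(plant, 0.0, 0.5)
        expected = 25.0 + (80.0 - 25.0) * np.exp(-5.0 / 3.0)
        assert plant.temperature_c == pytest.approx(expected, rel=1e-12)

    def test_constant_power_steady_state(self):
        plant = reference_plant()
        for _ in range(200):
            plant_advance(plant, 0.5, 0.5)
        assert plant.temperature_c == pytest.approx(25.0 + 80.0 * 0.5, abs=1e-6)

    def test_distance_reduces_gain_inverse_square(self):
        assert reference_plant(distance_mm=20.0).gain_c() == pytest.approx(80.0 / 4.0)

    def test_no_paste_emits_background_only(self):
        plant = reference_plant()
        plant.paste_present = False
        spec = plant_emitted_spectrum(plant, 1.0)
        np.testing.assert_array_equal(spec.intensities, plant.background_spectrum().intensities)


class TestClosedLoop:
    def test_setpoint_reached_and_held(self):
        cfg = ControllerConfig(setpoint_c=63.0)
        trace = run_closed_loop(reference_plant(), cfg, 120.0, np.random.default_rng(1))
        m = step_response_metrics(trace, 63.0, ambient_c=25.0)
        assert m.reached_setpoint
        final_third = trace.t_s >= 80.0
        assert np.nanmax(np.abs(trace.temp_c[final_third] - 63.0)) <= 2.0

    def test_zero_gains_stay_at_minimum_power(self):
        cfg = ControllerConfig(kp=0.0, ki=0.0, kd=0.0, setpoint_c=63.0)
        trace = run_closed_loop(reference_plant(), cfg, 60.0, np.random.default_rng(2))
        assert np.all(trace.power_frac == cfg.min_power)

    def test_larger_distance_slows_response(self):
        # setpoint low enough to be reachable at both distances
        cfg = ControllerConfig(setpoint_c=50.0)
        t_near = run_closed_loop(reference_plant(distance_mm=10.0), cfg, 120.0, np.random.default_rng(3))
        t_far = run_closed_loop(reference_plant(distance_mm=15.0), cfg, 120.0, np.random.default_rng(3))
        m_near = step_response_metrics(t_near, 50.0, ambient_c=25.0)
        m_far = step_response_metrics(t_far, 50.0, ambient_c=25.0)
        assert m_far.rise_time_s > m_near.rise_time_s
        assert abs(m_far.steady_state_error_c) < 1.0

    def test_power_always_within_bounds(self):
        for seed, sp in [(1, 60.0), (2, 70.0), (3, 80.0)]:
            cfg = ControllerConfig(setpoint_c=sp)
            trace = run_closed_loop(reference_plant(), cfg, 60.0, np.random.default_rng(seed))
            assert np.all(trace.power_frac >= cfg.min_power - 1e-12)
            assert np.all(trace.power_frac <= cfg.max_power + 1e-12)

    def test_shipped_gains_meet_tuning_requirements(self):
        for sp in (60.0, 70.0, 80.0):
            cfg = ControllerConfig(setpoint_c=sp)
            trace = run_closed_loop(reference_plant(), cfg, 120.0, np.random.default_rng(4))
            m = step_response_metrics(trace, sp, ambient_c=25.0)
            assert m.rise_time_s <= 10.0
            assert m.overshoot_c <= 5.0
            assert m.t90_s <= 20.0

    def test_too_short_duration_rejected(self):
        with pytest.raises(ParameterError):
            run_closed_loop(reference_plant(), ControllerConfig(), 1.0, np.random.default_rng(0))


class TestStepResponseMetrics:
    def _trace(self, temps, dt=0.5):
        n = len(temps)
        return ControlTrace(
            t_s=dt * np.arange(1, n + 1),
            temp_c=np.asarray(temps, dtype=float),
            power_frac=np.full(n, 0.5),
            peak_counts=np.full(n, 1e4),
            on_paste=np.ones(n, dtype=bool),
        )

    def test_never_exceeding_setpoint_means_zero_overshoot(self):
        tr = self._trace(np.linspace(25.0, 59.0, 100))
        m = step_response_metrics(tr, 60.0, ambient_c=25.0)
        assert m.overshoot_c == 0.0
        assert not m.reached_setpoint

    def test_t90_matches_first_order_closed_form(self):
        # uncontrolled plant step response: T = amb + K u (1 - e^(-t/tau))
        tau, amb, ku = 3.0, 25.0, 40.0
        t = 0.5 * np.arange(1, 241)
        temps = amb + ku * (1.0 - np.exp(-t / tau))
        setpoint = amb + ku  # asymptote
        tr = self._trace(temps)
        m = step_response_metrics(tr, setpoint, ambient_c=amb)
        t90_analytic = -tau * np.log(0.1)
        assert m.t90_s == pytest.approx(t90_analytic, abs=0.5)  # sampling resolution

    def test_overshoot_definition(self):
        tr = self._trace([25.0, 50.0, 66.0, 61.0, 60.0])
        m = step_response_metrics(tr, 60.0)
        assert m.overshoot_c == pytest.approx(6.0)


SCAN_LAYOUT = PasteLayout(segments=((0.0, 5.0), (7.0, 12.0)), path_length_mm=12.0)


@pytest.fixture(scope="module")
def scan_trace():
    cfg = ControllerConfig(setpoint_c=60.0, min_power=0.15)
    return scan_scenario(SCAN_LAYOUT, 2.0, cfg, rng=np.random.default_rng(1))


class TestScanScenario:
    LAYOUT = SCAN_LAYOUT

    def test_gap_power_is_safe_level(self, scan_trace):
        gap = (scan_trace.position_mm > 5.05) & (scan_trace.position_mm < 6.95)
        assert gap.any()
        assert np.all(scan_trace.power_frac[gap] == 0.15)

    def test_on_paste_steady_band(self, scan_trace):
        for lo, hi in ((1.0, 4.9), (8.0, 11.9)):
            seg = (scan_trace.position_mm > lo) & (scan_trace.position_mm < hi)
            assert np.nanmax(np.abs(scan_trace.temp_c[seg] - 60.0)) <= 2.0

    def test_power_bounds_hold_everywhere(self, scan_trace):
        assert np.all(scan_trace.power_frac >= 0.15 - 1e-12)
        assert np.all(scan_trace.power_frac <= 1.0 + 1e-12)

    def test_single_full_paste_layout_reduces_to_plain_loop(self):
        layout = PasteLayout(segments=((0.0, 4.0),), path_length_mm=4.0)
        cfg = ControllerConfig(setpoint_c=60.0)
        tr = scan_scenario(layout, 2.0, cfg, rng=np.random.default_rng(2))
        assert tr.on_paste.all()
        m = step_response_metrics(tr, 60.0, ambient_c=25.0)
        assert m.reached_setpoint and m.overshoot_c <= 5.0

    def test_anti_windup_on_reentry(self):
        # overshoot after a long gap must not exceed the plain-loop overshoot
        # by more than 1 degC (the integrator was frozen during the gap)
        cfg = ControllerConfig(setpoint_c=60.0, min_power=0.15)
        plain = run_closed_loop(reference_plant(), ControllerConfig(setpoint_c=60.0), 120.0,
                                np.random.default_rng(3))
        plain_ov = step_response_metrics(plain, 60.0, ambient_c=25.0).overshoot_c
        tr = scan_scenario(self.LAYOUT, 2.0, cfg, rng=np.random.default_rng(3))
        seg2 = tr.position_mm >= 7.0
        reentry_ov = max(0.0, np.nanmax(tr.temp_c[seg2]) - 60.0)
        assert reentry_ov <= plain_ov + 1.0

    def test_overlapping_segments_rejected(self):
        with pytest.raises(ParameterError):
            PasteLayout(segments=((0.0, 5.0), (4.0, 8.0)), path_length_mm=10.0)

    def test_csv_round_trip(self, scan_trace, tmp_path):
        path = tmp_path / "trace.csv"
        scan_trace.to_csv(path)
        loaded = ControlTrace.from_csv(path)
        np.testing.assert_allclose(loaded.power_frac, scan_trace.power_frac, rtol=1e-5)
        np.testing.assert_array_equal(loaded.on_paste, scan_trace.on_paste)
        assert loaded.position_mm is not None
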