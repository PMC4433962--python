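"""Signal conversion, filtering, double integration and event detection."""

import numpy as np
import pytest
from scipy import stats

from fhposture.kinematics import (
    DisplacementTrace,
    SignalTrace,
    acceleration_from_voltage,
    detect_stationary,
    double_integrate,
    log_linearity_check,
    lowpass_denoise,
    movement_direction,
    net_displacement,
    remove_gravity_and_drift,
)
from fhposture.simulator import (
    SimulationConfig,
    make_one_way_script,
    make_return_trip_script,
    simulate_motion,
    synthesize_voltages,
)
from fhposture.pipeline import run_pipeline


def trace_of(values, rate=100.0, units="m/s^2"):
    return SignalTrace(values=np.asarray(values, float), rate=rate, units=units)


class TestTraceTypes:
    def test_trace_validation(self):
        with pytest.raises(ValueError):
            SignalTrace(values=np.zeros(10), rate=0.0)
        with pytest.raises(ValueError):
            SignalTrace(values=np.array([1.0]), rate=100.0)

    def test_displacement_net_vs_peak_invariant(self, rng):
        for _ in range(20):
            vals = np.cumsum(rng.normal(size=50))
            d = DisplacementTrace(trace=trace_of(vals, units="cm"))
            assert d.net == pytest.approx(vals[-1] - vals[0])
            assert abs(d.net) <= d.peak_excursion + 1e-12


class TestAccelerationFromVoltage:
    def test_offset_maps_to_zero(self, x_cal):
        offset = x_cal.voltages[6]  # 0-degree node
        tr = trace_of(np.full(100, offset), units="mV")
        out = acceleration_from_voltage(tr, x_cal, sensitivity=67.0)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)
        assert out.units == "m/s^2"

    def test_affine_conversion(self, x_cal):
        offset = x_cal.voltages[6]
        tr = trace_of(np.full(100, offset + 67.0 * 2.0), units="mV")
        out = acceleration_from_voltage(tr, x_cal, sensitivity=67.0)
        np.testing.assert_allclose(out.values, 2.0)

    def test_non_positive_sensitivity_rejected(self, x_cal):
        tr = trace_of(np.full(10, 1590.0), units="mV")
        with pytest.raises(ValueError, match="sensitivity"):
            acceleration_from_voltage(tr, x_cal, sensitivity=0.0)

    def test_recovers_simulated_acceleration_within_noise(self, table):
        cfg = SimulationConfig(seed=7, noise_mv=2.0)
        truth = simulate_motion(make_one_way_script(3.0), cfg)
        traces = synthesize_voltages(truth, cfg, table)
        from fhposture.calibration import fit_channel_calibration
        from fhposture.simulator import sensitivity_from_calibration

        sens = sensitivity_from_calibration(table)
        out = acceleration_from_voltage(
            traces["vx"], fit_channel_calibration(table, "x"), sens
        )
        resid = out.values - truth.acceleration
        assert np.std(resid) == pytest.approx(2.0 / sens, rel=0.25)


class TestGravityFilter:
    def test_constant_input_rejected_to_numerical_zero(self):
        tr = trace_of(np.full(2000, 9.81))
        out = remove_gravity_and_drift(tr, cutoff=0.2)
        assert np.max(np.abs(out.values[500:-500])) < 1e-6

    def test_passband_sinusoid_amplitude_preserved(self):
        t = np.arange(0, 60, 0.01)
        tr = trace_of(np.sin(2 * np.pi * 1.0 * t))
        out = remove_gravity_and_drift(tr, cutoff=0.2)
        mid = slice(2000, -2000)  # skip filter edge transients
        amp = np.sqrt(2.0) * np.std(out.values[mid])
        assert amp == pytest.approx(1.0, rel=0.05)

    def test_linearity_dc_plus_sinusoid(self):
        t = np.arange(0, 30, 0.01)
        sine = np.sin(2 * np.pi * 1.0 * t)
        out_s = remove_gravity_and_drift(trace_of(sine), cutoff=0.2)
        out_sd = remove_gravity_and_drift(trace_of(sine + 9.81), cutoff=0.2)
        np.testing.assert_allclose(out_sd.values, out_s.values, atol=1e-6)

    def test_cutoff_at_nyquist_rejected(self):
        tr = trace_of(np.zeros(100))
        with pytest.raises(ValueError, match="Nyquist"):
            remove_gravity_and_drift(tr, cutoff=50.0)
        with pytest.raises(ValueError, match="Nyquist"):
            lowpass_denoise(tr, cutoff=60.0)


class TestDoubleIntegration:
    def test_zero_acceleration_gives_zero_displacement(self):
        d = double_integrate(trace_of(np.zeros(500)), detrend="none")
        np.testing.assert_array_equal(d.trace.values, 0.0)
        assert net_displacement(d) == 0.0

    def test_constant_acceleration_half_a_t_squared(self):
        a, T, rate = 0.5, 2.0, 100.0
        n = int(T * rate) + 1
        d = double_integrate(trace_of(np.full(n, a), rate=rate), detrend="none")
        expected_cm = 0.5 * a * T**2 * 100.0
        assert d.net == pytest.approx(expected_cm, rel=1e-4)

    @pytest.mark.parametrize("rate", [50.0, 100.0, 200.0])
    def test_sinusoid_closed_form(self, rate):
        # a(t) = -A w^2 sin(wt) doubly integrates to A sin(wt)
        A, w, T = 0.02, 2 * np.pi * 1.0, 3.0
        t = np.arange(0, T, 1 / rate)
        acc = -A * w**2 * np.sin(w * t)
        d = double_integrate(trace_of(acc, rate=rate), detrend="none")
        # integration constants: v(0) = 0 adds the linear term -A*w*t
        expected = (A * np.sin(w * t) - A * w * t) * 100.0
        err = np.max(np.abs(d.trace.values - expected))
        # trapezoid error ~ (w/rate)^2 per period times the signal scale
        assert err < 5.0 * A * (w / rate) ** 2 * w * T * 100.0

    def test_sinusoid_error_shrinks_with_rate(self):
        A, w = 0.02, 2 * np.pi * 1.0
        errs = []
        for rate in (50.0, 100.0, 200.0):
            t = np.arange(0, 3.0, 1 / rate)
            acc = -A * w**2 * np.sin(w * t)
            d = double_integrate(trace_of(acc, rate=rate), detrend="none")
            expected = (A * np.sin(w * t) - A * w * t) * 100.0
            errs.append(np.max(np.abs(d.trace.values - expected)))
        assert errs[0] > errs[1] > errs[2]

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError):
            SignalTrace(values=np.array([0.0]), rate=100.0)

    def test_linear_detrend_nulls_one_way_net(self, table):
        # documented behaviour: per-stage linear detrending suppresses drift
        # for return-to-start motion but also nulls genuine one-way nets
        cfg = SimulationConfig(seed=0, noise_mv=0.0)
        truth = simulate_motion(make_one_way_script(3.0), cfg)
        tr = trace_of(truth.acceleration)
        assert abs(double_integrate(tr, detrend="linear").net) < 2.0
        assert double_integrate(tr, detrend="zupt").net == pytest.approx(3.0, rel=0.02)

    def test_unknown_detrend_mode_rejected(self):
        with pytest.raises(ValueError, match="detrend"):
            double_integrate(trace_of(np.zeros(100)), detrend="quadratic")


class TestStationaryDetection:
    def test_rest_and_motion_separated(self):
        cfg = SimulationConfig(seed=3, noise_mv=2.0)
        truth = simulate_motion(make_one_way_script(3.0), cfg)
        rng = np.random.default_rng(3)
        noisy = truth.acceleration + rng.normal(0, 2.0 / 67.0, truth.times.size)
        mask = detect_stationary(trace_of(noisy))
        moving_true = np.abs(truth.velocity) > 1e-6
        # every strongly moving sample flagged as non-stationary
        strong = np.abs(truth.velocity) > 0.5 * np.max(np.abs(truth.velocity))
        assert not mask[strong].any()
        # most genuinely resting samples kept
        assert mask[~moving_true].mean() > 0.5


class TestNetDisplacement:
    def test_return_trip_through_full_chain_returns_to_zero(self, table):
        cfg = SimulationConfig(seed=11, noise_mv=2.0)
        truth = simulate_motion(make_return_trip_script(3.0), cfg)
        traces = synthesize_voltages(truth, cfg, table)
        _, report = run_pipeline(traces, table)
        assert abs(report["net_displacement_cm"]) < 0.3

    def test_one_way_3cm_recovered_within_10_percent(self, table):
        cfg = SimulationConfig(seed=5, noise_mv=2.0)
        truth = simulate_motion(make_one_way_script(3.0), cfg)
        traces = synthesize_voltages(truth, cfg, table)
        _, report = run_pipeline(traces, table)
        assert report["net_displacement_cm"] == pytest.approx(3.0, rel=0.10)

    def test_static_script_gives_zero(self, table):
        cfg = SimulationConfig(seed=2, noise_mv=0.0)
        from fhposture.simulator import MotionScript, Segment

        truth = simulate_motion(MotionScript(segments=(Segment(duration=2.0),)), cfg)
        d = double_integrate(trace_of(truth.acceleration))
        assert net_displacement(d) == pytest.approx(0.0, abs=1e-9)


class TestMovementDirection:
    @staticmethod
    def biphasic(sign=1.0):
        t = np.arange(0, 2.0, 0.01)
        pulse = np.zeros_like(t)
        in1 = (t >= 0.5) & (t < 0.8)
        in2 = (t >= 0.8) & (t < 1.1)
        pulse[in1] = sign
        pulse[in2] = -sign
        return trace_of(pulse)

    def test_positive_first_pulse_is_one_forward_event(self):
        events = movement_direction(self.biphasic(+1.0), threshold=0.5)
        assert len(events) == 1
        assert events[0].direction == "forward"
        assert events[0].leading_edge == "rising"
        assert events[0].onset_time == pytest.approx(0.5, abs=0.02)

    def test_negative_first_pulse_is_one_backward_event(self):
        events = movement_direction(self.biphasic(-1.0), threshold=0.5)
        assert len(events) == 1
        assert events[0].direction == "backward"
        assert events[0].leading_edge == "falling"

    def test_subthreshold_noise_gives_no_events(self, rng):
        tr = trace_of(rng.normal(0, 0.01, 500))
        assert movement_direction(tr, threshold=0.5) == []

    def test_negating_trace_flips_every_direction(self, rng):
        # antisymmetry property over random multi-burst traces
        for seed in range(5):
            g = np.random.default_rng(seed)
            vals = np.zeros(1000)
            for _ in range(3):
                start = g.integers(0, 900)
                vals[start : start + 50] += g.choice([-1.0, 1.0]) * 2.0
            tr = trace_of(vals)
            ev_pos = movement_direction(tr, threshold=0.5)
            ev_neg = movement_direction(trace_of(-vals), threshold=0.5)
            assert len(ev_pos) == len(ev_neg)
            flip = {"forward": "backward", "backward": "forward"}
            for a, b in zip(ev_pos, ev_neg):
                assert b.direction == flip[a.direction]
                assert b.onset_time == a.onset_time

    def test_non_positive_threshold_rejected(self):
        with pytest.raises(ValueError):
            movement_direction(trace_of(np.zeros(100)), threshold=0.0)


class TestLogLinearity:
    def test_square_law_gives_slope_two(self):
        d = np.array([0.5, 1, 1.5, 2.5, 3, 5])
        slope, r = log_linearity_check(d, d**2)
        assert slope == pytest.approx(2.0)
        assert r == pytest.approx(1.0)

    def test_proportional_gives_slope_one(self):
        d = np.array([0.5, 1, 1.5, 2.5, 3, 5])
        slope, r = log_linearity_check(d, 7.3 * d)
        assert slope == pytest.approx(1.0)
        assert r == pytest.approx(1.0)

    def test_pearson_matches_brute_force_oracle(self, rng):
        x = rng.uniform(0.5, 5.0, 20)
        y = x ** 1.7 * np.exp(rng.normal(0, 0.1, 20))
        _, r = log_linearity_check(x, y)
        lx, ly = np.log(x), np.log(y)
        r_oracle = float(
            np.sum((lx - lx.mean()) * (ly - ly.mean()))
            / np.sqrt(np.sum((lx - lx.mean()) ** 2) * np.sum((ly - ly.mean()) ** 2))
        )
        assert r == pytest.approx(r_oracle, rel=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            log_linearity_check([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            log_linearity_check([1.0, -2.0, 3.0], [1.0, 2.0, 3.0])


class TestZeroReturnProperty:
    def test_symmetric_out_and_back_net_small_across_seeds(self, table):
        # |net| <= 10% of peak excursion in the large majority of noisy runs
        ok = 0
        for seed in range(20):
            cfg = SimulationConfig(seed=seed, noise_mv=2.0)
            truth = simulate_motion(make_return_trip_script(3.0), cfg)
            traces = synthesize_voltages(truth, cfg, table)
            _, report = run_pipeline(traces, table)
            if abs(report["net_displacement_cm"]) <= 0.1 * report["peak_excursion_cm"]:
                ok += 1
        assert ok >= 16
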