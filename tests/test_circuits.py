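"""Driver design formulas and the two-stage amplifier model.

Closed-form values are asserted against the device's printed component
choices; the transient model is cross-checked against the closed-form
gain composition it must reproduce in the unclipped passband.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from osteosense import circuits as c


class TestDriverDesign:
    @pytest.mark.parametrize("i_mon_ma,duty,expected_ohm", [
        (0.2, 0.5, 9500.0),     # 940 nm diode
        (0.3, 0.5, 5433.3),     # 1310 nm diode (printed as 5.4 kOhm)
        (0.2, 1.0, 3400.0),     # continuous operation
    ])
    def test_set_resistor(self, i_mon_ma, duty, expected_ohm):
        d = c.DriverDesign(i_monitor=i_mon_ma * 1e-3, duty=duty)
        assert c.rset_for_monitor(d) == pytest.approx(expected_ohm, rel=1e-4)

    def test_infeasible_when_below_fixed_resistor(self):
        d = c.DriverDesign(i_monitor=1e-3, duty=1.0)  # needs 1.22 kOhm total
        with pytest.raises(c.InfeasibleDesignError):
            c.rset_for_monitor(d)

    @pytest.mark.parametrize("f,r,expected", [
        (300e3, 12.2e3, 1.202e-7),
        (55.0, 12.2e3, 6.557e-4),
    ])
    def test_integrator_capacitor_minimum(self, f, r, expected):
        assert c.min_integrator_cap(f, r) == pytest.approx(expected, rel=1e-3)

    @given(f=st.floats(1, 1e6), r=st.floats(100, 1e6))
    @settings(max_examples=50, deadline=None)
    def test_capacitor_inverse_in_frequency(self, f, r):
        assert c.min_integrator_cap(2 * f, r) == pytest.approx(
            c.min_integrator_cap(f, r) / 2)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            c.min_integrator_cap(0.0, 1e3)
        with pytest.raises(ValueError):
            c.DriverDesign(i_monitor=-1e-3)


class TestSmallSignalFormulas:
    def test_bias_corner_is_13_hz(self):
        f = c.corner_frequency(22e3, 27e3, 1e-6)
        assert f == pytest.approx(13.13, rel=1e-3)
        assert round(f) == 13

    def test_equal_resistors_use_half(self):
        assert c.corner_frequency(10e3, 10e3, 1e-6) == pytest.approx(
            1 / (2 * math.pi * 5e3 * 1e-6))

    def test_huge_capacitor_pushes_corner_to_zero(self):
        assert c.corner_frequency(22e3, 27e3, 1.0) < 0.02

    @pytest.mark.parametrize("rf,cf,expected_hz", [
        (5e6, 6.8e-12, 4681.0),
        (600e3, 6.8e-12, 39009.0),
        (470e3, 6.8e-12, 49798.0),   # printed as 50 kHz
    ])
    def test_stage_bandwidth(self, rf, cf, expected_hz):
        assert c.stage_bandwidth(rf, cf) == pytest.approx(expected_hz, rel=1e-3)


class TestSteadyState:
    def test_zero_input_idles_at_bias(self, tia):
        assert c.steady_state_output(0.0, tia) == (tia.v_bias, tia.v_bias)

    def test_bench_validation_point(self):
        p = c.TIAParams(r_f1=440e3, v_bias=2.8)
        _, v2 = c.steady_state_output(337e-9, p)
        assert v2 == pytest.approx(1.32, abs=5e-3)

    def test_saturation_onset_gain(self):
        p = c.TIAParams(r_f1=440e3, v_bias=2.8)
        g_sat = c.saturation_gain(337e-9, p)
        assert g_sat == pytest.approx(831e3, rel=2e-3)
        _, v2 = c.steady_state_output(337e-9, c.TIAParams(r_f1=g_sat * 1.001,
                                                          v_bias=2.8))
        assert v2 == 0.0

    def test_outputs_clip_to_rails(self, tia):
        v1, v2 = c.steady_state_output(1e-3, tia)  # absurdly large current
        assert v1 == tia.v_supply and v2 == 0.0

    def test_square_wave_levels_split_about_bias(self, tia):
        v_high, v_low = c.square_wave_levels(432e-9, 101e-9, tia)
        assert v_low == pytest.approx(3.693, abs=1e-3)
        assert v_high == pytest.approx(1.707, abs=1e-3)
        assert (v_high + v_low) / 2 == pytest.approx(tia.v_bias, abs=1e-9)


class TestTransient:
    @pytest.fixture(scope="class")
    def settled(self, tia):
        return c.transient_response(432e-9, 101e-9, 500.0, tia, duration=4.0)

    def test_steady_state_peak_to_peak(self, settled):
        assert settled.steady_state_peak_to_peak(1) * 1e3 == pytest.approx(
            198.6, abs=0.2)
        assert settled.steady_state_peak_to_peak(2) == pytest.approx(
            1.986, abs=2e-3)

    def test_gain_composition_exact_in_passband(self, tia):
        # peak-to-peak = dI * R_F1 * (R_F2 / R_4) below clipping
        tr = c.transient_response(200e-9, 50e-9, 500.0, tia, duration=4.0)
        assert tr.steady_state_peak_to_peak(2) == pytest.approx(
            150e-9 * tia.g_total, rel=1e-3)

    def test_amplitude_linear_below_clipping(self, tia):
        pp = [c.transient_response(a, 0.0, 500.0, tia, duration=3.0,
                                   power_on=False).steady_state_peak_to_peak(2)
              for a in (50e-9, 100e-9)]
        assert pp[1] == pytest.approx(2 * pp[0], rel=1e-3)

    def test_coupling_time_constant(self, tia):
        assert tia.tau == pytest.approx(0.47)

    def test_power_on_settles_to_bias_in_about_4_tau(self, settled, tia):
        t_settle = settled.settling_time(tol=0.02)
        assert 1.5 < t_settle < 2.5
        assert settled.cycle_mean(2) == pytest.approx(tia.v_bias, abs=0.02)

    def test_dc_input_decays_to_bias(self, tia):
        tr = c.transient_response(300e-9, 300e-9, 500.0, tia, duration=5.0)
        assert tr.cycle_mean(2) == pytest.approx(tia.v_bias, abs=0.01)
        assert tr.cycle_mean(2, at=0.1) < tia.v_bias - 0.5  # still charging

    def test_voltages_confined_to_rails(self, settled, tia):
        for v in (settled.v_stage1, settled.v_stage2):
            assert v.min() >= 0.0 and v.max() <= tia.v_supply

    def test_trace_export_columns(self, settled, tmp_path):
        p = tmp_path / "tr.csv"
        settled.to_csv(p)
        header = p.read_text().splitlines()[0]
        assert header == "t_s,stage1_v,stage2_v"


class TestFrequencyResponse:
    def test_passband_plateau_is_total_gain(self, tia):
        h = c.frequency_response(tia, [50.0, 100.0])
        assert h[1] == pytest.approx(tia.g_total, rel=1e-3)

    def test_dominant_pole_matches_closed_form_within_1pct(self):
        p = c.TIAParams(r_f1=5e6)   # 4.68 kHz pole, second stage 10x higher
        f3 = c.minus_3db_frequency(p)
        assert abs(f3 - p.f_stage1) / p.f_stage1 < 0.01

    def test_comparable_poles_pull_the_corner_down(self, tia):
        # 39 and 50 kHz poles combine below the single-stage figure
        f3 = c.minus_3db_frequency(tia)
        assert f3 < tia.f_stage1
        h3 = c.frequency_response(tia, [f3])[0]
        assert h3 == pytest.approx(tia.g_total / math.sqrt(2), rel=1e-6)

    def test_highpass_blocks_dc_side(self, tia):
        h = c.frequency_response(tia, [0.01])
        assert h[0] < 0.05 * tia.g_total

    def test_rejects_nonpositive_frequency(self, tia):
        with pytest.raises(ValueError):
            c.frequency_response(tia, [0.0, 10.0])
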