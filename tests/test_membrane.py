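"""Point-membrane physics: rate functions, temperature factors, pump and
current bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thermoblock import membrane as mb
from thermoblock.membrane import (GatingState, MembraneParams, Q10_BREAKPOINTS,
                                  gating_rates, phi, q10_rate,
                                  peak_conductances, pump_currents,
                                  membrane_current, gate_derivatives,
                                  steady_state_gates, resting_state)


class TestGatingRates:
    def test_reference_values_at_rest(self):
        a_n, b_n, a_m, b_m, a_h, b_h = gating_rates(-65.0)
        assert a_n == pytest.approx(0.1 / (np.e - 1.0), rel=1e-12)
        assert b_n == pytest.approx(0.125)
        assert a_m == pytest.approx(2.5 / (np.exp(2.5) - 1.0), rel=1e-12)
        assert b_m == pytest.approx(4.0)
        assert a_h == pytest.approx(0.07)
        assert b_h == pytest.approx(1.0 / (np.exp(3.0) + 1.0), rel=1e-12)

    @pytest.mark.parametrize("v, which, limit", [
        (-55.0, 0, 0.1),   # alpha_n singularity -> L'Hopital limit
        (-40.0, 2, 1.0),   # alpha_m singularity
    ])
    def test_removable_singularities(self, v, which, limit):
        assert gating_rates(v)[which] == pytest.approx(limit, rel=1e-9)
        # continuity just off the singular point
        near = gating_rates(v + 1e-7)[which]
        assert near == pytest.approx(limit, rel=1e-5)

    @given(st.floats(-120, 60))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_rates_nonnegative(self, v):
        assert all(r >= 0 for r in gating_rates(v))

    def test_nonfinite_voltage_rejected(self):
        with pytest.raises(ValueError):
            gating_rates(np.nan)


class TestPhi:
    def test_unity_at_base_temperature(self, params, params_original):
        for gate in "mhn":
            assert phi(6.3, gate, params) == pytest.approx(1.0)
            assert phi(6.3, gate, params_original) == pytest.approx(1.0)

    def test_branch_values(self, params):
        assert phi(10.0, "m", params) == pytest.approx(3 ** 0.37, rel=1e-12)
        expected_n25 = 3 ** 0.37 * 2.8 ** 0.5 * 2.4 ** 0.5 * 2.3 ** 0.5
        assert phi(25.0, "n", params) == pytest.approx(expected_n25, rel=1e-12)
        assert phi(25.0, "n", params) == pytest.approx(5.90, rel=1e-3)

    @pytest.mark.parametrize("gate", ["m", "h", "n"])
    @pytest.mark.parametrize("bp", Q10_BREAKPOINTS)
    def test_continuity_at_breakpoints(self, params, gate, bp):
        below = phi(bp - 1e-9, gate, params)
        above = phi(bp + 1e-9, gate, params)
        assert abs(above - below) / below < 1e-6

    def test_original_variant_single_q10(self, params_original):
        for gate in "mhn":
            assert phi(16.3, gate, params_original) == pytest.approx(3.0)
            assert phi(26.3, gate, params_original) == pytest.approx(9.0)

    def test_unknown_gate_rejected(self, params):
        with pytest.raises(ValueError):
            phi(10.0, "z", params)


class TestQ10Rate:
    @pytest.mark.parametrize("r1, q10, t1, t2, expected", [
        (0.1, 3.0, 5.0, 15.0, 0.3),
        (1.0, 1.88, 6.3, 6.3, 1.0),
        (2.0, 2.0, 6.3, 11.3, 2.0 * 2.0 ** 0.5),
    ])
    def test_examples(self, r1, q10, t1, t2, expected):
        assert q10_rate(r1, q10, t1, t2) == pytest.approx(expected, rel=1e-12)

    @given(st.floats(0.01, 100), st.floats(1.01, 4.0),
           st.floats(0, 30), st.floats(0, 30))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_round_trip(self, r1, q10, t1, t2):
        r2 = q10_rate(r1, q10, t1, t2)
        assert q10_rate(r2, q10, t2, t1) == pytest.approx(r1, rel=1e-9)

    def test_nonpositive_q10_rejected(self):
        with pytest.raises(ValueError):
            q10_rate(1.0, 0.0, 5.0, 10.0)


class TestConductancesAndPump:
    def test_gaussian_peak(self, params):
        g_k, _ = peak_conductances(27.88, params)
        assert g_k == pytest.approx(1.60)

    def test_base_temperature_values(self, params):
        g_k, g_na = peak_conductances(6.3, params)
        assert g_k == pytest.approx(0.09534, rel=1e-3)
        assert g_na == pytest.approx(0.21884, rel=1e-3)

    def test_original_fixed(self, params_original):
        for t in (0.0, 6.3, 35.0):
            assert peak_conductances(t, params_original) == (0.036, 0.120)

    def test_pump_example(self, params):
        i_na, i_k = pump_currents(-65.0, 6.3, params)
        assert i_na == pytest.approx(3 * 7e-6 * 155.0, rel=1e-12)
        assert i_k == pytest.approx(-2 * 7e-6 * 155.0, rel=1e-12)

    def test_pump_zero_at_reversal(self, params):
        assert pump_currents(-220.0, 20.0, params) == (0.0, 0.0)

    def test_pump_absent_in_original(self, params_original):
        for v, t in ((-65.0, 6.3), (0.0, 30.0)):
            assert pump_currents(v, t, params_original) == (0.0, 0.0)

    @given(st.floats(-90, 40).filter(lambda v: abs(v + 220) > 1e-6),
           st.floats(5, 40))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_pump_stoichiometry(self, v, t):
        i_na, i_k = pump_currents(v, t, MembraneParams())
        assert i_na / i_k == pytest.approx(-1.5, rel=1e-12)


class TestMembraneCurrent:
    def test_zero_driving_force(self, params):
        g = GatingState(m=0.0, h=0.0, n=1.0)
        cb = membrane_current(params.e_k, g, 6.3, params)
        assert cb.i_k == pytest.approx(0.0)

    def test_potassium_example_original(self, params_original):
        g = GatingState(m=0.0, h=0.0, n=0.5)
        cb = membrane_current(0.0, g, 6.3, params_original)
        assert cb.i_k == pytest.approx(0.036 * 0.5 ** 4 * 74.0, rel=1e-12)
        assert cb.i_k == pytest.approx(0.16650, abs=1e-5)

    def test_total_is_sum(self, params):
        g = steady_state_gates(-60.0)
        cb = membrane_current(-60.0, g, 10.0, params)
        total = cb.i_na + cb.i_k + cb.i_leak + cb.i_na_pump + cb.i_k_pump
        assert cb.i_total == pytest.approx(total, rel=1e-15)

    def test_ablation_scales(self, params):
        g = steady_state_gates(-50.0)
        cb = membrane_current(-50.0, g, 6.3, params, gk_scale=0.0, gna_scale=0.0)
        assert cb.i_k == 0.0 and cb.i_na == 0.0


class TestGateDynamics:
    def test_zero_derivative_at_steady_state(self, params):
        v = -58.0
        g = steady_state_gates(v)
        dm, dh, dn = gate_derivatives(v, g, 13.0, params)
        assert abs(dm) < 1e-12 and abs(dh) < 1e-12 and abs(dn) < 1e-12

    def test_from_zero_gate(self, params):
        g = GatingState(m=0.0, h=0.0, n=0.0)
        _, _, dn = gate_derivatives(-65.0, g, 6.3, params)
        assert dn == pytest.approx(0.1 / (np.e - 1.0), rel=1e-9)

    def test_q10_scaling_original(self, params_original):
        g = GatingState(m=0.0, h=0.0, n=0.0)
        _, _, dn_base = gate_derivatives(-65.0, g, 6.3, params_original)
        _, _, dn_warm = gate_derivatives(-65.0, g, 16.3, params_original)
        assert dn_warm == pytest.approx(3.0 * dn_base, rel=1e-12)

    @pytest.mark.parametrize("x0", [0.0, 0.5, 1.0])
    def test_gates_converge_to_steady_state(self, params, x0):
        # exact exponential update at fixed V converges to x_inf
        v, t, dt = -55.0, 15.0, 0.05
        a_n, b_n, a_m, b_m, a_h, b_h = gating_rates(v)
        x = x0
        ph = phi(t, "n", params)
        for _ in range(3000):
            xinf = a_n / (a_n + b_n)
            x += (xinf - x) * -np.expm1(-dt * ph * (a_n + b_n))
        assert x == pytest.approx(a_n / (a_n + b_n), abs=1e-9)


class TestRestingState:
    def test_original_near_minus_65(self, params_original):
        # the shared reversal-potential table puts the original variant's
        # stable rest about 2 mV above the textbook -65 mV
        v, gates = resting_state(6.3, params_original)
        assert -67.5 < v < -62.0
        g = steady_state_gates(v)
        assert gates.n == pytest.approx(g.n)

    def test_modified_rest_near_minus_65(self, params):
        v, _ = resting_state(6.3, params)
        assert -69.0 < v < -64.0

    def test_rest_is_current_root(self, params):
        v, gates = resting_state(12.0, params)
        cb = membrane_current(v, gates, 12.0, params)
        assert abs(cb.i_total) < 1e-9

    def test_passive_rest_with_both_channels_ablated(self, params):
        # leak + pump only: closed-form weighted-average rest
        v, _ = resting_state(6.3, params, gk_scale=0.0, gna_scale=0.0)
        gl, gp = params.g_leak, 7e-6
        expected = (gl * params.e_leak + gp * params.e_pump) / (gl + gp)
        assert v == pytest.approx(expected, abs=1e-6)
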