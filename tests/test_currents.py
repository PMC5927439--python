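"""Ionic currents, the GHK synaptic pathway, the membrane equation and rest."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from electrocyte import (MembraneState, achr_currents, achr_reversal,
                         conductance_currents, current_breakdown, epm_default,
                         ghk_current, integrate, pulsatile_regime,
                         resting_state, rhs)
from electrocyte.currents import _ghk_flux_factor
from electrocyte.kinetics import equilibrium_gates
from electrocyte.params import FARADAY


@pytest.fixture(scope="module")
def p():
    return epm_default()


class TestConductanceCurrents:
    def test_hand_computed_values(self, p):
        # 700*0.5^3*1*0.98*(-105); 700*0.5^3*0.02*(-105); 2000*0.1^4*44; 5*44
        st_ = MembraneState(v=-50.0, m=0.5, h=1.0, n=0.1)
        i_na_t, i_na_p, i_k, i_leak = conductance_currents(st_, p)
        assert i_na_t == pytest.approx(-9003.75)
        assert i_na_p == pytest.approx(-183.75)
        assert i_k == pytest.approx(8.8)
        assert i_leak == pytest.approx(220.0)

    def test_zero_driving_force_kills_sodium_currents(self, p):
        st_ = MembraneState(v=p.e_na, m=0.5, h=0.5, n=0.5)
        i_na_t, i_na_p, _, _ = conductance_currents(st_, p)
        assert i_na_t == 0.0 and i_na_p == 0.0

    def test_persistent_current_ignores_inactivation(self, p):
        with_h = conductance_currents(MembraneState(-50.0, 0.5, 1.0, 0.1), p)
        no_h = conductance_currents(MembraneState(-50.0, 0.5, 0.0, 0.1), p)
        assert no_h[0] == 0.0               # transient gone
        assert no_h[1] == with_h[1]         # persistent unchanged


class TestGhkCurrent:
    def test_frozen_high_precision_value(self, p):
        """Inward Na+ current at -90 mV against a 30-digit evaluation of the
        constant-field flux expression."""
        assert ghk_current(-90.0, "Na", 1.0, p) == pytest.approx(
            6770.9536274578637, rel=1e-12)

    def test_zero_voltage_limit(self, p):
        # u/(1-e^-u) -> 1, so I -> P*F*(c_out - c_in) per unit level (inward+)
        expect = FARADAY * p.synapse.p_na * (p.concentrations.na_out
                                             - p.concentrations.na_in)
        assert ghk_current(0.0, "Na", 1.0, p) == pytest.approx(expect, rel=1e-9)

    def test_series_and_direct_branches_agree(self):
        for u in np.geomspace(1e-3, 1e-1, 25):
            for sign in (1.0, -1.0):
                x = sign * u
                direct = x / (1.0 - math.exp(-x))
                assert _ghk_flux_factor(x) == pytest.approx(direct, rel=1e-12)

    def test_total_achr_current_reverses_near_plus_2_mv(self, p):
        from scipy.optimize import brentq

        vrev = brentq(lambda v: sum(achr_currents(v, 1.0, p)), -20.0, 20.0,
                      xtol=1e-10)
        assert vrev == pytest.approx(2.2, abs=0.1)
        assert achr_reversal(p) == pytest.approx(vrev, abs=1e-6)
        i_na, i_k = achr_currents(vrev, 1.0, p)
        assert i_na + i_k == pytest.approx(0.0, abs=1e-6)

    def test_scales_linearly_with_level(self, p):
        base = ghk_current(-60.0, "K", 1.0, p)
        assert ghk_current(-60.0, "K", 2.5, p) == pytest.approx(2.5 * base)
        assert ghk_current(-60.0, "K", 0.0, p) == 0.0

    def test_negative_level_rejected(self, p):
        with pytest.raises(ValueError):
            ghk_current(-60.0, "Na", -0.1, p)

    @given(v=st.floats(-120.0, 120.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_single_ion_current_monotone_in_voltage(self, v):
        """Depolarizing-positive single-ion GHK flux strictly decreases with V
        (outward-positive convention: strictly increases)."""
        p = epm_default()
        dv = 0.5
        for ion in ("Na", "K"):
            assert ghk_current(v, ion, 1.0, p) > ghk_current(v + dv, ion, 1.0, p)


class TestMembraneEquation:
    def test_rest_is_a_fixed_point(self, p):
        state = resting_state(p)
        assert np.all(np.abs(rhs(0.0, state, None, p)) < 1e-9)

    def test_rest_sits_just_above_e_k(self, p):
        state = resting_state(p)
        assert p.e_k < state.v < -85.0
        m, h, n = equilibrium_gates(state.v, p)
        assert state.m == pytest.approx(float(m))
        assert state.h == pytest.approx(float(h))
        assert state.n == pytest.approx(float(n))

    def test_depolarizing_drift_at_e_k(self, p):
        """Clamping gates to equilibrium at E_K, the net current drives V up:
        rest sits slightly above E_K."""
        m, h, n = equilibrium_gates(p.e_k, p)
        deriv = rhs(0.0, MembraneState(p.e_k, float(m), float(h), float(n)),
                    None, p)
        assert deriv[0] > 0

    def test_perturbed_rest_relaxes_back(self, p):
        """+1 mV off rest decays back to the same relaxed state (stability)."""
        state = resting_state(p)
        start = MembraneState(state.v + 1.0, state.m, state.h, state.n)
        perturbed = integrate(p, None, 250.0, initial=start)
        reference = integrate(p, None, 250.0, initial=state)
        assert perturbed.v[-1] == pytest.approx(reference.v[-1], abs=1e-6)

    def test_finite_difference_consistency_with_rhs(self, p):
        """Central differences of an integrated trajectory match the analytic
        right-hand side (the kernel and the reference formulas agree)."""
        regime = pulsatile_regime(1.0, 200.0)
        traj = integrate(p, regime, 10.0)
        t, v = traj.t, traj.v
        for i in range(200, 4500, 370):
            state = MembraneState(v[i], traj.m[i], traj.h[i], traj.n[i])
            deriv = rhs(t[i], state, regime, p)
            fd = (v[i + 1] - v[i - 1]) / (t[i + 1] - t[i - 1])
            assert fd == pytest.approx(deriv[0], rel=5e-3, abs=0.5)

    def test_current_bookkeeping_closes(self, p):
        """-C dV/dt equals the signed sum of the current breakdown."""
        from electrocyte import SolverOptions

        regime = pulsatile_regime(1.0, 200.0)
        traj = integrate(p, regime, 8.0,
                         SolverOptions(dt=5e-4, sample_dt=5e-4))
        bd = traj.breakdown()
        dv = np.gradient(traj.v, traj.t)
        net = -(bd["i_na_t"] + bd["i_na_p"] + bd["i_k"] + bd["i_leak"]) \
            + bd["i_achr_na"] + bd["i_achr_k"] + bd["i_clamp"]
        # compare C dV/dt with the current sum away from the sampling edges
        resid = p.capacitance * dv[5:-5] - net[5:-5]
        scale = np.abs(net[5:-5]).max()
        assert np.abs(resid).max() < 5e-3 * scale

    def test_breakdown_object_matches_equation(self, p):
        state = resting_state(p)
        regime = pulsatile_regime(1.0, 200.0)
        bd = current_breakdown(0.1, state, regime, p)
        deriv = rhs(0.1, state, regime, p)
        assert bd.net_capacitive == pytest.approx(
            p.capacitance * deriv[0], rel=1e-12)
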