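"""Membrane state, ionic currents, the membrane equation and its rest point.

Sign conventions
----------------
Conductance currents (I_NaT, I_NaP, I_K, I_L) are positive outward, entering
the membrane equation with minus signs:

    C dV/dt = -I_NaT - I_NaP - I_K - I_L + I_stim

The stimulus current I_stim (synaptic GHK flux and/or injected current) is
positive when depolarizing, i.e. GHK currents returned here are positive for
net inward cation flux.  The bookkeeping identity

    -C dV/dt = (I_NaT + I_NaP + I_K + I_L) - (I_AChR_Na + I_AChR_K + I_clamp)

holds at every instant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .kinetics import equilibrium_gates, gate_rates
from .params import FARADAY, ModelParams

#: Switch to the Taylor series of u/(1 - exp(-u)) below this |u|.
_GHK_SERIES_U = 1e-4
#: mm^3/s -> m^3/s times A -> nA: P[m^3/s] * F * conc[mol/m^3] gives amperes,
#: so the net prefactor applied to p_na (in mm^3/s) is 1e-9 * F * 1e9 = F.
_GHK_NA_PER_MM3S = FARADAY


@dataclass(frozen=True)
class MembraneState:
    """Membrane potential (mV) and the three gating variables."""

    v: float
    m: float
    h: float
    n: float

    def as_array(self) -> np.ndarray:
        return np.array([self.v, self.m, self.h, self.n])


@dataclass(frozen=True)
class CurrentBreakdown:
    """All membrane currents (nA) at one instant.

    Conductance currents are outward-positive; AChR and clamp currents are
    depolarizing-positive (see module docstring).
    """

    i_na_t: float
    i_na_p: float
    i_k: float
    i_leak: float
    i_achr_na: float
    i_achr_k: float
    i_clamp: float

    @property
    def net_capacitive(self) -> float:
        """C dV/dt implied by the currents (nA)."""
        return -(self.i_na_t + self.i_na_p + self.i_k + self.i_leak) \
            + self.i_achr_na + self.i_achr_k + self.i_clamp


def conductance_currents(state: MembraneState, params: ModelParams
                         ) -> Tuple[float, float, float, float]:
    """Transient Na, persistent Na, delayed-rectifier K and leak currents (nA).

    I_NaT = gNa_max m^3 h (1-gamma)(V-E_Na); I_NaP = gNa_max m^3 gamma (V-E_Na);
    I_K = gK_max n^4 (V-E_K); I_L = g_L (V-E_L).  uS x mV = nA.
    """
    v, m, h, n = state.v, state.m, state.h, state.n
    m3 = m ** 3
    i_na_t = params.g_na_max * m3 * h * (1.0 - params.gamma) * (v - params.e_na)
    i_na_p = params.g_na_max * m3 * params.gamma * (v - params.e_na)
    i_k = params.g_k_max * n ** 4 * (v - params.e_k)
    i_leak = params.g_leak * (v - params.e_leak)
    return i_na_t, i_na_p, i_k, i_leak


def _ghk_flux_factor(u):
    """u / (1 - exp(-u)) with the removable singularity at u = 0 handled by a
    4-term Taylor expansion for |u| < 1e-4."""
    u = np.asarray(u, dtype=float)
    small = np.abs(u) < _GHK_SERIES_U
    safe = np.where(small, 1.0, u)
    direct = safe / (1.0 - np.exp(-safe))
    series = 1.0 + u / 2.0 + u * u / 12.0 - u ** 4 / 720.0
    out = np.where(small, series, direct)
    return out if out.ndim else float(out)


def ghk_current(v, ion: str, level, params: ModelParams):
    """GHK electrodiffusive current (nA) through AChR channels for one ion.

    Positive = net inward (depolarizing) cation flux; scales linearly with the
    dimensionless activation ``level`` (syn_clamp).  Evaluated in SI internally
    (permeability in m^3/s, concentrations in mol/m^3) and converted to nA.
    """
    level = np.asarray(level, dtype=float)
    if np.any(level < 0):
        raise ValueError("syn_clamp level must be >= 0")
    c = params.concentrations
    if ion == "Na":
        p = params.synapse.p_na
        c_in, c_out = c.na_in, c.na_out
    elif ion == "K":
        p = params.synapse.p_na * params.synapse.pk_over_pna
        c_in, c_out = c.k_in, c.k_out
    else:
        raise ValueError(f"unknown ion {ion!r}; expected 'Na' or 'K'")
    v = np.asarray(v, dtype=float)
    u = v / params.rt_over_f     # zFV/RT with z = +1
    flux = _ghk_flux_factor(u) * (c_out * np.exp(-u) - c_in)
    out = level * _GHK_NA_PER_MM3S * p * flux
    return out if out.ndim else float(out)


def achr_currents(v, level, params: ModelParams):
    """(I_AChR_Na, I_AChR_K) in nA, depolarizing positive."""
    return (ghk_current(v, "Na", level, params),
            ghk_current(v, "K", level, params))


def achr_reversal(params: ModelParams) -> float:
    """Zero-current potential (mV) of the combined Na+/K+ AChR pathway."""
    s = params.synapse
    c = params.concentrations
    num = s.p_na * c.na_out + s.p_na * s.pk_over_pna * c.k_out
    den = s.p_na * c.na_in + s.p_na * s.pk_over_pna * c.k_in
    return params.rt_over_f * math.log(num / den)


def current_breakdown(t: float, state: MembraneState, regime,
                      params: ModelParams) -> CurrentBreakdown:
    """All currents at time ``t`` under a stimulus regime."""
    from .stimulus import clamp_current, syn_level

    i_na_t, i_na_p, i_k, i_leak = conductance_currents(state, params)
    i_achr_na = i_achr_k = i_clamp = 0.0
    if regime is not None:
        if regime.has_synaptic:
            level = syn_level(t, regime)
            i_achr_na, i_achr_k = achr_currents(state.v, level, params)
        if regime.clamp is not None:
            i_clamp = clamp_current(t, regime.clamp)
    return CurrentBreakdown(i_na_t, i_na_p, i_k, i_leak,
                            i_achr_na, i_achr_k, i_clamp)


def rhs(t: float, state: MembraneState, regime, params: ModelParams
        ) -> np.ndarray:
    """Right-hand side of the model ODE: (dV/dt, dm/dt, dh/dt, dn/dt).

    dV/dt in mV/ms; gating derivatives follow dj/dt = alpha(1-j) - beta*j.
    ``regime`` may be None for the unstimulated membrane.
    """
    bd = current_breakdown(t, state, regime, params)
    dv = bd.net_capacitive / params.capacitance
    derivs = [dv]
    for gate, kin, x in (("m", params.kinetics_m, state.m),
                         ("h", params.kinetics_h, state.h),
                         ("n", params.kinetics_n, state.n)):
        alpha, beta = gate_rates(state.v, gate, kin)
        derivs.append(float(alpha) * (1.0 - x) - float(beta) * x)
    return np.array(derivs)


def resting_state(params: ModelParams, v_bracket: Tuple[float, float] = None,
                  tol: float = 1e-9) -> MembraneState:
    """Stable resting point of the unstimulated membrane.

    At a fixed point the gates sit on their equilibrium curves, so the search
    reduces to a 1-D root of the steady-state current balance in V.  The
    default bracket spans (E_K, -85 mV), which isolates the stable rest point
    from the unstable threshold point; V_rest sits a fraction of a mV above
    E_K where the small Na window/leak currents balance I_K.

    Raises
    ------
    RuntimeError
        If no root lies in the bracket or the residual exceeds ``tol``.
    """
    from scipy.optimize import brentq

    if v_bracket is None:
        v_bracket = (params.e_k + 1e-9, -85.0)

    def balance(v):
        m, h, n = equilibrium_gates(v, params)
        st = MembraneState(v, float(m), float(h), float(n))
        i_na_t, i_na_p, i_k, i_leak = conductance_currents(st, params)
        return -(i_na_t + i_na_p + i_k + i_leak)

    try:
        v0 = brentq(balance, *v_bracket, xtol=1e-13)
    except ValueError as err:
        raise RuntimeError(f"no resting point in bracket {v_bracket}: {err}")
    m, h, n = equilibrium_gates(v0, params)
    state = MembraneState(v0, float(m), float(h), float(n))
    resid = np.abs(rhs(0.0, state, None, params))
    if np.any(resid > tol):
        raise RuntimeError(f"resting-state residual too large: {resid}")
    return state
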