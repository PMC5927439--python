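"""Compiled fixed-step integration kernel.

A Strang-split exponential scheme: each step advances the gating variables a
half step with exact exponential relaxation toward their equilibrium at the
current voltage (Rush-Larsen), advances the voltage a full step with an
exponential-Euler update (the conductance currents are linear in V, so the
linear part is integrated exactly; the GHK stimulus is handled by a
predictor-corrector), then advances the gates the remaining half step at the
new voltage.  The scheme is unconditionally stable in the gating equations,
second-order by symmetry, and bit-for-bit reproducible.

The physical formulas duplicate :mod:`electrocyte.currents` /
:mod:`electrocyte.stimulus`; the test suite asserts finite-difference
consistency of kernel trajectories with the reference right-hand side.
"""

import math

import numpy as np
from numba import njit

# clamp kinds
CLAMP_NONE = 0
CLAMP_STEP = 1
CLAMP_RAMP = 2
CLAMP_TRAIN = 3


@njit(cache=True)
def _ghk_pair(v, pre_na, pre_k, na_in, na_out, k_in, k_out, rtf):
    """Unit-level AChR (Na, K) currents in nA, depolarizing positive."""
    u = v / rtf
    if abs(u) < 1e-4:
        f = 1.0 + u / 2.0 + u * u / 12.0 - u ** 4 / 720.0
    else:
        f = u / (1.0 - math.exp(-u))
    emu = math.exp(-u)
    i_na = pre_na * f * (na_out * emu - na_in)
    i_k = pre_k * f * (k_out * emu - k_in)
    return i_na, i_k


@njit(cache=True)
def _syn(t, bg, amp, period, rise, plateau, tau):
    s = bg
    if amp > 0.0:
        tp = t % period
        if tp < rise:
            s += amp * tp / rise
        elif tp < rise + plateau:
            s += amp
        else:
            s += amp * math.exp(-(tp - rise - plateau) / tau)
    return s


@njit(cache=True)
def _clamp(t, kind, amp, start, dur, width, period):
    if kind == CLAMP_NONE:
        return 0.0
    rel = t - start
    if rel < 0.0 or rel >= dur:
        return 0.0
    if kind == CLAMP_STEP:
        return amp
    if kind == CLAMP_RAMP:
        return amp * rel / dur
    # pulse train
    if rel % period < width:
        return amp
    return 0.0


@njit(cache=True)
def integrate_kernel(v0, m0, h0, n0, dt, nstep, stride,
                     cm, gna, gk, gl, gamma, ena, ek, el,
                     kam, eam, kbm, ebm,
                     kah, eah, bh_max, bh_vhalf, bh_slope,
                     kan, ean, kbn, ebn,
                     pre_na, pre_k, na_in, na_out, k_in, k_out, rtf,
                     bg, amp, period, rise, plateau, tau,
                     clamp_kind, clamp_amp, clamp_start, clamp_dur,
                     clamp_width, clamp_period):
    """Integrate ``nstep`` steps of size ``dt`` (ms), sampling every ``stride``
    steps (including the initial state).  Returns (t, v, m, h, n) arrays."""
    nsamp = nstep // stride + 1
    ts = np.empty(nsamp)
    vs = np.empty(nsamp)
    ms = np.empty(nsamp)
    hs = np.empty(nsamp)
    ns = np.empty(nsamp)
    v, m, h, n = v0, m0, h0, n0
    ts[0] = 0.0
    vs[0] = v
    ms[0] = m
    hs[0] = h
    ns[0] = n
    k = 1
    half = 0.5 * dt
    for i in range(nstep):
        t = i * dt
        # --- gates: half step at V(t) ---
        am = kam * math.exp(eam * v)
        bm = kbm * math.exp(ebm * v)
        ah = kah * math.exp(eah * v)
        bh = bh_max / (math.exp(-(v - bh_vhalf) / bh_slope) + 1.0)
        an = kan * math.exp(ean * v)
        bn = kbn * math.exp(ebn * v)
        m += (am / (am + bm) - m) * (1.0 - math.exp(-(am + bm) * half))
        h += (ah / (ah + bh) - h) * (1.0 - math.exp(-(ah + bh) * half))
        n += (an / (an + bn) - n) * (1.0 - math.exp(-(an + bn) * half))
        # --- voltage: exponential Euler with GHK predictor-corrector ---
        s = _syn(t + half, bg, amp, period, rise, plateau, tau)
        ic = _clamp(t + half, clamp_kind, clamp_amp, clamp_start, clamp_dur,
                    clamp_width, clamp_period)
        m3 = m * m * m
        g_na_t = gna * m3 * h * (1.0 - gamma)
        g_na_p = gna * m3 * gamma
        g_kv = gk * n * n * n * n
        g_tot = g_na_t + g_na_p + g_kv + gl
        e_decay = math.exp(-dt * g_tot / cm)
        i_na, i_k = _ghk_pair(v, pre_na, pre_k, na_in, na_out, k_in, k_out, rtf)
        i_stim = s * (i_na + i_k) + ic
        v_inf = ((g_na_t + g_na_p) * ena + g_kv * ek + gl * el + i_stim) / g_tot
        v_pred = v_inf + (v - v_inf) * e_decay
        i_na2, i_k2 = _ghk_pair(v_pred, pre_na, pre_k,
                                na_in, na_out, k_in, k_out, rtf)
        i_stim = s * 0.5 * (i_na + i_k + i_na2 + i_k2) + ic
        v_inf = ((g_na_t + g_na_p) * ena + g_kv * ek + gl * el + i_stim) / g_tot
        v = v_inf + (v - v_inf) * e_decay
        # --- gates: half step at V(t+dt) ---
        am = kam * math.exp(eam * v)
        bm = kbm * math.exp(ebm * v)
        ah = kah * math.exp(eah * v)
        bh = bh_max / (math.exp(-(v - bh_vhalf) / bh_slope) + 1.0)
        an = kan * math.exp(ean * v)
        bn = kbn * math.exp(ebn * v)
        m += (am / (am + bm) - m) * (1.0 - math.exp(-(am + bm) * half))
        h += (ah / (ah + bh) - h) * (1.0 - math.exp(-(ah + bh) * half))
        n += (an / (an + bn) - n) * (1.0 - math.exp(-(an + bn) * half))
        if (i + 1) % stride == 0:
            ts[k] = (i + 1) * dt
            vs[k] = v
            ms[k] = m
            hs[k] = h
            ns[k] = n
            k += 1
    return ts[:k], vs[:k], ms[:k], hs[:k], ns[:k]
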