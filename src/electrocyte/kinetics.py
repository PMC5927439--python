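"""Gating-particle rate laws and equilibrium curves.

All functions accept scalar or ndarray voltage and broadcast.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np

from .params import GateKinetics, ModelParams

_GATES = ("m", "h", "n")


def gate_rates(v, gate: str, kinetics: GateKinetics) -> Tuple[np.ndarray, np.ndarray]:
    """Opening and closing rates (alpha, beta) in ms^-1 at potential ``v`` (mV).

    ``alpha = k_alpha * exp(eta_alpha * V)`` for every gate; ``beta`` follows
    the analogous exponential law for m and n, and the saturating sigmoidal
    law for h (see :class:`~electrocyte.params.GateKinetics`).
    """
    if gate not in _GATES:
        raise ValueError(f"unknown gate {gate!r}; expected one of {_GATES}")
    v = np.asarray(v, dtype=float)
    alpha = kinetics.k_alpha * np.exp(kinetics.eta_alpha * v)
    if kinetics.beta_form == "exp":
        beta = kinetics.k_beta * np.exp(kinetics.eta_beta * v)
    else:
        beta = kinetics.beta_sigmoid_max / (
            np.exp(-(v - kinetics.beta_sigmoid_vhalf) / kinetics.beta_sigmoid_slope)
            + 1.0)
    return alpha, beta


def gate_equilibrium(v, gate: str, kinetics: GateKinetics) -> Tuple[np.ndarray, np.ndarray]:
    """Steady-state open probability and relaxation time constant at ``v``.

    Returns ``(x_inf, tau)`` with ``x_inf = alpha/(alpha+beta)`` (dimensionless,
    in (0, 1)) and ``tau = 1/(alpha+beta)`` (ms).
    """
    alpha, beta = gate_rates(v, gate, kinetics)
    total = alpha + beta
    return alpha / total, 1.0 / total


def equilibrium_gates(v, params: ModelParams):
    """(m_inf, h_inf, n_inf) at potential ``v`` for a full parameter set."""
    m_inf, _ = gate_equilibrium(v, "m", params.kinetics_m)
    h_inf, _ = gate_equilibrium(v, "h", params.kinetics_h)
    n_inf, _ = gate_equilibrium(v, "n", params.kinetics_n)
    return m_inf, h_inf, n_inf


def activation_midpoint(params: ModelParams, gate: str, power: int,
                        bracket=(-80.0, 40.0)) -> float:
    """Potential (mV) at which the steady-state activation ``x_inf**power``
    reaches one half (e.g. the m^3 or n^4 curve midpoint)."""
    from scipy.optimize import brentq

    kin = {"m": params.kinetics_m, "h": params.kinetics_h,
           "n": params.kinetics_n}[gate]

    def f(v):
        x_inf, _ = gate_equilibrium(v, gate, kin)
        return float(x_inf) ** power - 0.5

    return brentq(f, *bracket, xtol=1e-10)
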