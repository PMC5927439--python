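"""Model parameters for the electrocyte posterior-membrane model.

The excitable posterior membrane of an *Eigenmannia* electrocyte is described
by a Hodgkin-Huxley-type system: a transient and a persistent Nav current
sharing m^3 activation, a delayed-rectifier Kv current with n^4 activation, an
ohmic leak, and a nicotinic AChR synaptic pathway modeled as
Goldman-Hodgkin-Katz (GHK) electrodiffusion of Na+ and K+.

Units follow the electrophysiological convention that keeps the membrane
equation free of conversion factors: potentials in mV, time in ms, conductance
in uS, capacitance in nF, currents in nA (uS x mV = nA and nA/nF = mV/ms).
The GHK pathway is evaluated in SI internally (see :mod:`electrocyte.currents`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

#: Faraday constant (C/mol).
FARADAY = 96485.33212
#: Molar gas constant (J/(mol K)).
GAS_CONSTANT = 8.31446261815324
#: Elementary charge (C).
ELEMENTARY_CHARGE = 1.602176634e-19

#: Ion count carried by 1 nA flowing for 1 ms (singly charged):
#: 1 nA ms = 1e-12 C = 6.2415e6 ions.
IONS_PER_NA_MS = 1e-12 / ELEMENTARY_CHARGE


def nernst(c_out: float, c_in: float, temperature: float) -> float:
    """Nernst equilibrium potential (mV) for a monovalent cation.

    Parameters
    ----------
    c_out, c_in
        Extracellular and intracellular concentrations (mM); must be > 0.
    temperature
        Absolute temperature (K).
    """
    if c_out <= 0 or c_in <= 0:
        raise ValueError("concentrations must be strictly positive")
    rt_over_f = 1000.0 * GAS_CONSTANT * temperature / FARADAY  # mV
    return rt_over_f * math.log(c_out / c_in)


@dataclass(frozen=True)
class GateKinetics:
    """Voltage-dependent opening/closing rates of one gating particle.

    Both rates follow single-exponential laws ``alpha = k_alpha*exp(eta_alpha*V)``
    and ``beta = k_beta*exp(eta_beta*V)`` except for the inactivation gate h,
    whose closing rate is the saturating (sigmoidal) law used by Hodgkin and
    Huxley, ``beta_h = k / (exp(-(V - v_half)/slope) + 1)``.  With the default
    constants this drives the inactivation time constant to ~0.3 ms at strong
    depolarization, as measured in electrocyte Nav channels.
    """

    k_alpha: float          # ms^-1
    eta_alpha: float        # mV^-1
    k_beta: Optional[float] = None      # ms^-1 (exponential form only)
    eta_beta: Optional[float] = None    # mV^-1 (exponential form only)
    beta_form: str = "exp"  # "exp" | "sigmoid"
    # sigmoidal beta constants (used only when beta_form == "sigmoid")
    beta_sigmoid_max: float = 3.33      # ms^-1
    beta_sigmoid_vhalf: float = -30.0   # mV
    beta_sigmoid_slope: float = 9.0     # mV

    def __post_init__(self) -> None:
        if self.k_alpha <= 0:
            raise ValueError("k_alpha must be > 0")
        if self.beta_form == "exp":
            if self.k_beta is None or self.eta_beta is None:
                raise ValueError("exponential beta requires k_beta and eta_beta")
            if self.k_beta <= 0:
                raise ValueError("k_beta must be > 0")
        elif self.beta_form == "sigmoid":
            if self.k_beta is not None or self.eta_beta is not None:
                raise ValueError("sigmoidal beta takes no (k_beta, eta_beta)")
            if self.beta_sigmoid_max <= 0 or self.beta_sigmoid_slope <= 0:
                raise ValueError("sigmoidal beta constants must be > 0")
        else:
            raise ValueError(f"unknown beta_form: {self.beta_form!r}")


@dataclass(frozen=True)
class IonConcentrations:
    """Intra/extracellular Na+ and K+ concentrations (mM = mol/m^3).

    These feed only the GHK synaptic pathway; the fixed reversal potentials of
    the conductance currents are independent constants (the model assumes
    perfect ion homeostasis).
    """

    na_in: float
    na_out: float
    k_in: float
    k_out: float

    def __post_init__(self) -> None:
        for name in ("na_in", "na_out", "k_in", "k_out"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class SynapsePermeability:
    """AChR channel permeability-area product and K/Na permeability ratio.

    ``p_na`` is in mm^3/s for the whole innervated membrane patch (permeability
    times synaptic membrane area); ``pk_over_pna`` is dimensionless.
    """

    p_na: float
    pk_over_pna: float

    def __post_init__(self) -> None:
        if self.p_na <= 0 or self.pk_over_pna <= 0:
            raise ValueError("permeabilities must be strictly positive")


@dataclass(frozen=True)
class ModelParams:
    """Complete parameter set of the posterior-membrane model."""

    capacitance: float      # nF
    g_na_max: float         # uS
    g_k_max: float          # uS
    g_leak: float           # uS
    gamma: float            # persistent fraction of gNa, dimensionless
    e_na: float             # mV (fixed)
    e_k: float              # mV (fixed)
    e_leak: float           # mV (fixed, == e_k)
    temperature: float      # K
    kinetics_m: GateKinetics
    kinetics_h: GateKinetics
    kinetics_n: GateKinetics
    concentrations: IonConcentrations
    synapse: SynapsePermeability

    def __post_init__(self) -> None:
        if not (0.0 <= self.gamma <= 1.0):
            raise ValueError("gamma must be in [0, 1]")
        for name in ("capacitance", "g_na_max", "g_k_max", "g_leak"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.e_leak != self.e_k:
            raise ValueError("e_leak must equal e_k in this model")
        if self.kinetics_h.beta_form != "sigmoid":
            raise ValueError("h gate must use the sigmoidal beta law")
        ek_nernst = nernst(self.concentrations.k_out, self.concentrations.k_in,
                           self.temperature)
        if abs(ek_nernst - self.e_k) > 0.5:
            raise ValueError(
                f"K+ Nernst potential {ek_nernst:.2f} mV inconsistent with "
                f"fixed E_K = {self.e_k} mV (|diff| > 0.5 mV)")

    @property
    def rt_over_f(self) -> float:
        """Thermal voltage RT/F in mV."""
        return 1000.0 * GAS_CONSTANT * self.temperature / FARADAY

    def with_g_na_max(self, g_na_max: float) -> "ModelParams":
        """Copy of this parameter set with a different maximal Na conductance."""
        return replace(self, g_na_max=g_na_max)


def epm_default() -> ModelParams:
    """Default posterior-membrane parameter profile ("epm-default").

    Notes
    -----
    The temperature (293.15 K) is chosen so that the K+ Nernst potential from
    the listed concentrations reproduces the fixed E_K = -94 mV.  The
    intracellular Na+ concentration is 13.5 mM, which simultaneously
    reproduces E_Na = 55 mV (Nernst) and the two-ion GHK reversal potential of
    the AChR pathway (+2.18 mV with P_K/P_Na = 1.11).
    """
    return ModelParams(
        capacitance=50.0,
        g_na_max=700.0,
        g_k_max=2000.0,
        g_leak=5.0,
        gamma=0.02,
        e_na=55.0,
        e_k=-94.0,
        e_leak=-94.0,
        temperature=293.15,
        kinetics_m=GateKinetics(k_alpha=8.03, eta_alpha=0.0037,
                                k_beta=0.2195, eta_beta=-0.0763),
        kinetics_h=GateKinetics(k_alpha=0.02247, eta_alpha=-0.06802,
                                beta_form="sigmoid"),
        kinetics_n=GateKinetics(k_alpha=2.135, eta_alpha=0.03792,
                                k_beta=0.3524, eta_beta=-0.01552),
        concentrations=IonConcentrations(na_in=13.5, na_out=120.0,
                                         k_in=89.0, k_out=2.16),
        synapse=SynapsePermeability(p_na=0.00016, pk_over_pna=1.11),
    )


#: Named parameter profiles available to config files and the CLI.
PROFILES = {"epm-default": epm_default}
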