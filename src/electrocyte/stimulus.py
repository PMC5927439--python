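"""Stimulus waveforms: synaptic activation (syn_clamp) and current clamp.

Synaptic drive is expressed as a dimensionless, time-varying scale factor on
the AChR cation permeability ("syn_clamp").  The standard pulsatile stimulus
has a 0.05 ms linear rise, a 0.200 ms plateau and an exponential decay with a
0.1 ms time constant, restarting every stimulus period; pulses may ride
additively atop a constant background level.  Current-clamp drives (step,
ramp, brief pulse train) reproduce the classic electrocyte I-clamp protocols.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np


@dataclass(frozen=True)
class PulsatileSynDrive:
    """Periodic pulsatile synaptic activation.

    ``amplitude`` is the dimensionless syn_clamp peak; ``frequency`` in Hz.
    The shape constants (ms) default to the standard stimulus.
    """

    amplitude: float
    frequency: float
    rise: float = 0.05
    plateau: float = 0.200
    decay_tau: float = 0.1

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.frequency <= 0:
            raise ValueError("frequency must be > 0")
        if self.period <= self.rise + self.plateau:
            raise ValueError("stimulus period must exceed rise + plateau")

    @property
    def period(self) -> float:
        """Stimulus period in ms."""
        return 1000.0 / self.frequency


@dataclass(frozen=True)
class BackgroundSynDrive:
    """Constant (0 Hz) synaptic activation level."""

    level: float

    def __post_init__(self) -> None:
        if self.level < 0:
            raise ValueError("background level must be >= 0")


@dataclass(frozen=True)
class CurrentClampDrive:
    """Injected-current protocol: ``step``, ``ramp`` or ``pulse-train``.

    For ``step`` the current is ``amplitude`` (nA) on [start, start+duration).
    For ``ramp`` it rises linearly from 0 to ``amplitude`` over ``duration``.
    For ``pulse-train`` rectangular pulses of ``pulse_width`` ms repeat at
    ``frequency`` Hz within the protocol window.
    """

    kind: str
    amplitude: float        # nA (peak amplitude for ramp)
    duration: float         # ms
    start: float = 0.0      # ms
    pulse_width: Optional[float] = None   # ms, pulse-train only
    frequency: Optional[float] = None     # Hz, pulse-train only

    def __post_init__(self) -> None:
        if self.kind not in ("step", "ramp", "pulse-train"):
            raise ValueError(f"unknown current-clamp kind {self.kind!r}")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.kind == "pulse-train":
            if not self.pulse_width or not self.frequency:
                raise ValueError("pulse-train needs pulse_width and frequency")
            if self.pulse_width >= 1000.0 / self.frequency:
                raise ValueError("pulse width must be shorter than the period")


@dataclass(frozen=True)
class StimulusRegime:
    """Declarative stimulus description: synaptic and/or injected drive."""

    pulsatile: Optional[PulsatileSynDrive] = None
    background: Optional[BackgroundSynDrive] = None
    clamp: Optional[CurrentClampDrive] = None

    def __post_init__(self) -> None:
        if self.pulsatile is None and self.background is None and self.clamp is None:
            raise ValueError("regime must contain at least one drive component")
        if self.clamp is not None and (self.pulsatile is not None
                                       or self.background is not None):
            warnings.warn("combining synaptic and current-clamp drive is not a "
                          "standard protocol", stacklevel=3)

    @property
    def has_synaptic(self) -> bool:
        return self.pulsatile is not None or self.background is not None


def pulse_shape(t_in_period, rise: float = 0.05, plateau: float = 0.200,
                decay_tau: float = 0.1):
    """Unit pulsatile waveform evaluated at a phase ``t_in_period`` (ms).

    Piecewise: ``t/rise`` during the rise, 1 on the plateau, then
    ``exp(-(t-rise-plateau)/decay_tau)``.  The caller is responsible for
    wrapping t into [0, period); the tail is truncated at the period end
    (carry-over is < e^-10 even at 600 Hz).
    """
    t = np.asarray(t_in_period, dtype=float)
    out = np.where(
        t < rise, t / rise,
        np.where(t < rise + plateau, 1.0,
                 np.exp(-(t - rise - plateau) / decay_tau)))
    return out if out.ndim else float(out)


def syn_level(t, regime: StimulusRegime):
    """Total syn_clamp level at time ``t`` (ms): background + pulsatile."""
    if not regime.has_synaptic:
        raise ValueError("regime has no synaptic component")
    t = np.asarray(t, dtype=float)
    level = np.zeros_like(t)
    if regime.background is not None:
        level = level + regime.background.level
    p = regime.pulsatile
    if p is not None and p.amplitude > 0:
        level = level + p.amplitude * pulse_shape(
            np.mod(t, p.period), p.rise, p.plateau, p.decay_tau)
    return level if level.ndim else float(level)


def clamp_current(t, drive: CurrentClampDrive):
    """Injected current (nA) at time ``t`` (ms) for a current-clamp drive."""
    t = np.asarray(t, dtype=float)
    rel = t - drive.start
    inside = (rel >= 0) & (rel < drive.duration)
    if drive.kind == "step":
        i = np.where(inside, drive.amplitude, 0.0)
    elif drive.kind == "ramp":
        i = np.where(inside, drive.amplitude * rel / drive.duration, 0.0)
    else:  # pulse-train
        period = 1000.0 / drive.frequency
        phase = np.mod(rel, period)
        i = np.where(inside & (phase < drive.pulse_width), drive.amplitude, 0.0)
    return i if i.ndim else float(i)


def stimulus_current(t, v, regime: StimulusRegime, params) -> float:
    """Total stimulus current I_stim (nA, depolarizing positive) at (t, V)."""
    from .currents import achr_currents

    i = 0.0
    if regime.has_synaptic:
        level = syn_level(t, regime)
        i_na, i_k = achr_currents(v, level, params)
        i += i_na + i_k
    if regime.clamp is not None:
        i += clamp_current(t, regime.clamp)
    return i
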