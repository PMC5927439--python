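"""Integration, spike detection, frequency measurement and ion-entry tallies."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from . import _kernel
from .currents import MembraneState, achr_currents, resting_state
from .params import IONS_PER_NA_MS, FARADAY, ModelParams
from .stimulus import StimulusRegime, clamp_current, syn_level

#: Default integration step (ms).  Halving it changes V_peak by ~1e-5 mV
#: (see the solver-convergence test).
DEFAULT_DT = 5e-4
#: Default output sample interval (ms); well below the 0.005 ms resolution
#: needed to follow the 0.05 ms stimulus rise.
DEFAULT_SAMPLE_DT = 2e-3

#: Spike detection: upward crossing of this potential (mV) counts as a spike
#: (well above the ~-45 mV apparent threshold, below all reported peaks).
SPIKE_THRESHOLD = -20.0
#: Absolute refractory lockout for spike detection (ms).
SPIKE_REFRACTORY = 0.5


@dataclass(frozen=True)
class SolverOptions:
    """Fixed-step solver settings; identical options give bit-for-bit
    identical trajectories."""

    dt: float = DEFAULT_DT
    sample_dt: float = DEFAULT_SAMPLE_DT

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.sample_dt < self.dt:
            raise ValueError("need dt > 0 and sample_dt >= dt")


@dataclass
class Trajectory:
    """Sampled solution of the membrane equation under one stimulus regime."""

    t: np.ndarray
    v: np.ndarray
    m: np.ndarray
    h: np.ndarray
    n: np.ndarray
    regime: Optional[StimulusRegime]
    params: ModelParams
    options: SolverOptions

    def breakdown(self) -> dict:
        """Per-sample current breakdown (nA) as named arrays.

        Conductance currents outward-positive, AChR/clamp depolarizing-positive
        (the membrane-equation convention).
        """
        p = self.params
        m3 = self.m ** 3
        out = {
            "i_na_t": p.g_na_max * m3 * self.h * (1 - p.gamma) * (self.v - p.e_na),
            "i_na_p": p.g_na_max * m3 * p.gamma * (self.v - p.e_na),
            "i_k": p.g_k_max * self.n ** 4 * (self.v - p.e_k),
            "i_leak": p.g_leak * (self.v - p.e_leak),
        }
        if self.regime is not None and self.regime.has_synaptic:
            level = syn_level(self.t, self.regime)
            i_na, i_k = achr_currents(self.v, level, p)
            out["i_achr_na"], out["i_achr_k"] = i_na, i_k
        else:
            out["i_achr_na"] = np.zeros_like(self.v)
            out["i_achr_k"] = np.zeros_like(self.v)
        if self.regime is not None and self.regime.clamp is not None:
            out["i_clamp"] = np.asarray(clamp_current(self.t, self.regime.clamp))
        else:
            out["i_clamp"] = np.zeros_like(self.v)
        return out

    def to_csv(self, path) -> None:
        """Write the trajectory with per-current columns (units in header)."""
        import pandas as pd

        bd = self.breakdown()
        df = pd.DataFrame({
            "t_ms": self.t, "V_mV": self.v,
            "m": self.m, "h": self.h, "n": self.n,
            "I_NaT_nA": bd["i_na_t"], "I_NaP_nA": bd["i_na_p"],
            "I_K_nA": bd["i_k"], "I_L_nA": bd["i_leak"],
            "I_AChR_Na_nA": bd["i_achr_na"], "I_AChR_K_nA": bd["i_achr_k"],
            "I_clamp_nA": bd["i_clamp"],
        })
        df.to_csv(path, index=False, float_format="%.10g")


@dataclass(frozen=True)
class SpikeTrain:
    """Detected spike times (ms) and interpolated peak potentials (mV)."""

    times: np.ndarray
    peaks: np.ndarray

    def __len__(self) -> int:
        return len(self.times)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"spike_times_ms": self.times.tolist(),
                       "v_peak_mV": self.peaks.tolist()}, fh, indent=1)


@dataclass(frozen=True)
class EntryTally:
    """Per-AP ion entry by pathway, in units of 1e9 ions.

    Na+ tallies count inward flux (all are >= 0 since V never nears E_Na);
    K+ tallies count net outward flux through Kv and leak and net flux through
    the AChR pathway (outward positive).
    """

    na_transient: float
    na_persistent: float
    na_achr: float
    k_delayed_rectifier: float
    k_leak: float
    k_achr: float
    n_spikes: int
    window_ms: float

    @property
    def na_nav(self) -> float:
        """Na+ entry through Nav channels (transient + persistent)."""
        return self.na_transient + self.na_persistent

    @property
    def na_total(self) -> float:
        """Total Na+ entry per AP (Nav + AChR); exactly the pathway sum."""
        return self.na_transient + self.na_persistent + self.na_achr

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({k: getattr(self, k) for k in
                       ("na_transient", "na_persistent", "na_achr", "na_nav",
                        "na_total", "k_delayed_rectifier", "k_leak", "k_achr",
                        "n_spikes", "window_ms")}, fh, indent=1)


def integrate(params: ModelParams, regime: Optional[StimulusRegime],
              duration: float, options: SolverOptions = SolverOptions(),
              initial: Optional[MembraneState] = None) -> Trajectory:
    """Integrate the model for ``duration`` ms, starting from rest by default."""
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if initial is None:
        initial = resting_state(params)
    dt = options.dt
    stride = max(1, int(round(options.sample_dt / dt)))
    nstep = int(round(duration / dt))

    # pack drive
    bg = amp = 0.0
    period = rise = plateau = tau = 1.0
    clamp_kind = _kernel.CLAMP_NONE
    clamp_amp = clamp_start = clamp_width = clamp_period = 0.0
    clamp_dur = 1.0
    if regime is not None:
        if regime.background is not None:
            bg = regime.background.level
        p = regime.pulsatile
        if p is not None:
            amp, period = p.amplitude, p.period
            rise, plateau, tau = p.rise, p.plateau, p.decay_tau
        c = regime.clamp
        if c is not None:
            clamp_kind = {"step": _kernel.CLAMP_STEP, "ramp": _kernel.CLAMP_RAMP,
                          "pulse-train": _kernel.CLAMP_TRAIN}[c.kind]
            clamp_amp, clamp_start, clamp_dur = c.amplitude, c.start, c.duration
            if c.kind == "pulse-train":
                clamp_width = c.pulse_width
                clamp_period = 1000.0 / c.frequency
            else:
                clamp_width, clamp_period = 0.0, 1.0

    p = params
    pre_na = FARADAY * p.synapse.p_na
    pre_k = pre_na * p.synapse.pk_over_pna
    c = p.concentrations
    km, kh, kn = p.kinetics_m, p.kinetics_h, p.kinetics_n
    t, v, m, h, n = _kernel.integrate_kernel(
        initial.v, initial.m, initial.h, initial.n, dt, nstep, stride,
        p.capacitance, p.g_na_max, p.g_k_max, p.g_leak, p.gamma,
        p.e_na, p.e_k, p.e_leak,
        km.k_alpha, km.eta_alpha, km.k_beta, km.eta_beta,
        kh.k_alpha, kh.eta_alpha,
        kh.beta_sigmoid_max, kh.beta_sigmoid_vhalf, kh.beta_sigmoid_slope,
        kn.k_alpha, kn.eta_alpha, kn.k_beta, kn.eta_beta,
        pre_na, pre_k, c.na_in, c.na_out, c.k_in, c.k_out, p.rt_over_f,
        bg, amp, period, rise, plateau, tau,
        clamp_kind, clamp_amp, clamp_start, clamp_dur,
        clamp_width, clamp_period)
    if not (np.all((m >= 0) & (m <= 1)) and np.all((h >= 0) & (h <= 1))
            and np.all((n >= 0) & (n <= 1))):
        raise RuntimeError("gating variable left [0, 1]; integration invalid")
    return Trajectory(t, v, m, h, n, regime, params, options)


def detect_spikes(traj: Trajectory, threshold: float = SPIKE_THRESHOLD,
                  refractory: float = SPIKE_REFRACTORY) -> SpikeTrain:
    """Detect spikes as upward threshold crossings followed by a local maximum.

    The peak time and potential are refined by a quadratic through the three
    samples bracketing the maximum.  An empty train is allowed.
    """
    t, v = traj.t, traj.v
    cross = np.flatnonzero((v[:-1] < threshold) & (v[1:] >= threshold))
    times, peaks = [], []
    last = -math.inf
    for i in cross:
        j = i
        while j + 1 < len(v) and v[j + 1] >= v[j]:
            j += 1
        if j == 0 or j + 1 >= len(v):
            continue  # maximum not bracketed by samples
        y0, y1, y2 = v[j - 1], v[j], v[j + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom == 0.0:
            tp, vp = t[j], y1
        else:
            off = 0.5 * (y0 - y2) / denom
            tp = t[j] + off * (t[j] - t[j - 1])
            vp = y1 - 0.25 * (y0 - y2) * off
        if tp - last < refractory:
            continue
        times.append(tp)
        peaks.append(vp)
        last = tp
    return SpikeTrain(np.array(times), np.array(peaks))


def measure_frequency(train: SpikeTrain, window: Tuple[float, float]) -> float:
    """Mean firing rate (Hz) from inter-spike intervals inside ``window``.

    Fewer than 3 spikes in the window is reported as non-firing (0 Hz).
    """
    t0, t1 = window
    sel = train.times[(train.times >= t0) & (train.times <= t1)]
    if len(sel) < 3:
        return 0.0
    return 1000.0 / float(np.diff(sel).mean())


def mean_peak(train: SpikeTrain, window: Tuple[float, float]) -> float:
    """Mean interpolated V_peak (mV) of the spikes inside ``window``."""
    mask = (train.times >= window[0]) & (train.times <= window[1])
    if not mask.any():
        raise ValueError("no spikes in window")
    return float(train.peaks[mask].mean())


def _integrate_window(t: np.ndarray, y: np.ndarray, t0: float, t1: float) -> float:
    mask = (t >= t0) & (t <= t1)
    return float(np.trapezoid(y[mask], t[mask]))


def tally_entry(traj: Trajectory, train: SpikeTrain,
                skip_periods: int = 5, skip_ms: float = 25.0,
                min_spikes: int = 20) -> EntryTally:
    """Per-AP ion entry by pathway over the post-transient steady state.

    Charge through each pathway is integrated over an integer number of
    analysis windows and converted at 1 nA ms = 6.2415e6 ions.  For pulsatile
    drive the windows are stimulus periods (the first ``skip_periods`` are
    discarded); for steady drive they are the midpoints between successive
    spikes after ``skip_ms``.  The leak carries no Na+ (E_L = E_K), so total
    Na+ entry is exactly transient + persistent + AChR.

    Raises
    ------
    ValueError
        If fewer than ``min_spikes`` post-transient spikes are available.
    """
    t = traj.t
    pulsatile = traj.regime is not None and traj.regime.pulsatile is not None \
        and traj.regime.pulsatile.amplitude > 0
    if pulsatile:
        period = traj.regime.pulsatile.period
        t0 = skip_periods * period
        t1 = math.floor(t[-1] / period) * period
    else:
        post = train.times[train.times >= skip_ms]
        if len(post) < 3:
            raise ValueError("steady-drive tally needs >= 3 post-transient spikes")
        t0 = 0.5 * (post[0] + post[1])
        t1 = 0.5 * (post[-2] + post[-1])
    n_spk = int(np.count_nonzero((train.times >= t0) & (train.times <= t1)))
    if n_spk < min_spikes:
        raise ValueError(f"only {n_spk} post-transient APs in tally window; "
                         f"need >= {min_spikes}")
    bd = traj.breakdown()
    scale = IONS_PER_NA_MS / n_spk / 1e9  # -> 1e9 ions per AP
    return EntryTally(
        na_transient=_integrate_window(t, -bd["i_na_t"], t0, t1) * scale,
        na_persistent=_integrate_window(t, -bd["i_na_p"], t0, t1) * scale,
        na_achr=_integrate_window(t, bd["i_achr_na"], t0, t1) * scale,
        k_delayed_rectifier=_integrate_window(t, bd["i_k"], t0, t1) * scale,
        k_leak=_integrate_window(t, bd["i_leak"], t0, t1) * scale,
        k_achr=_integrate_window(t, -bd["i_achr_k"], t0, t1) * scale,
        n_spikes=n_spk,
        window_ms=t1 - t0,
    )
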