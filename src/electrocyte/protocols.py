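"""Experiment protocols: calibration, thresholds, f-I curves, entrainment
staircases, per-AP Na+ cost budgets and the jamming-avoidance sweep.

The organizing idea: across the species' discharge range (200-600 Hz) the
action potential amplitude is held at a standard V_peak by adjusting only the
maximal Na conductance (a proxy for Nav channel density), and the energetic
cost of each AP is the Na+ load it imposes on the 3Na+/2K+-ATPase, tallied
separately for Nav and AChR pathways.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .currents import resting_state
from .params import ModelParams
from .simulate import (SolverOptions, SpikeTrain, Trajectory, detect_spikes,
                       integrate, mean_peak, measure_frequency, tally_entry)
from .stimulus import (BackgroundSynDrive, CurrentClampDrive,
                       PulsatileSynDrive, StimulusRegime)

#: Standard AP amplitude used as the calibration target (mV).
STANDARD_V_PEAK = 12.86
#: Bisection resolution for maximal Na conductance (uS).
G_NA_TOL = 0.5
#: Bisection resolution for syn_clamp threshold searches.
LEVEL_TOL = 1e-4
#: Relative frequency tolerance for recognizing phase locking.
LOCK_TOL = 0.01


def pulsatile_regime(amplitude: float, frequency: float,
                     background: float = 0.0) -> StimulusRegime:
    """Pulsatile synaptic drive, optionally atop a constant background."""
    return StimulusRegime(
        pulsatile=PulsatileSynDrive(amplitude=amplitude, frequency=frequency)
        if amplitude > 0 else None,
        background=BackgroundSynDrive(level=background)
        if (background > 0 or amplitude == 0) else None,
    )


def steady_regime(level: float) -> StimulusRegime:
    """Constant (0 Hz) synaptic drive."""
    return StimulusRegime(background=BackgroundSynDrive(level=level))


@dataclass(frozen=True)
class PulsatileResponse:
    """Steady-state response of the membrane to periodic pulses."""

    v_peak: float           # mean post-transient interpolated peak (mV)
    n_spikes: int
    n_periods: int
    entrained: bool         # 1:1 spike-per-stimulus over the analysis window
    train: SpikeTrain


def pulsatile_response(params: ModelParams, frequency: float,
                       amplitude: float = 1.0, background: float = 0.0,
                       n_periods: int = 30, skip_periods: int = 10,
                       options: SolverOptions = SolverOptions(),
                       initial=None) -> PulsatileResponse:
    """Run ``n_periods`` of pulsatile drive and summarize the steady state."""
    period = 1000.0 / frequency
    regime = pulsatile_regime(amplitude, frequency, background)
    traj = integrate(params, regime, n_periods * period, options,
                     initial=initial)
    train = detect_spikes(traj)
    t0, t1 = skip_periods * period, n_periods * period
    mask = (train.times >= t0) & (train.times <= t1)
    n_spk = int(mask.sum())
    n_per = n_periods - skip_periods
    v_peak = float(train.peaks[mask].mean()) if n_spk else -math.inf
    return PulsatileResponse(v_peak=v_peak, n_spikes=n_spk, n_periods=n_per,
                             entrained=abs(n_spk - n_per) <= 0,
                             train=train)


def calibrate_gnamax(frequency: float, params: ModelParams,
                     amplitude: float = 1.0, background: float = 0.0,
                     target_vpeak: float = STANDARD_V_PEAK,
                     bracket: Tuple[float, float] = (400.0, 2500.0),
                     tol: float = G_NA_TOL) -> float:
    """Maximal Na conductance (uS) yielding the standard V_peak at ``frequency``.

    Bisection on g_na_max against the mean steady-state V_peak of a 1:1
    entrained pulsatile train.  A conductance too low to entrain 1:1 counts
    as below target (dropped spikes mean insufficient gNa); the upper bracket
    end must entrain, otherwise RuntimeError.
    """
    lo, hi = bracket

    def peak(g):
        r = pulsatile_response(params.with_g_na_max(g), frequency, amplitude,
                               background)
        return r.v_peak if r.entrained else -math.inf

    r_hi = pulsatile_response(params.with_g_na_max(hi), frequency, amplitude,
                              background)
    if not r_hi.entrained:
        raise RuntimeError(
            f"no 1:1 entrainment at upper bracket g_na_max={hi:.1f} uS, "
            f"{frequency} Hz ({r_hi.n_spikes} spikes / {r_hi.n_periods} "
            "stimuli)")
    p_lo, p_hi = peak(lo), r_hi.v_peak
    if not (p_lo < target_vpeak < p_hi):
        raise RuntimeError(
            f"target V_peak {target_vpeak} mV not bracketed: "
            f"[{p_lo:.2f}, {p_hi:.2f}] mV on g_na_max [{lo}, {hi}] uS")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if peak(mid) < target_vpeak:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def steady_response(params: ModelParams, level: float, duration: float = 525.0,
                    skip_ms: float = 25.0,
                    options: SolverOptions = SolverOptions()
                    ) -> Tuple[float, float, SpikeTrain]:
    """(frequency Hz, mean V_peak mV, train) under constant synaptic drive.

    Non-firing (fewer than 3 post-transient spikes) reports 0 Hz and nan.
    """
    traj = integrate(params, steady_regime(level), duration, options)
    train = detect_spikes(traj)
    freq = measure_frequency(train, (skip_ms, duration))
    if freq == 0.0:
        return 0.0, math.nan, train
    return freq, mean_peak(train, (skip_ms, duration)), train


def steady_threshold(params: ModelParams,
                     bracket: Tuple[float, float] = (0.002, 0.05),
                     tol: float = LEVEL_TOL, window: float = 500.0) -> float:
    """Minimal constant syn_clamp level producing sustained repetitive firing.

    Firing means >= 3 spikes in a ``window``-ms post-transient interval.
    Bisection to ``tol`` absolute; raises RuntimeError on a bad bracket.
    """
    lo, hi = bracket
    dur = window + 25.0

    def fires(level):
        return steady_response(params, level, duration=dur)[0] > 0.0

    if fires(lo) or not fires(hi):
        raise RuntimeError(f"threshold not bracketed by levels {bracket}")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if fires(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def frequency_curve(params: ModelParams, levels: Sequence[float],
                    duration: float = 525.0
                    ) -> List[Tuple[float, float, float]]:
    """f-I curve under steady synaptic drive: (level, Hz, mean V_peak) rows.

    Non-firing points report 0 Hz.  The membrane is Class 1 excitable, so the
    curve rises continuously from zero at threshold.
    """
    out = []
    for level in levels:
        freq, vp, _ = steady_response(params, level, duration)
        out.append((float(level), freq, vp))
    return out


@dataclass(frozen=True)
class StaircaseResult:
    """Output of the entrainment staircase over pulse amplitude."""

    amplitudes: np.ndarray
    frequencies: np.ndarray          # Hz, 0 where non-firing
    plateaus: List[Tuple[float, float, float]]  # (ratio, amp_lo, amp_hi)
    critical_amplitude: Optional[float]         # smallest 1:1 amplitude


def staircase(params: ModelParams, background: float, pulse_frequency: float,
              amplitudes: Optional[Sequence[float]] = None,
              n_periods: int = 120, skip_periods: int = 40) -> StaircaseResult:
    """Devil's-staircase scan: output AP frequency vs pulse amplitude.

    With a subthreshold background, weak periodic pulses entrain the membrane
    at rational fractions (1/2, 1/3, ...) of the stimulus frequency; the
    critical amplitude is the smallest sustaining 1:1 firing.  Plateaus are
    reported where the output/input frequency ratio matches 1/k (k = 1..6)
    within 1% over >= 2 consecutive grid points.
    """
    if amplitudes is None:
        amplitudes = np.arange(0.0, 0.5 + 1e-12, 0.005)
    amplitudes = np.asarray(amplitudes, dtype=float)
    period = 1000.0 / pulse_frequency
    freqs = np.zeros_like(amplitudes)
    rest = resting_state(params)
    for i, amp in enumerate(amplitudes):
        regime = pulsatile_regime(float(amp), pulse_frequency, background)
        traj = integrate(params, regime, n_periods * period, initial=rest)
        train = detect_spikes(traj)
        freqs[i] = measure_frequency(
            train, (skip_periods * period, n_periods * period))

    ratios = freqs / pulse_frequency
    plateaus = []
    k_values = [1, 2, 3, 4, 5, 6]
    for k in k_values:
        target = 1.0 / k
        on = np.abs(ratios - target) <= LOCK_TOL * target
        # contiguous runs of >= 2 grid points
        i = 0
        while i < len(on):
            if on[i]:
                j = i
                while j + 1 < len(on) and on[j + 1]:
                    j += 1
                if j > i:
                    plateaus.append((target, float(amplitudes[i]),
                                     float(amplitudes[j])))
                i = j + 1
            else:
                i += 1
    one_to_one = np.abs(ratios - 1.0) <= LOCK_TOL
    critical = None
    if one_to_one.any():
        critical = float(amplitudes[np.flatnonzero(one_to_one)[0]])
    return StaircaseResult(amplitudes, freqs, plateaus, critical)


@dataclass(frozen=True)
class CostRecord:
    """One row of the stimulus-regime cost table."""

    target_frequency: float     # Hz of the pulsatile part (0 for pure steady)
    background: float           # 0 Hz syn_clamp part
    pulse_amplitude: float      # pulsatile syn_clamp part
    g_na_max: float             # uS, calibrated for the standard V_peak
    v_peak: float               # mV, verification
    firing_frequency: float     # Hz, measured
    na_total: float             # 1e9 ions / AP
    na_nav: float
    na_achr: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "target_frequency", "background", "pulse_amplitude", "g_na_max",
            "v_peak", "firing_frequency", "na_total", "na_nav", "na_achr")}


def entry_for_regime(params: ModelParams, frequency: float, amplitude: float,
                     background: float, n_periods: int = 40,
                     skip_periods: int = 10):
    """Steady-state per-AP entry tally for a pulsatile(+background) regime."""
    period = 1000.0 / frequency
    regime = pulsatile_regime(amplitude, frequency, background)
    traj = integrate(params, regime, n_periods * period)
    train = detect_spikes(traj)
    return tally_entry(traj, train, skip_periods=skip_periods), train


def entry_for_steady(params: ModelParams, level: float, duration: float = 250.0):
    """Per-AP entry tally under constant drive (spike-midpoint windows)."""
    traj = integrate(params, steady_regime(level), duration)
    train = detect_spikes(traj)
    return tally_entry(traj, train), train


def calibrate_steady_gnamax(params: ModelParams, level: float,
                            target_vpeak: float = STANDARD_V_PEAK,
                            bracket: Tuple[float, float] = (400.0, 2500.0),
                            tol: float = G_NA_TOL) -> float:
    """g_na_max giving the standard V_peak under constant drive at ``level``."""
    lo, hi = bracket

    def peak(g):
        freq, vp, _ = steady_response(params.with_g_na_max(g), level,
                                      duration=275.0)
        if freq == 0.0:
            raise RuntimeError(f"no sustained firing at g_na_max={g:.1f} uS")
        return vp

    if not (peak(lo) < target_vpeak < peak(hi)):
        raise RuntimeError("target V_peak not bracketed for steady calibration")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if peak(mid) < target_vpeak:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


#: The 18 stimulus regimes of the cost table: (target frequency Hz,
#: background level, pulse amplitude).  For each target frequency the rows are
#: pure pulsatile; subthreshold background (80% of the 0 Hz firing threshold)
#: with standard and reduced pulses; suprathreshold background (free-running
#: at ~70% of target) with standard and reduced pulses; pure steady drive.
TABLE_REGIMES: List[Tuple[float, float, float]] = [
    (200.0, 0.0, 1.0), (200.0, 0.0074, 1.0), (200.0, 0.0074, 0.34),
    (200.0, 0.03, 1.0), (200.0, 0.03, 0.16), (200.0, 0.048, 0.0),
    (500.0, 0.0, 1.0), (500.0, 0.0064, 1.0), (500.0, 0.0064, 0.68),
    (500.0, 0.12, 1.0), (500.0, 0.12, 0.45), (500.0, 0.28, 0.0),
    (600.0, 0.0, 1.0), (600.0, 0.0054, 1.0), (600.0, 0.0054, 0.85),
    (600.0, 0.18, 1.0), (600.0, 0.18, 0.7), (600.0, 0.47, 0.0),
]


def cost_record(params: ModelParams, frequency: float, background: float,
                amplitude: float, g_na_max: Optional[float] = None
                ) -> CostRecord:
    """Calibrate (unless ``g_na_max`` is given) and tally one cost-table row."""
    if amplitude > 0:
        if g_na_max is None:
            g_na_max = calibrate_gnamax(frequency, params, amplitude,
                                        background)
        p = params.with_g_na_max(g_na_max)
        tally, train = entry_for_regime(p, frequency, amplitude, background)
        period = 1000.0 / frequency
        window = (10 * period, 40 * period)
        freq = measure_frequency(train, window)
        vp = mean_peak(train, window)
    else:
        if g_na_max is None:
            g_na_max = calibrate_steady_gnamax(params, background)
        p = params.with_g_na_max(g_na_max)
        tally, train = entry_for_steady(p, background)
        freq = measure_frequency(train, (25.0, math.inf))
        vp = mean_peak(train, (25.0, math.inf))
    return CostRecord(target_frequency=frequency, background=background,
                      pulse_amplitude=amplitude, g_na_max=g_na_max,
                      v_peak=vp, firing_frequency=freq,
                      na_total=tally.na_total, na_nav=tally.na_nav,
                      na_achr=tally.na_achr)


def cost_matrix(params: ModelParams,
                regimes: Optional[Sequence[Tuple[float, float, float]]] = None
                ) -> List[CostRecord]:
    """Cost-table rows for a list of (frequency, background, amplitude)
    regimes (default: the full 18-regime table).  Calibration failures are
    recorded as rows with nan entries rather than aborting the table."""
    if regimes is None:
        regimes = TABLE_REGIMES
    records = []
    for freq, bg, amp in regimes:
        try:
            records.append(cost_record(params, freq, bg, amp))
        except (RuntimeError, ValueError):
            records.append(CostRecord(freq, bg, amp, math.nan, math.nan,
                                      math.nan, math.nan, math.nan, math.nan))
    return records


def cost_fit_foldchange(points: Sequence[Tuple[float, float]]) -> float:
    """Fold change over 200 Hz predicted by an exponential fit to per-AP cost.

    Fits ``entry = A * exp(b * f)`` by unweighted least squares in log space
    to the (frequency Hz, total entry) points and returns ``exp(200 * b)`` --
    the fitted ratio between costs 200 Hz apart (e.g. 500 vs 300 Hz).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need at least two (frequency, entry) points")
    if np.any(pts[:, 1] <= 0):
        raise ValueError("entries must be strictly positive")
    b, _ = np.polyfit(pts[:, 0], np.log(pts[:, 1]), 1)
    return float(np.exp(200.0 * b))


def jar_sweep(params: ModelParams, center_frequency: float, g_na_max: float,
              deltas: Sequence[float] = (-10.0, -5.0, 0.0, 5.0, 10.0),
              amplitude: float = 1.0) -> List[Tuple[float, float]]:
    """V_peak across a band of AP frequencies at fixed g_na_max.

    Emulates a jamming avoidance response: the discharge frequency shifts by
    ~+-10 Hz with unchanged channel densities.  Returns (frequency, mean
    V_peak) pairs; raises RuntimeError if any frequency fails to entrain 1:1.
    """
    out = []
    for d in deltas:
        f = center_frequency + d
        r = pulsatile_response(params.with_g_na_max(g_na_max), f, amplitude)
        if not r.entrained:
            raise RuntimeError(f"no 1:1 entrainment at {f} Hz")
        out.append((f, r.v_peak))
    return out


def pulse_amplitude_scan(params: ModelParams, frequency: float,
                         amplitudes: Sequence[float], g_na_max: float
                         ) -> List[Tuple[float, float, "EntryTally"]]:
    """(amplitude, V_peak, entry tally) at fixed g_na_max across stimulus
    strengths -- shows that total Na+ entry is nearly amplitude-invariant
    while the AChR share grows."""
    p = params.with_g_na_max(g_na_max)
    out = []
    for amp in amplitudes:
        tally, train = entry_for_regime(p, frequency, float(amp), 0.0)
        period = 1000.0 / frequency
        vp = mean_peak(train, (10 * period, 40 * period))
        out.append((float(amp), vp, tally))
    return out
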