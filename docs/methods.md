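# Methods

## Model

The package models the innervated posterior membrane of an *Eigenmannia*
electrocyte as a single isopotential compartment (C = 50 nF):

    C dV/dt = −I_NaT − I_NaP − I_K − I_L + I_stim

Conductance currents are positive outward; the stimulus current (synaptic
GHK flux and/or injected current) is positive when depolarizing.  The two Nav
currents share m³ activation; a fraction γ = 0.02 of the Na conductance never
inactivates (persistent current).  Repolarization requires a delayed
rectifier (n⁴, gK_max = 2000 µS): it is retained as a necessary placeholder
even though its molecular identity in *Eigenmannia* electrocytes is
unsettled.  The leak (5 µS) reverses at E_K, so it carries no Na⁺ and the
per-AP Na⁺ budget is exactly the sum of the transient, persistent and AChR
pathways.

Gating rates are single exponentials α_j = k_αj·exp(η_αj·V) (and likewise
β_m, β_n).  The closing rate of inactivation uses the saturating law

    β_h(V) = 3.33 / (exp(−(V+30)/9) + 1)   [ms⁻¹]

chosen so that τ_h → 0.3 ms at strong depolarization, matching eel
electrocyte Nav kinetics; a non-saturating exponential would leave τ_h near
1 ms and too slow for 600 Hz firing.  The resulting activation curves have an
m³ midpoint of −28 mV and an n⁴ midpoint of −2.6 mV with slope 0.017 mV⁻¹,
and the model shows Class 1 excitability with an apparent firing threshold
near −45 mV under current clamp.

### Fixed reversal potentials vs. GHK concentrations

E_Na = 55 mV and E_K = E_L = −94 mV are fixed constants: the model assumes
perfect ion homeostasis and never recomputes them from concentrations.  The
ion concentrations ([Na]ᵢ = 13.5, [Na]ₒ = 120, [K]ᵢ = 89, [K]ₒ = 2.16 mM)
feed only the synaptic GHK pathway.  Temperature is set to 293.15 K, which
makes the K⁺ Nernst potential of those concentrations (−93.94 mV) agree with
the fixed E_K; the same choice gives Na⁺ Nernst = 55.19 mV and a two-ion GHK
reversal of +2.177 mV with P_K/P_Na = 1.11 — i.e. one temperature and one
[Na]ᵢ reproduce all three printed electrochemical anchors simultaneously.
(An intracellular Na⁺ of 1.35 mM would put E_Na near +116 mV and the AChR
reversal near +40 mV, inconsistent with everything else; 13.5 mM is the only
self-consistent reading, and it remains overridable in config.)

### Synaptic pathway

AChR channels pass Na⁺ and K⁺ by constant-field electrodiffusion:

    I_X = P_X·F·z·f(u)·([X]ₒ·e^(−u) − [X]ᵢ),   u = zFV/RT,
    f(u) = u / (1 − e^(−u))

evaluated in SI (P in m³/s, concentrations in mol/m³) and converted to nA;
with P_Na in mm³/s the net conversion prefactor is numerically F.  The sign
is chosen depolarizing-positive so the total enters the membrane equation in
the +I_stim slot.  The removable singularity at V = 0 is replaced by the
4-term Taylor series 1 + u/2 + u²/12 − u⁴/720 for |u| < 10⁻⁴; the two
branches agree to better than 10⁻¹² relative over 10⁻³ < |u| < 10⁻¹.

Activation is a dimensionless waveform ("syn_clamp") multiplying both GHK
currents: the standard pulse is a 0.05 ms linear rise, 0.200 ms plateau and
exponential decay (τ = 0.1 ms), restarting each period; backgrounds add to
pulses (the two components are specified separately and compose additively).
The tail is truncated at the period boundary — at τ = 0.1 ms the carried-over
amplitude is < e⁻¹⁰ even at 600 Hz, so cross-period summation is immaterial.

## Numerical scheme

The integrator is a fixed-step Strang-split exponential scheme, compiled
with numba:

1. gates advance dt/2 by exact exponential relaxation toward their
   equilibrium at the current voltage (Rush–Larsen), which is
   unconditionally stable;
2. the voltage advances dt by exponential Euler — the conductance currents
   are linear in V, so the linear part is integrated exactly; the GHK
   stimulus is treated as constant over the step with one
   predictor–corrector pass;
3. gates advance the remaining dt/2 at the new voltage.

Default dt = 0.5 µs, output sampled every 2 µs (well below the 10 µs
resolution needed to follow the stimulus rise).  Halving dt changes the
steady-state AP peak by ~1×10⁻⁵ mV (self-convergence test in the suite), two
orders below the 0.01 mV calibration tolerance.  The scheme was chosen over
an adaptive stiff solver because the stimulus waveform has kinks every
period (which force an adaptive method to restart constantly), because
fixed-step integration is bit-for-bit reproducible given identical options,
and because the compiled kernel makes the full protocol battery (hundreds of
multi-hundred-millisecond runs) run in seconds.  The kernel's physics
duplicates the reference `rhs`; a finite-difference consistency test and a
current-bookkeeping test (−C·dV/dt equals the signed current sum) tie the
two implementations together.

The resting state is found by reducing the fixed point to a 1-D root in V
(gates on their equilibrium curves) and solving with Brent's method on
(E_K, −85 mV), which isolates the stable rest (≈ −93.84 mV) from the
unstable threshold point near −71 mV; residual derivatives are required to
be < 10⁻⁹.

## Measurements

- **Spikes**: upward crossings of −20 mV followed by a local maximum, with a
  0.5 ms refractory lockout; V_peak is refined by a quadratic through the
  three samples bracketing the maximum (reported to 0.01 mV).
- **Firing frequency**: 1000 / mean inter-spike interval over a
  post-transient window; fewer than 3 spikes counts as non-firing.
- **Per-AP entry**: pathway currents are integrated (trapezoid on the sample
  grid) over an integer number of analysis windows and converted at
  1 nA·ms = 6.2415×10⁶ ions.  For pulsatile drive the windows are stimulus
  periods, discarding the first 5; for steady drive they are spike-midpoint
  windows after a 25 ms transient.  At least 20 steady-state APs are
  required; per-AP values are stationary to < 0.5% under window doubling.
- **Calibration**: bisection on gNa_max (to 0.5 µS) until the mean
  steady-state V_peak of a 1:1 entrained train is within 0.01 mV of the
  12.86 mV standard; failure to entrain counts as "below target".
- **Thresholds**: bisection (to 10⁻⁴) on the constant syn_clamp level, with
  firing defined as ≥ 3 spikes in a 500 ms post-transient window.  Because
  the system is Class 1 (period diverges at threshold), any finite window
  yields a slight upper bound: the default window reports 0.0095 where a
  longer one would edge toward 0.009.
- **Staircase**: amplitude grid of 0.005 over [0, 0.5] (noise-free, like the
  underlying model); locking plateaus are flagged where the output/input
  frequency ratio matches 1/k within 1% over ≥ 2 consecutive grid points,
  and the critical amplitude is the smallest grid point with 1:1 locking.
- **Cost table**: 18 reference regimes (pure pulsatile, subthreshold
  background at 80% of threshold with standard/reduced pulses,
  suprathreshold background firing at ~70% of target, pure steady) at 200,
  500 and 600 Hz.  The background levels are the printed regime definitions,
  taken as inputs; each row re-calibrates gNa_max for the standard peak.
  Using 75% or 85% of threshold instead of 80% changes V_peak by ≤ 0.01 mV
  and entry by ≤ 0.2% (regression-tested).
- **Cost fold-change**: unweighted least squares of log(entry) against
  frequency at 300/400/500 Hz; the reported statistic is exp(200·b), the
  fitted ratio between frequencies 200 Hz apart.

## Problem sizes

Protocol runs use 30–120 stimulus periods (50–600 ms of model time) with the
first 5–40 discarded as transient; calibration and threshold searches take
~12 bisection steps each.  These lengths hold every reported statistic
stable to well inside its stated tolerance (stationarity and
window-doubling tests) while keeping the full battery at desk scale.

## Scope and limitations

- Single compartment: no cable structure, no anterior membrane, no
  electrogenic pump current.  Ion homeostasis is assumed perfect (fixed
  E_Na/E_K); Na⁺ entry is an accounting proxy for pump demand, not a
  feedback variable.
- The synaptic drive is deterministic and noise-free; real quantal release
  would jitter both components, raising the pulse amplitude needed for
  reliable 1:1 firing above the noise-free critical amplitude and smearing
  the staircase plateaus.
- The standard pulsatile waveform is faster than any recorded electroplaque
  postsynaptic current; it is a conjecture about what 600 Hz triggering
  would require, not a measurement.
- Above ~650 Hz, 1:1 entrainment fails for any conductance in a generous
  range: incomplete recovery from inactivation between stimuli produces
  irregular amplitudes and timing.  Near that boundary per-AP statistics
  become sensitive to dropped spikes; the tallies here verify strict 1:1
  firing and per-period stationarity before reporting.
- τ_h in real electric-fish electrocytes increases again at very large
  depolarizations; this lies outside the physiological voltage range of the
  model and is not represented.
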