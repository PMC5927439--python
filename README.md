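# electrocyte

A conductance-based model of the excitable posterior membrane of the
*Eigenmannia* electrocyte — the cell whose synchronized action potentials
(APs) produce the fish's continuous 200–600 Hz electric organ discharge — and
the protocols needed to study the **energetics of sustained high-frequency
firing**: per-AP Na⁺-entry budgets by pathway, conductance calibration across
frequency, steady/pulsatile/mixed synaptic drive, entrainment staircases, and
jamming-avoidance sweeps.

It is written for computational neurophysiologists: a plain Python library
(`import electrocyte`) with narrative scripts in `examples/` and a thin
`electrocyte` command-line wrapper.

## The model

The membrane potential obeys

```
C dV/dt = −I_NaT − I_NaP − I_K − I_L + I_stim
```

with Hodgkin–Huxley currents (µS·mV = nA; C = 50 nF):

- `I_NaT = gNa_max · m³h(1−γ)(V−E_Na)` — transient Nav current,
- `I_NaP = gNa_max · m³γ(V−E_Na)` — persistent (non-inactivating) fraction γ = 0.02,
- `I_K = gK_max · n⁴(V−E_K)` — delayed rectifier (gK_max = 2000 µS),
- `I_L = g_L(V−E_L)` — leak (5 µS, E_L = E_K = −94 mV),

gates following `dj/dt = α_j(1−j) − β_j j` with single-exponential rate laws
(`α = k e^{ηV}`), except the sigmoidal β_h, which drives the inactivation
time constant to ~0.3 ms at depolarized potentials.  Synaptic activation of
nicotinic AChR channels is a Goldman–Hodgkin–Katz electrodiffusive Na⁺/K⁺
pathway (P_K/P_Na = 1.11, reversal ≈ +2.2 mV) scaled by a dimensionless
"syn_clamp" waveform — either the standard pulsatile shape (0.05 ms rise,
0.2 ms plateau, 0.1 ms decay), a constant background, or both.

The energetic bookkeeping: every Na⁺ ion entering the cell must be extruded
by the 3Na⁺/2K⁺-ATPase (1 ATP per 3 Na⁺), so the time integral of inward Na⁺
current per AP — split into Nav and AChR pathways — is a direct proxy for
the homeostatic cost of each discharge cycle.

## Worked example

```sh
python examples/na_entry_budget.py
```

```
freq   gNa_max   Na+/AP total   Nav     AChR   (1e9 ions)
 200 Hz     700         59.2    48.6    10.5
 600 Hz    1126         82.4    72.1    10.3
```

At 200 Hz, each AP admits 59.2×10⁹ Na⁺ ions (≈ 20×10⁹ ATP), 48.6 through Nav
channels and 10.5 through AChRs.  Holding the AP peak at the 12.86 mV
standard at 600 Hz requires raising gNa_max to 1126 µS (more Nav channels),
which drives the Nav share up ~50% — while the synaptic share is essentially
frequency-invariant.  That asymmetry is the model's central prediction: Nav
channel density should rise with discharge frequency, AChR density should
not, and the electrocyte AP itself is too cheap to explain the steep
whole-animal cost of high-frequency discharge.

Other examples: `single_action_potential.py` (the standard 200 Hz train),
`calibration_curve.py` (gNa_max vs frequency and the exponential cost fit),
`steady_drive_map.py` (Class 1 f–I curve under constant activation),
`devils_staircase.py` (sub-harmonic locking on a subthreshold background),
`jamming_avoidance.py` (±10 Hz sweeps at fixed conductance), and
`current_clamp.py` (step/ramp injection).

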