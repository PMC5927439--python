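"""Per-action-potential Na+-entry budget: the energetic cost proxy.

Every Na+ ion that enters during an AP must be pumped back out by the
3Na+/2K+-ATPase (1 ATP per 3 Na+), so the per-AP Na+ entry measures the
homeostatic cost of firing.  Entry is tallied separately for the voltage-gated
(Nav) and synaptic (AChR) pathways at 200 Hz and 600 Hz, each with the maximal
Na conductance calibrated to hold the standard 12.86 mV peak.
"""

from electrocyte import entry_for_regime, epm_default

params = epm_default()
print("freq   gNa_max   Na+/AP total   Nav     AChR   (1e9 ions)")
for freq, gna in ((200.0, 700.0), (600.0, 1126.0)):
    tally, _ = entry_for_regime(params.with_g_na_max(gna), freq, 1.0, 0.0)
    print(f"{freq:4.0f} Hz {gna:7.0f}   {tally.na_total:10.1f} {tally.na_nav:7.1f}"
          f" {tally.na_achr:7.1f}")
# The Nav share grows steeply with frequency (more channels are needed to keep
# the peak constant) while the synaptic share stays essentially flat.
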