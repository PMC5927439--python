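"""Sub-harmonic locking of weak pulses on a subthreshold background.

200 Hz pulses riding on a just-subthreshold constant activation (0.00736,
80% of threshold) entrain the membrane at rational fractions of the stimulus
frequency.  Sweeping pulse amplitude traces a devil's staircase: plateaus at
200/k Hz, with full 1:1 entrainment above a critical amplitude (~0.32).
"""

import numpy as np

from electrocyte import epm_default, staircase

params = epm_default()
amps = np.arange(0.02, 0.40 + 1e-9, 0.01)
res = staircase(params, background=0.00736, pulse_frequency=200.0,
                amplitudes=amps)

print("amplitude  output frequency")
for a, f in zip(res.amplitudes, res.frequencies):
    bar = "#" * int(f / 5)
    print(f"  {a:5.2f} {f:9.1f} Hz  {bar}")
print(f"\ncritical amplitude for 1:1 firing: {res.critical_amplitude}")
for ratio, lo, hi in res.plateaus:
    print(f"locking at {200 * ratio:6.1f} Hz over amplitudes [{lo:.2f}, {hi:.2f}]")
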