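"""Classic current-clamp protocols: sustained step and ramp injection.

Reproduces the bench protocol on the model: a 40 ms constant-current step
elicits a tonic AP train whose rate grows with intensity; a 40 ms ramp to
2400 nA sweeps the firing rate upward within the train.
"""

import numpy as np

from electrocyte import (CurrentClampDrive, StimulusRegime, detect_spikes,
                         epm_default, integrate, measure_frequency)

params = epm_default()

print("40 ms current steps:")
for amp in (200.0, 400.0, 800.0, 1600.0):
    drive = CurrentClampDrive(kind="step", amplitude=amp, duration=40.0)
    traj = integrate(params, StimulusRegime(clamp=drive), 50.0)
    train = detect_spikes(traj)
    freq = measure_frequency(train, (0.0, 40.0))
    print(f"  {amp:6.0f} nA -> {len(train):2d} spikes, {freq:5.0f} Hz")

drive = CurrentClampDrive(kind="ramp", amplitude=2400.0, duration=40.0)
traj = integrate(params, StimulusRegime(clamp=drive), 45.0)
train = detect_spikes(traj)
isi = np.diff(train.times)
print(f"\n40 ms ramp to 2400 nA: {len(train)} spikes; instantaneous rate "
      f"{1000 / isi[0]:.0f} -> {1000 / isi[-1]:.0f} Hz")
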