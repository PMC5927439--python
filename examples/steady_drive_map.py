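"""Firing under constant synaptic activation: threshold and f-I curve.

A constant (0 Hz) syn_clamp level can also drive repetitive firing.  The
membrane is Class 1 excitable: firing starts at arbitrarily low rates just
above a threshold level and accelerates smoothly with intensity.
"""

from electrocyte import epm_default, steady_response, steady_threshold

params = epm_default()
thr = steady_threshold(params)
print(f"firing threshold: constant syn_clamp ~ {thr:.4f}\n")
print("level    frequency    V_peak")
for level in (0.03, 0.05, 0.1, 0.2, 0.4):
    freq, vpeak, _ = steady_response(params, level)
    print(f"{level:5.2f} {freq:9.0f} Hz {vpeak:8.1f} mV")
# Frequency spans the whole species range (and beyond) but the AP amplitude
# droops at high intensity unless gNa_max is raised.
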