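"""The two-stage clock-drift correction, rung by rung.

A static device is rendered for two minutes with a 40 ppm relative clock
offset between the panel and the wearable.  Without synchronization the
apparent height drifts at c * 40e-6 = 1.37 cm/s; beacon alignment removes
almost all of it; the chunked-regression post-processing takes out the
jitter-limited residual.
"""

from acuheight.evaluate import drift_ladder

out = drift_ladder(seed=5, duration=120.0)
print(f"{'regime':<22}{'max |drift| (cm)':>18}{'final |drift| (cm)':>20}")
for name, res in out.items():
    print(f"{name:<22}{res['max_abs_cm']:>18.3f}{res['final_abs_cm']:>20.4f}")
print()
print("Uncorrected drift grows at ~1.37 cm/s (the closed-form c*dppm*t);")
print("beacon sync leaves a sub-ppm residual set by reception jitter, and")
print("the 30-s-chunk regression brings the accumulated drift to ~0.")
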