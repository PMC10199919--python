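"""End-to-end clinical-protocol analogue: bed steps and MAP correction.

The device is calibrated at the panel, attached 1.5 m under it, and the
bed is stepped up in 5 cm increments (three levels here to keep the
example quick; dwells stay at the clinical tens-of-seconds scale because
the residual-drift regression assumes motion is sparse in time).  The
tracked height change corrects the stationary transducer's mean arterial
pressure; with perfect correction the MAP error would be zero at every
bed height.
"""

from acuheight.evaluate import bed_session_eval

out = bed_session_eval(seed=3, levels_cm=(0, 5, 10), dwell=45.0,
                       device_noise_sd=0.0)
tab = out["plateaus"]
print(f"delta_transducer = {out['delta_transducer']:+.2f} mmHg "
      "(baseline inter-transducer offset, removed by the normalization)")
print()
print(f"{'bed level':>10}{'dh true':>9}{'dh est':>9}{'dh err':>9}{'MAP err':>10}")
for _, r in tab.iterrows():
    print(f"{r.level_cm:>8.0f} cm{r.dh_true_cm:>7.1f}cm{r.dh_est_cm:>7.1f}cm"
          f"{r.dh_err_cm:>7.2f}cm{r.map_a_minus_truth_mmhg:>8.2f}mm")
print()
print("Each centimetre of uncorrected height error would bias the pressure")
print("by 0.735 mmHg; sub-0.5-cm height errors keep the corrected MAP well")
print("inside 1 mmHg of the true arterial pressure.")
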