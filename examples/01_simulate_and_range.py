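"""Render a static scene and recover the per-speaker distances.

A device hangs 1 m under the speaker panel; the simulator renders what its
microphone records (three time-shifted 18-22 kHz chirps plus noise), and
the two-step ranging pipeline reads the per-speaker distances back out of
the FMCW beat phase.
"""

import numpy as np

from acuheight import (
    ChirpConfig, SpeakerArray, AcousticScene, Trajectory, render_received,
    track_distances, TimeMapping,
)

cfg = ChirpConfig()          # 18-22 kHz, 43 ms chirps at 50 kHz
array = SpeakerArray(L=0.1)  # 10 cm square panel, 3 active speakers

scene = AcousticScene(
    array=array, cfg=cfg,
    trajectory=Trajectory.static([0.0, 0.0, 1.0]),
    noise_snr_db=20.0,
)
res = render_received(scene, duration=2.0, seed=1)
track = track_distances(res.wave, TimeMapping.identity(cfg.fs), cfg, array)

true_d = array.distances(np.array([0.0, 0.0, 1.0]))[:3]
est_d = track.d_tilde[5:].mean(axis=0)  # skip warm-up frames

print(f"rendered {len(res.wave)} samples, {len(track.t)} chirp frames")
for j in range(3):
    print(f"speaker {j}: true {true_d[j]*100:7.3f} cm   "
          f"estimated {est_d[j]*100:7.3f} cm   "
          f"error {abs(est_d[j]-true_d[j])*1000:5.2f} mm")
print("Sub-millimetre errors show the phase readout resolving far below")
print("the ~8.6 cm resolution of the raw beat spectrum.")
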