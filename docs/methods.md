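# Methods

This note documents the models inside `acuheight`: what the simulator
generates, how each processing stage works, the numerical choices that
were genuinely open, and what the synthetic results do and do not say
about real hardware.

## Signal model and geometry

Each of three active speakers on a square panel (side `L`, z = 0 plane,
z pointing at the patient) plays the same periodic linear chirp
(`f0 = 18 kHz`, `f1 = 22 kHz`, `T = 43 ms`, `fs = 50 kHz`), delayed by
`i·shift_fraction·T` (default `T/5`). The complex analytic chirp is the
internal representation; WAV export takes the real part. Multiplying a
received frame by the reference chirp maps a path delay `t_d` to a beat
tone at `(B/T)·t_d` (so the speakers occupy disjoint 800 Hz slots) whose
complex amplitude carries the conjugated dechirped phase
`φ(t) = −2π(B/T·t·t_d + f0·t_d − B/(2T)·t_d²)`.

**Speaker separation.** `L` is configurable; the default is **0.10 m**.
The far-field height formula `Z = √(d̄² − X² − Y²)` carries a geometric
bias because d̄ averages distances to the corners rather than to the
panel centre: `d̄² ≈ z² + L²/2 + cross-terms`, i.e. a height bias of
roughly `L²/(4z)`. At `L = 0.1` this is 0.25 cm at 1 m and ~1.3 cm at
0.2 m — consistent with a sub-centimetre median over the 0.2–2 m working
range. A 0.2 m panel would double-to-quadruple these biases and was
rejected for the default on those grounds. The speaker corner ordering
is chosen so the difference pairs `(d1−d2)` and `(d1−d3)` carry the sign
of the device's true x and y.

## Scene simulator

The simulator evaluates the analytic chirp phase at the exact
(continuous) emission time of every receiver sample, so fractional
delays are exact — there is no sample rounding anywhere in the forward
model (1 cm is only ~1.46 samples at 50 kHz).

* **Clocks.** The transmitter's chirp bank runs on a clock with
  fractional error `ppm_tx·1e-6`; the receiver's ADC samples at
  `fs·(1+ppm_rx·1e-6)`. Both devices keep free-running 16 MHz timers
  wrapping at 800 000 ticks (20 Hz). Beacons are emitted at 200 Hz of
  the transmitter clock carrying its tick count; the receiver latches
  its own timer on arrival with Gaussian latency jitter
  (`beacon_jitter_sd`, default 50 µs — BLE interrupt-latency scale) and
  both values quantize to whole ticks (62.5 ns).
* **Paths.** The direct path per speaker follows the trajectory; body
  reflections are parametrized by an excess path length (they ride with
  the device) and a scalar amplitude. Construction enforces the
  direct-path-dominance constraint (summed reflection amplitude below
  the direct amplitude) outside scripted occlusion windows. Clothing is
  a scalar dB attenuation of the direct path; occlusion windows multiply
  the direct amplitude by a factor for an interval.
* **Noise.** White Gaussian, scaled so that the *mean per-speaker
  direct-path power* over the noise power equals `noise_snr_db`.
* **Trajectory.** Piecewise linear knots (cosine ramps are emitted as
  dense knots), plus a sinusoidal chest-motion term (`respiration_amp`
  is the peak-to-peak z excursion, default rate 0.25 Hz). The
  accelerometer stream is the finite-difference z acceleration at 50 Hz;
  the motion flag is `|az| > 0.05 m/s²` (chest motion at 0.5 cm
  peak-to-peak stays below it, bed transitions exceed it).
* **Pressures.** The clinical transducer reads the true MAP; the
  stationary transducer adds `0.735·Δh_true` plus a per-session
  inter-transducer offset (drawn N(0.8, 1.9²) mmHg when not specified)
  and optional per-reading device noise (default sd 0.5 mmHg ≈ a ±1 mmHg
  device spec). Beat-to-beat physiologic MAP variability is
  piecewise-constant per beat (default sd 1.5 mmHg) and common to both
  transducers, as it is in a two-transducer rig fed by one artery.

What the simulator does **not** contain: room reverberation beyond the
explicit path list, spherical spreading or air absorption (amplitudes
are free parameters), Doppler within a chirp (device speeds are cm/s),
speaker/microphone frequency responses, and Bluetooth packet loss.
Passing tests therefore demonstrate the *algorithms* under controlled
multipath/noise/drift, not performance in any particular room.

## Ranging pipeline

Per frame (segmented on the beacon-aligned timeline; the localizer knows
its own transmit schedule, and the sub-sample segmentation residual is
folded back into the recovered delay):

1. **Dechirp + separate.** One FFT of frame × reference chirp. During
   acquisition each speaker's peak is taken by argmax in its base slot;
   the sub-bin offset uses the complex-ratio (three-bin) estimator,
   which is asymptotically unbiased for a rectangular-window tone — a
   log-parabola fit is biased by ~0.1 bin, which is already enough to
   mis-pick the phase unwrap count. Because a far-shifted speaker's slot
   tone is split by the in-frame wrap into two phase-incoherent
   segments, the acquisition coarse delay is refined on the contiguous
   post-gap segment of the *shift-aligned* dechirp, where the tone is
   clean and near DC.
2. **SNR estimate.** Mainlobe (3-bin) power against the mean noise
   floor taken from the quiet band just above the beat slots, converted
   to the per-speaker time-domain SNR (the ~33 dB FFT processing gain is
   divided out, so the report matches the rendered scene SNR).
3. **Adaptive band-pass.** Linear-phase FIR (firwin), passband 4
   frame-rate bins around the beat, group delay 15 ms for SNR > 10 dB
   and 30 ms otherwise (1501/3001 taps at 50 kHz). In the tracker the
   taps are wrapped modulo the frame length and applied as circular
   convolution — exact for the frame-periodic chirp bank and already
   zero-phase, so no separate group-delay compensation is needed. The
   stand-alone `adaptive_bandpass` applies ordinary linear convolution
   with explicit compensation.
4. **Phase → time of flight.** The filtered component is evaluated at
   the midpoint of the post-arrival span `[t_d', T]` (this reduces to
   `t = T/2` for small delays; a fixed `T/2` readout would land *before*
   the arrival for far speakers). The dechirped-phase quadratic is
   solved per candidate unwrap count and the in-range root nearest the
   anchor is kept.

**Tracking discipline.** The method measures *relative* distance change
from a calibrated start, so the unwrap count is carried frame to frame
with a constant-velocity prediction (capped at 25 µs/frame ≈ 0.2 m/s).
Three safeguards keep the chain honest, each added against a concrete
observed failure mode:

* Once locked, the band-pass is centred on the *predicted* beat rather
  than the per-frame spectral argmax — during motion a body reflection
  can intermittently capture the argmax and hijack the chain.
* A measurement further than 30 µs (~1 cm) from the prediction is
  rejected (frame invalid, value held), so one wrong unwrap cannot seed
  the self-consistent runaway branch aliased by one ambiguity step
  (~50 µs) per frame.
* Sustained rejections while a healthy tone sits near the prediction
  (≥ ~1 s at > 12 dB) mean the geometry really changed (e.g. motion
  during occlusion); the chain re-acquires from the coarse peak. Low-SNR
  rejections (true occlusion) never re-acquire — values hold and frames
  stay flagged invalid.

A post-pass (`repair_cycle_slips`) re-levels any residual per-speaker
steps at whole multiples of the ~1.7 cm ambiguity that the other
speakers do not share (the cycle-slip repair familiar from carrier-phase
tracking); with the predictive tracker it is rarely triggered but is
kept as defence in depth.

## Calibration

`D_i` is the mean raw reading minus the true geometric distance with the
device held at a known reference spot (default 5 cm on-axis from the
panel). Any constant per-speaker bias — speaker latency, and crucially a
constant unwrap offset acquired under multipath — is absorbed here,
which is why the tracker only needs unwrap *continuity*, not absolute
correctness. Calibration is rejected if the accelerometer flags motion.
The benchmark scenes place the device at the reference spot with a
2 mm/axis Gaussian placement error: at the 5 cm stand-off the speaker
directions diverge strongly, so placement error decorrelates across
speakers and (amplified by d̄/L) dominates the lateral x/y errors, which
is why height errors are the smallest of the three axes — the panel is
perpendicular to the height axis.

## Time synchronization

Stage 1 (`beacon_align`) unwraps both tick series, normalizes the
initial offset modulo the 50 ms wrap period (a wrapping timer only
defines offset mod its period; a first tick straddling the boundary must
not shift the timeline by a wrap), and fits receiver time on transmitter
time by OLS over an initial sync window (default 10 s). The slope is the
drift factor α usable by `resample_with_drift` (a chirp-z evaluation of
the frequency-scaled inverse transform, signed frequencies, identity at
α = 1 to transform round-off). Modelling sync as one-shot offset+rate
leaves a jitter-limited sub-ppm rate residual — the "sampling and
precision limits" that motivate stage 2; continuous per-beacon
correction would leave nothing for the regression stage to do in a
simulator with perfectly constant ppm.

Stage 2 (`estimate_residual_drift` / `postprocess_drift`): trailing
300 s window, 30 s chunks, OLS per chunk, rank by residual sum of
squares, mean slope of the lower `floor(n/2)` chunks. Chunks with fewer
than 10 samples or spanning under 90% of the chunk length are discarded;
fewer than two usable chunks yields a flagged zero-correction estimate.
The offline pass re-estimates every 30 s on the corrected history and
anchors corrections at the series start (retroactively for the warm-up
span), applied per-speaker in the distance domain; the equivalent
sampling drift factor is `α = 1 + slope/c`. The estimator assumes motion
is *sparse* (under half of any 5-minute window) — it is robust to 40%
corrupted chunks, but a staircase with dwells shorter than the chunk
length would be partly absorbed as drift, so bed-session dwells belong
at the clinical tens-of-seconds scale.

## IMU gate

Idle (no accelerometer motion): the reported height is held regardless
of the acoustics. Motion switches to active tracking; the gate returns
to idle only when motion has ended and the last 2 s of *valid* frames
are dense (≥ 80%) and quiet (sd < 0.3 cm), taking the window mean as the
new held height. Occlusions of a stationary device therefore cannot move
the output at all, and an occlusion that overlaps a height change keeps
the tracker active until the estimate stabilizes after it clears.
Invalid stretches longer than 5 s are flagged unreliable in the output.

## Pressure correction

`MAP = MAP_s − 0.735·Δh + Δtransducer`, with 0.735 mmHg/cm treated as a
fixed blood-column constant and Δtransducer the baseline-window mean
difference between the clinical and stationary transducers. Computation
is full precision; only the reporting layer rounds, decimal-half-up to
0.1 mmHg (clinical convention — 7.35 prints as 7.4). Only the mean
pressure is corrected; systolic/diastolic extremes are also shaped by
waveform damping, which a height model cannot address.

## Power model

`life = capacity / (duty·I_active + (1−duty)·I_idle)` with 6 mA active,
17.53 µA idle. The coin-cell capacity is a parameter (default 220 mAh —
the published active and idle endpoints imply slightly different
capacities, ~216 vs ~225 mAh, so both are treated as approximate).

## Benchmark suite sizes

The standard runs (used by the tests and the acceptance script, sized to
finish in tens of seconds to a few minutes each): 100 static scenes of
~4–25 s (calibration dwell 1.5 s, hand-carry at 0.10 m/s — comfortably
inside the tracker's 0.2 m/s velocity envelope — and a 2 s test dwell);
one 600 s drift scene processed three ways; one 10-plateau bed session
with 45 s dwells and 1.5 s cosine transitions. Randomness is seeded
per scene (`default_rng([seed, index])`); identical seeds give
bit-identical outputs.

## Known limitations

* The update rate is the chirp rate 1/T ≈ 23 Hz; overlapping frames
  could raise it but are not implemented.
* The residual-drift stage corrects each `d_i`; correcting Z directly is
  algebraically equivalent to first order but not exposed as a switch.
* Re-acquisition after a genuine geometry change restores tracking but
  may land on a different unwrap offset under strong multipath; the
  IMU-gated output and cycle-slip repair bound, but do not eliminate,
  the resulting centimetre-scale risk.
* The far-field `Z` bias (~`L²/4z`) is inherent to the triangulation
  formulas; height *changes* cancel it to ≲2 mm per 5 cm step over the
  working envelope, which is what the pressure correction consumes.
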