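# Methods

This note documents the models, conventions, and numerical choices behind
`stepkit`: what each detector computes, what the synthetic gait generator
does and does not emulate, and where the design was genuinely open.

## Preprocessing

Every detector consumes the same chain applied to the 3-axis accelerometer:

1. **Magnitude** `‖a‖₂` per sample — removes dependence on sensor
   orientation, so no calibration or coordinate alignment is required.
2. **Savitzky–Golay smoothing**, polynomial order 3, window given in seconds
   and converted to samples as `round(window_s × rate)`, incremented to odd
   (the filter requires odd windows). Order 3 reproduces cubic trends
   exactly, so peak amplitudes and locations survive smoothing — the reason
   this filter is preferred over a conventional low-pass for event timing.
   The order is exposed as an advanced argument.
3. **Median subtraction** — isolates the dynamic component. The median is
   used rather than the mean because step transients are exactly the kind of
   high-amplitude outlier that biases a mean.

Smoothing precedes median-centring; the two operations commute up to filter
edge effects, so the order is a convention, fixed for determinism.

Units are normalized at the I/O boundary: acceleration m/s² (×9.80665 when a
file declares g), angular rate deg/s (×180/π from rad/s), time in seconds
from recording start.

## Detectors

**Peak Detection.** Local maxima of the preprocessed magnitude with three
constraints: point-wise height above a rolling threshold (centred 2 s rolling
standard deviation × multiplier 0.5 — the rolling window shrinks at the
edges rather than padding), prominence ≥ 0.2, and minimum separation 0.35 s.
The point-wise (rather than global scalar) threshold was chosen because it
lets sensitivity adapt within a recording: quiet segments get a low bar,
high-activity segments a high one, and a perfectly quiet recording yields no
detections at any amplitude scale.

**Zero-Crossing.** A hysteresis state machine on the centred signal: a step
requires an excursion above +0.3 m/s² followed by one below −0.3 m/s². The
step timestamp is the negative-going zero crossing between the two
excursions, linearly interpolated between samples. Detections closer than
0.4 s to the previous one are suppressed, but the state machine itself keeps
running, so a suppressed cycle cannot desynchronize subsequent cycles.

**Spectral Analysis.** Power spectrogram with Hann windows of 8 s and 80 %
overlap. Per window, the dominant frequency is the in-band (0.8–2.0 Hz)
power argmax refined by parabolic interpolation of log-power over the three
bins around the maximum; the refined value is clamped to the band. The
refinement matters: at 100 Hz and 800-sample windows the raw bin width is
0.125 Hz, and the final count multiplies the frequency estimate by the full
recording duration, so bin-level quantization alone would shift a 20 s count
by a whole step. With interpolation the estimate is accurate to a few mHz
for clean periodic gait. Cadence is the median of per-window dominants
(robust to occasional windows dominated by artifacts); windows whose in-band
power does not exceed an absolute floor (10⁻¹², guarding numerically silent
recordings) contribute nothing. Count = round(cadence × duration), rounding
half away from zero; step times are the midpoints of `count` equal bins —
the method estimates a rate, not event times, so any placement is a
convention and midpoints make that explicit. Recordings shorter than the
window are analysed as one full-length window and flagged.

**Adaptive Threshold.** Phase 1 collects *all* local maxima. Each
candidate's amplitude is its height above the minimum within a centred 0.8 s
window; candidates below 10⁻⁶ m/s² are discarded outright (otherwise an
exactly constant signal promotes float-rounding ripples into candidates).
The retention threshold is 0.5 × the mean candidate amplitude. Retained
peaks are thinned to 0.4 s spacing keeping the larger amplitude, ties to the
earlier peak — a deterministic rule that favours the stronger of two
conflicting events.

**SHOE.** Accelerometer and gyroscope magnitudes are smoothed and min–max
normalized to [0, 1]; the combined signal is 0.7·accelₙ + 0.3·gyroₙ. A
sliding 0.3 s window is stance when

```
1000 · var(combined) + 10 · mean(gyroₙ)  <  9.0
```

This statistic encodes the two-condition stance definition (low acceleration
variance *and* low angular rate) against the single published threshold 9.0;
the two scale factors map the dimensionless variance and mean onto that
threshold's scale and are exposed as parameters because the mapping is a
convention of this implementation, not an identity. One step is registered
per transition into stance (stance onset), thinned to 0.35 s. SHOE uses its
own smoothing default of 0.2 s — shorter than the other detectors — because
stance/swing contrast lives at sub-cycle timescales and a 0.5 s window
smears the normalized gyro plateau onto the threshold knife-edge.
When the recording has no gyroscope, or no window classifies as stance
(typical away from the foot, where the sensor never rests), the detector
falls back to peak picking on the combined signal and flags the result.

### Output contract

All detectors return strictly increasing step times inside the recording
span, carry the exact parameter set used, and are deterministic: no detector
uses randomness, and none mutates its input.

## Evaluation

Matching is greedy leftmost one-to-one pairing of the two sorted time lists
under a ±0.3 s window (the default tolerance absorbs the 100–200 ms human
reaction delay of manual annotation). For a uniform window on a line this
greedy scheme attains maximum matching cardinality; the test suite verifies
that against exhaustive search on random instances. Precision, recall, and
F1 use the 0/0 → 0 convention so degenerate outputs score zero instead of
crashing batch runs. Per-recording F1 values are averaged across trials when
aggregating (pooled counts can be recomputed from the stored TP/FP/FN via
`prf` if preferred).

The plausibility screen classifies a step count as credible when it falls in
an inclusive range, 4–20 by default — sized for a Timed Up and Go trial,
where the lower bound catches near-zero detector failures and the upper
accommodates short strides over the ~6 m walked. Summaries use nearest-rank
percentiles so that summaries of integer counts remain observed integers.
Bilateral consistency reports mean and sample SD (n−1) of |left − right|
counts over paired sensors; a single pair yields SD 0 with a warning.

## The synthetic gait generator

The generator produces 9-axis recordings with exact ground-truth heel-strike
times. It emulates the *morphological* features that distinguish mounting
sites, not biomechanics:

- **Step times** sit on a cadence grid (default 1.6 Hz, the dominant
  frequency of comfortable walking) with non-accumulating Gaussian jitter,
  SD 2 % of the period truncated at 10 % — consecutive steps therefore stay
  ≥ 0.8 periods apart and the grid phase never drifts.
- **Ankle**: a biexponential impact transient at each heel strike (rise
  15 ms, decay 80 ms, amplitude 1.0 m/s²) riding on a swing oscillation
  (1.5 m/s² at the cadence, with a small phase lead — the limb decelerates
  into contact); **upper arm**: the pendulum-like sinusoid alone;
  **wrist**: the sinusoid plus sporadic gesture artifacts; **thigh**: an
  attenuated transient (0.6 m/s²) plus sinusoid. The dominant dynamic
  component rides on the gravity axis so the magnitude reflects it nearly
  linearly; a small half-cadence lateral sway adds realism.
- **Gyroscope**: flat-topped swing bursts with smoothstep ramps, near zero
  in a stance window (35 % of the period) centred on each strike; the
  recording opens and closes mid-swing so the first and last stance entries
  are genuine transitions.
- **Scenarios**: stair descent scales amplitudes 1.35× vs 0.85× for ascent
  (gravitational assistance); jogging doubles amplitude and shortens stance;
  stairs-combined switches amplitude at the midpoint. The TUG scenario
  chains sit → stand-up transient → walk bout → turn (strong rotation,
  sub-band sway) → walk bout → sit-down, with ground truth only inside the
  walking bouts and defaults giving a 10–15 s trial with 10 steps.
- **Noise**: white Gaussian acceleration noise (default SD 0.1 m/s², a
  realistic consumer-IMU-plus-soft-tissue level) with proportional gyro
  noise and 5 % per-step amplitude variation. Wrist gesture artifacts are
  part of the noise model and appear only when noise is enabled, so the
  noiseless configuration is a clean identifiability fixture.

All waveform constants live in one config block (`MORPHOLOGY`,
`SCENARIO_MODS`) and were fixed once, during generator development, so that
each mounting matches its qualitative description and clean gait is
recoverable by design; they are data of the simulation, not fitted
quantities.

**What passing tests on synthetic data do and do not show.** Noiseless
parameter recovery (F1 = 1.0 for the four event/frequency detectors across
mountings and cadences 0.9–2.0 Hz) demonstrates correctness of the
implementations — each algorithm recovers exactly the events the generator
planted under its own assumptions. It does not predict field accuracy: real
gait has variable cadence, asymmetry, soft-tissue artifact structure, device
mis-mounting, and annotation error, none of which the generator models.
The TUG fixture shows the *direction* of the spectral detector's failure
(systematic over-counting on intermittent activity); clinical magnitudes
will differ.

## Numerical and degenerate-input conventions

- Rolling statistics use centred windows that shrink at signal edges.
- Min–max normalization of an (effectively) constant channel returns zeros.
- A recording with a single sample is valid for detection (trivially zero
  steps) but not for resampling.
- Resampling interpolates linearly onto `round(span × rate) + 1` points
  spanning the original time range inclusively.
- CSV output carries 9 significant digits; write → read round-trips are
  lossless to 1e-9 and byte-identical across repeated writes.
- Spectral count rounding is half-away-from-zero (`floor(x + 0.5)`).

## Known limitations

- The simulator is a morphology emulator: no inverse dynamics, no
  pathological gait models beyond amplitude/asymmetry knobs, no magnetometer
  content (channels carried through I/O but zero-information).
- SHOE's stance statistic is one defensible realization of a two-condition
  rule against a single threshold; other scale choices are expressible
  through `ShoeParams` but change its operating point.
- The spectral detector's uniform step placement makes its step *times*
  nominal; only its *count* is meaningful for irregular gait.
- Adaptive Threshold has no absolute amplitude scale: on recordings that are
  pure noise its relative threshold keeps noise peaks, a known failure mode
  of the algorithm class (the plausibility screen exists to catch exactly
  this).
- No statistical comparison across algorithms is implemented (per-recording
  metrics and summary tables only).
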