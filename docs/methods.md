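# Methods

This note describes the signal model behind `gaitkit`, the numerical choices
made in each stage, what the synthetic generator does and does not emulate,
and the known limitations of the approach.

## Signal model

The pipeline estimates temporal gait parameters from a single sagittal-view
pose-estimation track. The input is a time series of 33 body landmarks per
frame (the common 33-point pose topology: nose, eyes, ears, shoulders,
elbows, wrists, hands, hips, knees, ankles, heels and foot indices), each
with image-normalized `(x, y)` coordinates, a depth estimate `z`, and a
visibility score in `[0, 1]`.

For each leg the pipeline computes the **forward hip-to-foot distance**

```
d(t) = direction * (foot_index_x(t) - hip_x(t))        [pixels]
```

where `direction` is `+1` when the subject walks toward increasing image
`x` and `-1` otherwise (inferred from the net displacement of the mid-hip
point). During stance the foot is planted while the hip advances over it,
so `d` decreases monotonically; during swing the foot overtakes the hip and
`d` rises again. Consequently:

* **heel strike (HS)** — the foot is maximally ahead of the hip — is a
  local *maximum* of `d`;
* **toe-off (TO)** — the foot is maximally behind — is a local *minimum*.

From the event sequence the temporal parameters are pure subtractions:

| parameter | definition |
|---|---|
| stance time | ipsilateral HS → next ipsilateral TO |
| swing time | ipsilateral TO → next ipsilateral HS |
| step time | contralateral HS → ipsilateral HS (named after the trailing leg) |
| double support (L2R) | right HS → left TO; R2L is the mirror |

A parameter is emitted only for *complete* cycles: the two defining events
must be adjacent in the per-leg (or merged, for double support) event
sequence with no intervening ipsilateral event. Incomplete cycles at the
ends of a recording are skipped and logged, never padded.

## Pipeline stages and parameter defaults

### 1. Missingness and visibility (`keypoints`)

A landmark sample is *missing* when the backend did not report it or its
visibility score falls below the **visibility floor (default 0.5)**.
Missing samples are stored as NaN and survive CSV/JSON round trips as empty
cells. The floor of 0.5 is the conventional midpoint of the score range:
below it the landmark position is closer to a guess than a measurement.

### 2. Gap filling (`preprocess.fill_gaps`)

Interior gaps are filled with a **cubic spline (not-a-knot boundary)**
through the valid samples. Cubic splines restore samples of any cubic
polynomial exactly and are the standard compromise between smoothness and
locality for marker trajectories. Leading and trailing gaps are **never
extrapolated**; the analysis window simply shrinks to the first and last
valid sample. At least 4 valid samples are required (the minimum for a
cubic). Gap filling operates on each landmark coordinate independently.

### 3. Low-pass filtering (`preprocess`)

Each trajectory is filtered with a **10th-order Butterworth low-pass**
applied in **zero-phase** (forward-backward) fashion, with a **normalized
cutoff of 0.1752 in fractions of the Nyquist frequency** (2.19 Hz at
25 fps). Rationale for the numerical choices:

* *Zero-phase application* (`scipy.signal.sosfiltfilt`) removes the
  filter's group delay. Event *timing* is the quantity of interest, so a
  phase-distorting single pass would bias every event late.
* The filter is realized as **cascaded second-order sections**, not as a
  transfer-function polynomial: a 10th-order Butterworth in `(b, a)` form
  is numerically ill-conditioned.
* Odd-symmetric edge padding with `padlen = 3 * order` suppresses start-up
  transients; the signal must therefore have at least `3 * order + 1 = 31`
  samples.
* Two passes square the magnitude response, so the effective gain at the
  cutoff is 0.5 rather than the single-pass 1/sqrt(2).
* The *cutoff convention* is explicit (`cutoff_convention="nyquist"`,
  matching `scipy`'s `Wn` convention at `fs=2`). A convention
  (`"fs"`) interpreting the same number as a fraction of the sampling rate
  is provided because this is a common source of silent factor-of-two
  errors between toolchains.

Filtering is performed on normalized coordinates; because both filtering
and the pixel conversion are linear, this is identical to filtering pixel
coordinates.

### 4. Event detection (`events`)

Candidate extrema are strict run-length-encoded local extrema of the
per-leg distance signal; a plateau is resolved to its first frame, and
samples at the very edges of the valid window are never candidates (an
edge sample cannot be verified to be a true local extremum). Candidates
are then filtered by two physiological thresholds:

* **amplitude floor** — peaks must reach **35% (left leg) / 46% (right
  leg)** of the global maximum, minima must reach **18%** of the global
  minimum. The left/right asymmetry compensates for the camera-side leg
  sweeping a larger image-plane amplitude than the far leg.
* **minimum separation of 0.8 s** between events of the same kind and leg
  (`round(0.8 * fps)` frames), slightly below the shortest plausible
  stride time for normal walking. Conflicts are resolved greedily in order
  of descending extremum magnitude (earlier frame on ties).

Optional parabolic sub-frame refinement of event times is available
(`subframe_refinement`), off by default so that reported event frames are
observed frames.

### 5. Parameters and agreement (`temporal`, `agreement`)

Parameter extraction is exact arithmetic on event times (see table above).
The validation module implements the standard method-comparison toolkit:

* greedy nearest-time **one-to-one event matching** within a tolerance
  (default 0.25 s, well under half a stride) giving true/false positives
  and signed timing errors (reference − test);
* mean error, sample SD, mean absolute error and range;
* pooled-variance independent-samples **t-test** (Welch optional),
  **Pearson's r**, and **ICC(2,1)** — two-way random effects, absolute
  agreement, single measure — computed from the ANOVA decomposition
  `ICC = (MSR − MSE) / (MSR + (k−1)MSE + (k/n)(MSC − MSE))`. Absolute
  agreement is the right form for comparing two measurement systems
  because it penalizes constant offsets, which "consistency" forms ignore.
* ICC categories: poor < 0.500 ≤ moderate < 0.750 ≤ good < 0.900 ≤
  excellent (boundary values fall in the higher bin).

Cycle-level agreement pairs cycles of the two systems by the start time of
their defining event (nearest-first within the matching tolerance), so a
missed cycle in one system cannot silently misalign all later cycles.

## The synthetic generator

`synthgait` produces keypoint series with *exact* ground-truth events, so
the whole pipeline can be validated without any external data.

**What it emulates.** A subject crosses the frame at constant hip velocity.
The hip-to-foot forward distance follows an idealized stride waveform:
during stance (fraction `duty_factor`, default 0.66, of the stride) the
distance falls *linearly* from `+A` to `−A` — exactly what a planted foot
under a constant-velocity hip produces, with `A = v * stance_time / 2` —
and during swing it returns from `−A` to `+A` along a smoothstep, which is
monotone and has zero slope at both ends. HS and TO are therefore *exactly*
at the constructed waveform corners, and the ground truth is written down,
not re-detected. The two legs are identical waveforms offset by
`step_phase_offset` (default 0.5) of a stride. Optional degradations:
isotropic Gaussian keypoint noise (`noise_sd_px`), random whole-frame foot
dropouts (`gap_fraction`), and between-subject stride-time jitter in
cohorts. Partial cycles at the sequence edges are real signal features and
are included in the ground truth.

**What it does not emulate.** Pose-estimator error is neither isotropic
nor white; real noise is autocorrelated and worse on the far-side leg.
There is no camera perspective, lens distortion, limb occlusion, depth
variation, gait asymmetry, within-subject stride variability, speed drift,
turning, or soft-tissue artifact. The waveform's sharp corners at HS/TO
are an idealization — real distance curves round off near the extrema.
Synthetic results therefore bound what the *algorithm* can do, not what a
camera system achieves in a clinic.

## Known limitations

* **Systematic stance shortening under the default filter.** The 10th-order
  zero-phase low-pass at 0.1752 Nyquist smooths the waveform corners and
  moves both extrema *into* the stance phase: on the default synthetic
  waveform the detected HS is ~15 ms late and the detected TO ~14 ms
  early, shortening every stance estimate by roughly 30 ms (and lengthening
  swing by the same amount). This is a bias of the method, not noise: it
  survives sub-frame refinement and does not average away. Step times are
  unaffected (the bias is common to both HS events of a step). A practical
  consequence: on a cohort whose true between-subject stance SD is small
  (≈0.05 s), this bias plus frame quantization caps the achievable
  per-subject stance ICC(2,1) near 0.85 — below the conventional
  "excellent" threshold — even though Pearson's r stays above 0.98. The
  corresponding acceptance test asserts the ≥0.90 target as specified and
  fails honestly.
* **Frame-rate quantization.** At 25 fps every event time is quantized to
  40 ms; single-event errors below half a frame are unresolvable without
  sub-frame refinement.
* **Sagittal-plane assumption.** Direction inference and the forward
  distance use image `x` only; walking toward the camera is out of scope
  (`AmbiguousDirectionError`).
* **Fixed thresholds.** The amplitude fractions and the 0.8 s separation
  assume normal adult walking; pathological or very slow/fast gait may
  need different settings (all are exposed in `EventDetectionConfig`).
* **No pose estimation included.** The package consumes keypoint files (or
  a user-supplied backend object); pose-model quality is outside its
  control and dominates real-world accuracy.

No empirical claim in this document goes beyond quantities computed by the
test suite or by `scripts/acceptance.py`.
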