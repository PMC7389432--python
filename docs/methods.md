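# Methods

## Problem and pipeline

`emgait` classifies each instant of a walking trial as stance or swing and
predicts the timing of heel-strike (HS) and toe-off (TO) from surface EMG
(sEMG) alone. The ground truth is the binary foot–floor-contact
("basographic") signal measured by foot-switches: 0 while the foot is on
the ground, 1 while it is airborne. The pipeline is:

1. **Envelope extraction** (`sigproc`). Raw sEMG is high-pass filtered at
   20 Hz and low-pass filtered at 450 Hz with linear-phase FIR filters
   (order 250, Hamming window, applied as a cascade with group-delay
   compensation), full-wave rectified, and smoothed with a second-order
   Butterworth low-pass at 5 Hz run forward and backward (zero net phase
   shift; effectively 4th-order magnitude). Each channel is then min–max
   normalized into [0, 1] within the subject.
2. **Windowing** (`windowing`). Each of the 10 channels is split into
   non-overlapping 20-sample windows (10 ms at 2 kHz); the ten synchronized
   windows are interleaved channel-fastest into one 200-sample vector. A
   window whose basographic samples are uniform is labeled stance/swing;
   windows containing a phase transition are masked — excluded from
   classifier training and accuracy, but still predicted when
   reconstructing the contact signal for event detection.
3. **Classification** (`model`). A multi-layer perceptron
   200–512–256–128–1 (ReLU between hidden layers, sigmoid output,
   label 1 iff output strictly > 0.5) trained with plain SGD
   (learning rate 0.01, batch 32) on binary cross-entropy, at most
   100 epochs. The chronological tail 10 % of the training sequence is the
   validation set; training stops once validation *accuracy* has not
   improved for 10 consecutive epochs and the best-epoch weights are
   restored. A single-hidden-layer 128-unit variant is available
   (`single_layer_variant`).
4. **Event extraction** (`events`). Window predictions are expanded back to
   a sample-rate binary signal. Any phase shorter than 175 ms
   (≈ 16 % of a typical gait cycle; 350 samples at 2 kHz) is merged into
   the preceding phase, scanning left to right until a fixed point; runs of
   exactly 175 ms are kept (strict inequality). HS is every 1→0 transition,
   TO every 0→1 transition; the event time is the first sample of the new
   phase, so timing resolution is one window (10 ms). Predictions are
   matched one-to-one to truth events of the same type within a strict
   tolerance T (default 600 ms; 50 ms as the strict variant), greedily in
   chronological order to the nearest unmatched truth event. Precision
   = TP/(TP+FP), recall = TP/(TP+FN), F1 their harmonic mean; MAE is the
   mean |t_g − t_p| over matched pairs in ms. Metrics with empty
   denominators are reported as missing (`None`/`null`), never as 0.
5. **Protocols** (`protocols`). *Intra-subject*: the window sequence of one
   subject is split into 10 contiguous slots; each fold trains on 9 slots
   and tests on the held-out slot (10-fold cross-validation over time, not
   over shuffled windows, so test strides are genuinely unseen).
   *Inter-subject*: leave-one-subject-out over a cohort. Group differences
   are tested metric-by-metric: Shapiro–Wilk on each group, then a
   two-tailed unpaired t test if both groups are compatible with normality
   at the 5 % level, otherwise Kruskal–Wallis; significance at p < 0.05.

## Synthetic data

Real recordings of this kind are not freely redistributable, so the
`synthdata` module generates walks with the statistical structure the
pipeline relies on:

- **Gait timeline.** Stride durations are drawn i.i.d. from a normal law
  (default 1100 ± 60 ms, truncated at ±3 SD — no negative or
  non-physiological durations); within each stride the stance phase
  occupies a fraction drawn around 0.60 ± 0.02, truncated to
  [0.45, 0.75] — the canonical ~60/40 stance/swing split of healthy
  walking. A 5-minute walk yields roughly 270 strides. The recording holds
  complete strides only (a final partial stride is dropped), so run-length
  decoding the basographic signal reproduces the truth events exactly.
- **Two legs.** The right leg walks half a cycle out of phase with the
  left, sharing the stride schedule but drawing independent stance
  fractions, as in contralateral gait.
- **Muscle activity.** Each channel's activation envelope is a sum of
  Gaussian bursts in cycle-fraction coordinates (truncated at ±3σ,
  wrapping at the cycle boundary), with defaults that mimic healthy
  activation timing: TA at loading response and mid-swing, GL in
  mid/terminal stance, MH in terminal swing and early stance, VL at loading
  response, RF at loading response and around toe-off. The raw-like signal
  is `(noise_floor + envelope) × carrier`, where the carrier is unit-
  variance zero-mean noise band-limited to 20–450 Hz (513-tap FIR); the
  default noise floor is 0.05 of the burst amplitude scale.
- **Cohorts.** `generate_population` jitters stride duration (relative SD
  8 % × heterogeneity), stance fraction (SD 0.03 × heterogeneity), burst
  centers (SD 0.05 cycle fractions × heterogeneity) and amplitudes
  (log-normal, SD 0.3 × heterogeneity) per subject. Heterogeneity 0 yields
  identical parameters (signals differ only through carrier noise);
  heterogeneity ≈ 0.5 produces between-subject timing differences larger
  than the within-subject stride-to-stride variability, which is what makes
  leave-one-subject-out measurably harder than within-subject
  cross-validation.

**What the simulator does not model**: motor-unit physiology, electrode
crosstalk and placement variability, fatigue and gait drift over the trial,
non-stationary walking (turns, accelerations), signal artifacts, and
sub-phases of stance. Synthetic subjects are also *easier* to classify than
real ones — activation is strictly phase-locked and noise is stationary —
so absolute accuracies here overstate what the pipeline would achieve on
real recordings; the tests establish correctness of the machinery and the
*direction* of protocol differences, not clinical performance levels.

## Numerical and design choices

- **FIR order 250** per filter (251 taps, type I): at 2 kHz this gives a
  ~26 Hz transition band and >50 dB stop-band attenuation with a Hamming
  window; an order knob is exposed. The high-pass/low-pass pair is applied
  as a cascade rather than a single band-pass design.
- **Zero-phase envelope**: `sosfiltfilt` with its default reflective edge
  padding; DC gain is exactly 1; tiny negative undershoots are clipped
  at 0.
- **Normalization bounds** are computed on the full recording
  (subject-level normalization, which also spans the test portion). Bounds
  can be supplied explicitly (`minmax_normalize(..., bounds=...)`,
  `preprocess_recording(..., bounds=...)`) to normalize on a training
  portion only; the default is subject-level.
- **Weight initialization**: He-style scaled uniform (±√(6/fan_in)) under
  the config seed; mini-batch order reshuffles each epoch under a stream
  derived from the same seed. Training is deterministic given the seed.
- **Validation split** is always the chronological tail of whatever
  sequence is being trained on: the last 10 % of the nine training slots
  (intra) or of the concatenated training subjects (inter). Validation
  improvement is strict (>); ties do not reset patience.
- **Spike-removal direction**: a too-short run merges into the *preceding*
  phase (the first run merges forward); the scan repeats until no run
  before the last violates the minimum. The trailing run is exempt, since
  a truncated final phase is not a spike. This rule is deterministic and
  validated against a brute-force oracle that re-encodes the raw sample
  array each pass.
- **Greedy event matching** (chronological, nearest unmatched truth event,
  strict |t_g − t_p| < T) coincides with the exhaustive optimal assignment
  when same-type events are about a stride apart and T ≤ 600 ms; the test
  suite asserts this equivalence on jittered gait-like instances. On
  adversarially close events the two can differ — such inputs do not arise
  from cleaned gait signals, where consecutive same-type events are at
  least two minimum-phase durations apart.
- **Slot boundaries** fall at window boundaries, not stride boundaries;
  a stride straddling a boundary contributes windows to both sides but no
  window is duplicated.
- **Per-fold seeds** are derived from the study seed with
  `numpy.random.SeedSequence([master, fold])`, so folds are independent
  but reproducible.
- **Train accuracy** is measured on the training windows themselves
  (including the validation tail), labeled as such in reports.

## Problem sizes used by the test suite and acceptance script

End-to-end checks run at desk scale: one 5-minute subject (≈ 30,000
windows, 10 folds, up to 30 epochs) for the intra-subject evaluation, and
a 5-subject cohort of 3-minute walks (heterogeneity 0.5, up to 8 epochs
with patience 3) for the intra-vs-inter comparison. These sizes keep a full
run in minutes on one CPU while leaving hundreds of strides per subject —
enough for the protocol contrast to be stable under the default seeds.

## Known limitations

- Event timing resolution is one window (10 ms); no sub-window
  interpolation is attempted.
- Events are scored per test slot in the intra protocol; an event whose
  truth lies just outside a slot boundary can count as a false positive or
  negative for that fold. With 30 s slots and ~1 s strides the effect on
  aggregate metrics is negligible.
- One model is trained per leg; reports cover the configured target leg
  (default left).
- The statistical comparison treats per-subject metrics as independent
  samples, as is conventional for cohort summaries.
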