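# Methods

## Problem setting

Three tri-axial accelerometers are mounted along the spine — sensor 1 at
L5/S1, sensor 2 at the thoracic/cervical transition (Th1/C7), sensor 3 on
the back of the head. The X axis points roughly cranial→caudal, Y
lateral→medial, Z ventral→dorsal. Subjects perform each exercise in two
forms: the clinically prescribed execution (CPE) and one typical
compensatory movement (TCM) per exercise — a longitudinal spine twist in
Prone-Rocking, an upward head tilt with lumbar extension in Bird-Dog, and a
rounded lower back (posterior pelvic tilt) in Bent-over Rowing. Each
(subject, category) performs 3 sets of 6 repetitions; a push-button channel
marks the set start and the end of every repetition. The classification
unit is the *set*.

## Synthetic-data generator

The generator produces recordings with the structure above so the pipeline
is verifiable without the original recordings. It is a *kinematic stand-in*,
not a biomechanical simulation: each sensor follows a parametric tilt
trajectory per repetition,

    phi(u) = baseline + amplitude * (1 - cos(2*pi*u)) / 2,  u in [0, 1],

projected through gravity onto the sensor axes (A_X = g sin phi, A_Z =
g cos phi, g = 9.81 m/s²; tilt is confined to the sagittal X–Z plane).
On top of this deterministic skeleton sit, in order:

* **Common oscillations** (both categories): small sinusoidal acceleration
  components (0.2–0.3 m/s²) that give every channel a movement texture.
  Every oscillatory term draws a fresh random phase and a frequency-jitter
  factor U(0.7, 1.3) per repetition, so repetition averaging attenuates it
  and its waveform shape varies between sets. This is what keeps
  scale-invariant shape statistics (skewness, kurtosis) noisy within a
  category: without it, any deterministic waveform difference between CPE
  and TCM would be picked up by shape statistics first, which real
  movement data do not support.
* **TCM effects** (TCM category only): per exercise,
  - Prone-Rocking: lateral oscillation on sensor-2 Y (1.6 m/s², 2
    cycles/rep) plus a weaker echo on sensor-1 Y (0.5 m/s²) — feeds
    `var_Y2`;
  - Bird-Dog: head-bob oscillation on sensor-3 Z (2.8 m/s²) plus a
    hollow-back postural tilt offset (+8°) applied to *all three* sensors
    — feeds `var_Z3` and shifts `phiRMS_1..3`. Applying the postural shift
    to every sensor reflects the whole spine extending and means it cancels
    out of the between-sensor tilt differences;
  - Rowing: an extra tilt excursion (+18°/rep) on sensor 1 only — the
    lumbar segment diverges from the upper back, feeding `maxdphi_1_2` —
    plus head Z activity (1.0 m/s², feeds `aRMS_Z3`).
  A global `effect_scale` multiplies all TCM amplitudes; at 0 the two
  categories are generatively identical (bit-identical for equal seeds,
  because effect phase parameters are drawn category-independently).
* **Subject profile** (drawn once per subject, shared by all their sets):
  a postural tilt offset common to all sensors (SD 3°) plus per-sensor
  mounting scatter (SD 1.5°); gravity leakage into Y from mounting roll
  (SD 0.6 m/s²); a log-normal movement-excursion factor (SD 0.30 on the
  log scale) multiplying all waveform amplitudes — the back moves as a
  unit, so single-sensor amplitude statistics are subject-confounded while
  tilt differences between sensors are not; a log-normal tempo factor
  (SD 0.10) and a log-normal TCM-magnitude factor (SD 0.20). A per-set
  excursion factor (SD 0.15) adds day-to-day variation. The rowing tilt
  divergence additionally scales with the subject's excursion factor.
* **Sensor front-end**: i.i.d. Gaussian noise (SD 0.15 m/s²), then
  quantization to 2¹² signed levels over ±4 g (the resolution is a study
  constant; the full-scale range is a configurable package choice) with
  clipping at full scale.

Repetition durations are i.i.d. log-normal with per-exercise means
(Prone-Rocking 3.0 s, Bird-Dog 4.0 s, Rowing 2.5 s — plausible tempi, not
reported values) and CV 0.15. Markers sit exactly at repetition boundaries
(operator latency 0); 0.25 s of static padding surrounds the set so every
marker falls on a recorded sample.

**What the generator does not emulate:** musculoskeletal dynamics and
inertial (non-gravitational) acceleration of the sensors, soft-tissue
artifacts, sensor orientation drift, operator marker latency, multiple
compensation patterns per exercise, and any overlap continuum between
"correct" and "compensated" execution beyond what the nuisance
distributions induce. Passing tests therefore demonstrate that the
*pipeline* is correct and well calibrated, not that the classifier would
reach the same accuracies on real patients.

## Preprocessing conventions

Repetition *i* spans the half-open sample interval [marker_i, marker_{i+1})
— no boundary sample is counted twice. The longest repetition of a set
defines the reference grid; the others are linearly interpolated onto it in
normalized time (averaging must happen in normalized time for sample-wise
means to be well defined). Re-normalizing an averaged set is a no-op.
Averaging across the six repetitions is the only outlier handling.

## Features

All moments are population moments (divide by N), consistent with the
z-score using the population SD; kurtosis is raw (normal → 3), matching the
moment-ratio definition k = E(n−n̄)⁴/σ⁴. The tilt angle is undefined for a
zero-norm sample; such samples propagate as missing and a set is rejected
when more than 1 % of its tilt samples are invalid. A constant series has
undefined skewness/kurtosis: both are set to 0 with a warning so degenerate
synthetic inputs do not abort a run. Tilt differences are signed (φ₁−φ₂,
φ₂−φ₃) before the maximum is taken. Features are computed on the averaged,
time-normalized set trace, not per repetition. Full mode: 5 stats × 9
channels + φRMS₁..₃ + max Δφ pairs = 50 columns; single-sensor mode:
5 × 3 + φRMS = 16.

Z-scoring is fit on the complete matrix by default. That convention leaks
test-set information into the scaling; a `train_only` mode re-scales each
cross-validation/LOSO fold with training statistics only and is provided
for leakage-free analyses. The default stays full-matrix because that is
the convention the pipeline reproduces.

## Feature selection

Deterministic greedy forward selection (the small numbers of evaluated
subsets reported for this procedure are only consistent with the
deterministic variant, not with random subset sampling). The loss is the
pooled misclassification rate over a stratified, seeded 5-fold partition
drawn once per selection run and reused for every candidate, so candidate
scores are comparable. The empty-model baseline is the minority-class rate.
Ties between candidates resolve to the lexicographically smallest feature
name. The cap of 5 features encodes the N_Sub ≤ N/2 rule with N = 36 taken
at face value; it is a configuration constant, not recomputed from fold
sizes. Degenerate partitions (a training fold with one class) are redrawn
with the next seed, at most 10 times.

Note an important interaction: running selection on a full matrix and then
evaluating the selected features by LOSO on the *same* matrix inflates the
LOSO estimate (the selector has seen the held-out subjects). On null data
(effect_scale = 0) this bias is ≈ +0.08 accuracy. The null-calibration test
therefore evaluates a fixed a-priori feature, and reported LOSO accuracies
after selection should be read as optimistic in the same way the original
procedure's are.

## Decision tree

Binary CART with Gini impurity G = 1 − Σ pₖ². Split candidates are the
midpoints of consecutive distinct sorted values ("all possible values" up
to the equivalence of thresholds between the same two data points);
ties in weighted child Gini resolve to the smallest threshold, ties across
features to the smallest feature name. A split is accepted only if it
strictly reduces the weighted child Gini. The one-use-per-feature rule is
global — a feature appears at most once in the whole tree, the stricter
reading; the left subtree consumes shared budget first, and a per-path
variant is available (`one_use="path"`). Leaves take the majority class;
exact ties go to CPE (do not flag compensation without evidence). At
prediction, `value < split` descends left, so a row exactly at the split
value goes right. TCM is the positive class for sensitivity — a convention,
chosen so that sensitivity measures the detection of compensation.

Greedy CART is not a global optimizer: on tiny adversarial datasets its
training loss can exceed the optimum over all one-use trees (≈ 2–5 % of
random 8-row/3-feature cases in our experiments — the classic limitation of
greedy impurity splitting). The oracle tests therefore verify the split
search exhaustively at node level, check the whole tree against an
independently coded naive reference, and bound the greedy training loss
below by the exhaustive-tree minimum, rather than asserting an equality
that greedy recursion cannot guarantee.

## Evaluation

Confusion counts are pooled over LOSO folds; accuracy, sensitivity and
specificity are computed from the pooled counts (identities hold exactly by
construction). A held-out subject with rows of only one category is still
evaluated. Split values reported alongside an evaluation come from a tree
fitted on the full matrix, in z-score units.

Under the null (effect_scale = 0), per-seed LOSO accuracy is *overdispersed*
relative to Binomial(180, 0.5): the six sets of a held-out subject share
that subject's random offsets and tend to fall on the same side of a
learned split (empirical per-seed SD ≈ 0.053 vs binomial 0.037). The
calibration test asserts the 20-seed mean inside the binomial 95 % interval
for n = 180 and a per-seed corridor of 0.35–0.65 sized for the clustered
variance; demanding every seed inside the binomial band would reject a
correctly calibrated pipeline with high probability.

## Problem sizes and determinism

Default study-scale runs use 30 subjects (180 sets per exercise; the
bird-dog sides collapse into one label by default, `keep_sides=True`
separates them, giving the 24-sets-per-subject bookkeeping across 4 counted
exercises). The test suite runs the full 30-subject cohorts for the
acceptance-level checks and 4–6-subject cohorts for unit-level checks. All
randomness flows from explicit integer seeds through
`numpy.random.SeedSequence` spawning (subject profiles and per-set streams
are independent children of the master seed), so identical seeds give
bit-identical recordings, matrices and artifacts; the pipeline writes
SHA-256 hashes of every artifact to make this checkable end to end.

## Known limitations

* The generator's TCM effects are designed so that the clinically motivated
  features are the generatively informative ones; it cannot adjudicate
  which features would win on real recordings.
* Greedy CART optimality is node-local (see above).
* No automatic repetition detection: segmentation requires the marker
  channel, as in the original procedure.
* Single TCM per exercise; no multi-class compensation taxonomy.
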