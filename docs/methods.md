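# Methods

## Problem and pipeline

posegym classifies which of ten exercises a person is performing from a pose
estimator's 3-D landmark stream. The pipeline has four stages, each its own
module:

1. **landmarks** — data model and I/O. Only the 22 non-facial landmarks
   (MediaPipe Pose indices 11–32) are used; facial rows in raw dumps are
   dropped on read. Coordinates may be image-normalized or metric: only
   finiteness is validated, because the angle features are invariant to
   translation, rotation and scale, and the coordinate features are consumed
   by a model trained in the same convention as its inputs.
2. **features** — per frame, 66 coordinates + 12 joint angles = 78 attributes.
3. **cnn** — a per-frame 1-D convolutional softmax classifier.
4. **ensemble** — soft voting over K-frame windows (default K = 30).

## Joint angles

The angle at vertex p₂ is obtained via the law of cosines from the three
pairwise Euclidean distances, converted to degrees, with the acos argument
clamped to [−1, 1] to absorb floating-point overshoot on near-collinear
joints. Which twelve joints constitute "the major joint angles" is a design
choice; the default set (left/right elbow, shoulder, hip, knee, ankle, wrist,
each defined by the adjacent segment landmarks, e.g. elbow =
shoulder–elbow–wrist) covers every major limb joint resolvable from the
22-landmark set and is bilaterally symmetric. It is overridable via
`AngleSpec` lists.

Degenerate joints (coincident landmarks) raise by default; a lenient mode
returns NaN, and NaN frames are excluded from window votes with a logged
count — a window with no valid frames yields no decision.

Coordinate standardization (per-sequence zero mean, unit variance) exists as
a flag but defaults **off**: the classifier consumes raw coordinates, and
angles are never standardized since they are already scale-free. Columns that
are constant up to float accumulation error are centred but not scaled.

## The classifier

The reference stack is: conv(32, k3) → pool(2) → conv(64, k3) → pool(2) →
conv(128, k3) → pool(2) → conv(256, k3) → pool(2) → flatten(768) →
dense(512, relu) → dense(10, softmax). Valid convolutions (L → L − k + 1),
floor-division pooling (L → ⌊L/2⌋); `compute_layer_shapes` implements this
arithmetic and rejects stacks whose intermediate length falls below the next
kernel.

The network is written in numpy: convolution as an im2col matrix product,
max-pool backward routed through stored argmax indices, explicit
backpropagation (verified against central-difference numeric gradients in the
test suite), softmax cross-entropy loss, Adam updates. Training
hyperparameter defaults — relu, Adam at 1e-3, batch 64, 50 epochs — are
standard desk-scale choices, all exposed in `ModelConfig`. Dropout (default
0) applies only between the 512-unit dense layer and the output. One integer
seed drives He-normal initialization, epoch shuffling and dropout masks;
bit-exact reproducibility is promised in single-threaded deterministic mode
(BLAS threading can reorder floating-point sums).

Every frame inherits its sequence's label during training, and **all splits
are at the sequence level** — frames of one video never straddle train and
test, which would leak near-duplicate samples.

## Soft-voting ensemble

Per-frame probability vectors within a K-frame window are summed; the argmax
of the sums is the decision (summing and averaging are equivalent under
argmax). Ties break to the lowest class index. The default stride equals K —
non-overlapping verdicts, one per second at 30 fps — and stride 1 gives a
sliding stream for latency-sensitive use. A whole-sequence verdict takes the
majority class over window decisions, ties broken by total summed scores,
then lowest index; sequences shorter than K fall back to a single vote over
all frames.

K = 30 is the default because windowed accuracy saturates near that length
while keeping decisions quick (about one second of video); the
`accuracy_vs_frames` curve reproduces this trade-off on any labelled test
set.

## Synthetic motion generator

The simulator emulates avatar-style exercise clips: each class is a set of
per-joint sinusoids — baseline + amplitude · sin(2πft + phase) over the
twelve default joints, clamped to [2°, 178°] — e.g. the squat oscillates
knees (120° ± 55°) and hips (120° ± 48°) while the curl moves essentially
only the elbows (90° ± 60°); pedalling-type classes (bicycle crunch, bird
dog) drive left and right half a cycle out of phase. Frequencies are
0.4–0.6 Hz (realistic repetition cadence). The signatures are hand-designed
caricatures, config-overridable via a YAML registry, and validated to be
pairwise distinct: every class pair differs by ≥ 15° in baseline or amplitude
on at least one joint.

Landmark positions follow by forward kinematics over fixed segment lengths
(defaults roughly metric: torso 0.50, thigh 0.45, shank 0.42, upper arm 0.30,
forearm 0.27). Each body side is laid out in its own sagittal plane at a
constant depth offset (left +z, right −z, separation from the shoulder/hip
widths). Because every default angle spec uses landmarks of a single side,
each commanded angle is exactly the angle the feature extractor re-measures —
the generator and extractor are mutual oracles, and the closed-loop test
requires agreement within 1e-3°. Full 3-D choreography (trunk rotation,
abduction out of the sagittal plane) is deliberately out of scope.

Noise: i.i.d. Gaussian jitter on every coordinate (default σ = 0.005, i.e.
1% of torso length) plus outlier frames — with probability 0.05 a frame's
jitter is inflated 10× — modelling pose-estimator glitches, the failure mode
frame-level voting is designed to absorb.

**What passing tests show:** the synthetic classes are cleanly separable by
design, so near-perfect recovery demonstrates that feature extraction,
training, inference and voting are wired correctly — not that the model
reaches any particular accuracy on real captures, where occlusion,
viewpoint, anthropometric variation and estimator bias all matter.

## Evaluation

The evaluation unit is the window decision. Metrics come from the confusion
matrix (rows true, columns predicted): per-class precision, recall, F1;
macro averages (headline) computed over classes with defined values, plus
support-weighted averages. A class never predicted has undefined precision,
reported as 0 and flagged explicitly. Cross-validation is stratified k-fold
(default 5) at the sequence level: each class's sequences are shuffled with
the fold seed and dealt round-robin, so every fold tests a class-balanced
set; the pooled report sums fold confusion matrices, making pooled accuracy
exactly trace/total.

## Problem sizes and numerical choices

- Acceptance runs train on 10 classes × 15 sequences × 120 frames (18 000
  frames) for 8 epochs — enough for the separable synthetic task — and hold
  out 5 sequences per class (200 windows at K = 30); the cross-validation
  study uses 10 × 5 × 60 frames with 4 epochs per fold.
- Seeds: per-sequence seeds derive from a master seed via
  `numpy.random.SeedSequence` and are recorded in the dataset manifest.
- Serialization writes coordinates at 17 significant digits; CSV reads use
  pandas' round-trip float parser so read∘write is the identity.
- acos clamping, constant-column handling in standardization, and the
  lowest-index tie-break are the deliberate edge-case policies; each is
  unit-tested.

## Known limitations

- The simulator's planar-dominant motion cannot produce classes that differ
  only in out-of-plane movement; adding such classes would require a richer
  signature parameterization.
- The numpy trainer is single-process and CPU-bound; it is sized for
  desk-scale datasets (10⁴–10⁵ frames), not for large video corpora.
- Real-video ingestion (video → landmarks) is an adapter concern left to
  external pose estimators; the package starts at the landmark file.
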