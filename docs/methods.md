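# Methods

## Problem setting

Skeletal phenotyping screens image anesthetized mice dorsally and measure
the lengths of the tibia, femur and pelvis on both sides. Manual
measurement is slow and operator-dependent; `murimetry` automates it with a
two-stage keypoint detector: stage one finds each mouse and scores the
probability that the detection is a top-view animal, stage two localizes
the 12 bone endpoints (3 bones x 2 sides x 2 endpoints) inside each
detection. Post-processing converts endpoint pairs into per-bone lengths
with quality flags, and the statistics layer supports the downstream
phenotype analysis: agreement between manual and automated lengths,
residualization of length against age per sex, and variance comparison
between measurement methods by F-test.

## Detector

**Backbone.** A conv/BN/ReLU pyramid with FPN lateral connections over
three levels (strides 2, 4, 8). The stride-2 stem output is the first
pyramid level; two further stride-2 stages deepen the representation. The
`tiny_fpn` profile (stem 8, stages 16/32, FPN width 8; ~5 x 10^4
parameters) trains on one CPU; `efficientnet_b3_fpn` instantiates the same
design at B3-like depth/width (stem 40, stages 96x3/232x4, FPN width 64)
for full-scale use. No pretrained weights are used.

**Region proposals.** One square anchor (96 px, roughly an adult mouse) per
stride-8 cell. The head has separate objectness and box-delta conv towers:
with a shared tower the dense, low-variance box-regression gradients
suppressed objectness learning at this parameter scale. Proposals are
ranked by objectness *logits* — sigmoid scores saturate to exact ties,
after which an argsort would select cells by array order rather than
evidence — then NMS (IoU 0.5) keeps the top 8.

**ROI classification.** Proposals are bilinearly ROI-aligned from the
stride-4 level to 7x7 and classified by a 2-layer MLP into background /
top-view mouse (optionally a non-top-view class), with a class-agnostic box
refinement. Training samples proposals plus ground-truth boxes, near-copies
(8% jitter) as positive diversity, off-centre copies (35% shift) as hard
negatives, and random anchor-sized boxes. The hard negatives are what
teaches the classifier that a box covering half a mouse is background;
without them, shifted duplicates of a detection survive NMS with high
confidence and break the count. Detection NMS uses IoU 0.1: dorsal-view
mice on a scanner bed never overlap, so aggressive suppression is safe.
At inference, duplicate resolution and keypoint-window placement use the
*proposal* boxes: at the tiny scale the RPN's per-anchor regression is
substantially more reliable than the ROI refinement (which is trained and
reported in the loss, but a rare catastrophic refinement would otherwise
swallow a neighbouring detection in NMS or strand a duplicate). The
reported detection box is the proposal grown to cover the decoded
keypoints, which are more precise than any box regression.

**Keypoint head.** A fixed-size window (112 px, even-aligned) centred on
the detection box is cropped from the stride-2 FPN level — an integer crop,
not an interpolated resize, so heatmap bins stay in 1:1 registration with
image pixels (the varying-size -> fixed-size bilinear ROI-align the
detector uses for classification is deliberately *not* used here). Features
outside the detection box (+6 px margin) are zeroed so a neighbouring mouse
cannot attract a keypoint; two normalized coordinate channels are appended
(CoordConv) because the window is mouse-centred and translation-equivariant
convolutions otherwise cannot tell a left tibia from a right one. The head
is 8 conv+BN+ReLU blocks (8 channels) followed by one transposed
convolution (stride 2) producing, per keypoint, a heatmap logit plane plus
a 2-plane continuous offset field, all at 1 px per bin.

**Keypoint supervision.** Heatmaps are trained with per-keypoint softmax
cross-entropy against Gaussian soft labels whose width anneals from
sigma = 1.5 to 0.7 bins across the phase (broad targets spread gradient
early; narrow targets sharpen blobs late). Offset planes are trained with
smooth-L1 (beta 0.25) against the exact continuous displacement at every
bin within 2 px of the target. The window/mask box is jittered by up to
6 px during training because inference windows come from proposals, not
ground-truth boxes. A squared-coordinate loss through a soft-argmax decode
is also implemented (`keypoint_supervision="coordinate"`); the heatmap path
is the default. The evaluation-facing loss definitions (mean binary
cross-entropy objectness, mean categorical cross-entropy class loss,
per-box summed squared keypoint error, and their sum) live in
`murimetry.losses` with analytic gradients; the keypoint term is
implemented with positive sign — a squared error is only a loss when
bounded below.

**Decoding.** Skeleton-consistent peak picking: each side's keypoints form
a kinematic chain (pelvis start/end, femur start/end, tibia start/end)
decoded jointly by Viterbi dynamic programming over the top-4 candidate
peaks per keypoint, maximizing summed peak logits subject to articulation
proximity (9 px) and plausible bone extent (6-60 px). A single confused
heatmap — a tibia tip attracted to its mirror twin, a hip channel peaking
on the knee — then loses to the chain that keeps the whole leg consistent.
Since scenes articulate bones exactly, the two keypoint channels at each
joint are decoded as one chain node from their summed heatmaps
(`tie_joints`), and bone links additionally require caudal monotonicity
(every leg bone points tailward in a head-up dorsal view), which rules out
start/end reversals. The higher-scoring side commits first; the other
side's candidates near committed mirror locations are penalized, because
left and right tips are locally indistinguishable and must not collapse
onto one point. A bilateral-symmetry pass follows: if a bone disagrees
with its mirror by more than 35%, the weaker-scoring chain is re-decoded
with per-bone length bounds borrowed from the stronger side and a deeper
candidate list.

Inference averages head logits over the four mirror views of the window
(identity, horizontal, vertical, both; channel labels swapped for single
mirrors, mirrored offset components negated). Each view is computed
through the backbone — convolutions do not commute with mirroring — and
every view is in the training distribution because training augments with
both flips. A side confusion in one view is rarely repeated in the others,
so inconsistent peaks cancel and consistent ones sharpen. Because the
CoordConv head is sensitive to window placement, decoding runs a second
pass with the window re-centred on the keypoint-grown box whenever the
first pass moves it, reproducing the training-time placement.

The chosen bin is refined by the learned offset field (or, without
offsets, by the softmax-weighted centroid of the logits in a 7x7 window —
unbiased for a symmetric blob, unlike a quarter-pixel shift toward the
runner-up neighbour, which is a pure 0.25 px bias when the truth lies
exactly on a bin). The final detection box is expanded to cover its
decoded keypoints, so the keypoints-inside-box invariant can never corrupt
a coordinate by clipping.

## Training protocol

Detection and keypoint supervision come from separate passes. A *detection
phase* freezes the keypoint header and updates backbone + RPN + ROI head
with objectness, class and box losses. A *keypoint phase* freezes the ROI
header and updates backbone + keypoint header with objectness and keypoint
losses; the backbone there runs with frozen (running-statistic) BatchNorm —
standard practice when fine-tuning detection models — and takes
0.1x-scaled steps so the frozen ROI header keeps seeing features close to
the ones it was trained on. Each phase warm-starts at learning rate 0.0002
for one epoch, then 0.001 with multi-step decay (x0.1 at 60% and 85% of the
phase budget), Adam, batch size 4, and stops early when the validation
metric fails to improve by 1e-4 for `patience` checks (objectness accuracy
for detection; the *median* squared keypoint error for the keypoint phase —
the mean is recorded too, but a single flickering outlier should not stop
training). Full-scale budgets are 100 detection and 1000 keypoint
epochs; the desk profile uses 20 and 85 (decay at epochs 65/78). Periodic
validation runs without the inference-time flip ensemble to keep its cost
proportionate. Any non-finite loss aborts training with a diagnostic
naming the phase, epoch and batch.

## Synthetic scenes

Each scene is Gaussian background noise plus 0-2 non-overlapping stylized
mice: a soft elliptical body and six bright anti-aliased capsules whose
exact endpoints are the stored ground truth. Skeleton geometry emulates a
prone mouse: near-vertical spine with +-12 degrees tilt, pelvis flaring ~32
degrees from the hip, femur continuing outward (~58 degrees), tibia turning
back inward (~10 degrees). Bones articulate *exactly* — the femur starts at
the pelvis end, the tibia at the femur end. This is deliberate: the bright
capsules are max-composited and blurred, so two tips displaced by a random
sub-capsule jitter would merge into one blob and the jittered endpoints
would not be recoverable from the image even in principle; an exactly
shared joint point keeps every ground-truth coordinate well-posed (an
`adjacency_jitter` parameter remains available for sensitivity studies).
Default lengths (pelvis 18, femur 22, tibia 26 px, sd 1.5)
keep the tibia > femur > pelvis ordering of the real animal at a scale
where one mouse fits a 256x256 frame. `integer_keypoints` (default on)
snaps endpoints to the pixel grid so decoding error can be separated from
generation error. A light Gaussian blur (sigma 0.8) mimics radiographic
softness.

What the generator does **not** emulate: soft-tissue contrast, bone-density
variation, overlapping or non-top-view animals (a dim decoy body is
available but off by default), scanner artefacts, or anatomical
pathologies. Passing the benchmark therefore demonstrates that the
pipeline's machinery — detection, windowing, heatmap localization,
measurement, statistics — is correct and precise on ideal contrast, not
that the tiny profile would transfer to real radiographs; the full-scale
profile plus real annotations would be needed for that.

The cohort simulator draws ages uniformly (30-120 d), assigns sex evenly,
and produces bone lengths along a Michaelis-Menten-shaped growth curve
(asymptotes 30/26/21 px; males +4%) plus i.i.d. Gaussian measurement noise
(default sd 0.3 px) — enough structure to exercise per-sex spline
residualization and method-variance comparisons.

## Measurement rules

Detections are kept only with top-view probability strictly above 0.5.
Lengths are Euclidean distances between decoded endpoint pairs, reported in
pixels (mm = px x pixel spacing if calibrated). Refinement attaches flags
and never alters values: `length_outlier` when |length - median| > k x MAD
within the bone class (k = 5); `abnormal_geometry` for missing/coincident
endpoints, articulation gaps beyond half the median femur length, or
left/right asymmetry beyond 25% of the pair mean; `low_confidence` when an
endpoint score falls below threshold. Records are flagged, never deleted —
removal policy belongs to the caller.

## Statistics

* Keypoint MSE: mean squared pixel distance over matched visible keypoints
  (matching by greedy IoU > 0.5). Reported on the squared-pixel scale.
* Objectness accuracy: fraction of images whose retained-detection count
  equals the true mouse count.
* Correlation: Pearson r with R^2 = r^2 and the two-sided t-transform
  p-value (may underflow to 0 at large n), plus the least-squares line.
* Residualization: per sex, a cubic regression B-spline of length on age
  (df = 5, knots at age quantiles; optional ridge penalty on non-intercept
  coefficients). The intercept is never penalized, which makes residuals
  exactly mean-zero per sex.
* Variance comparison: two-sided F-test on residual variances with
  (n_a - 1, n_b - 1) degrees of freedom.

## Numerical choices

Probabilities are clamped to [1e-7, 1 - 1e-7] before logarithms. All
network arithmetic is float32 (im2col + GEMM convolutions, manual
backward passes, verified against finite differences to ~1e-3 relative);
loss/statistics arithmetic is float64. Box coordinates are half-open
`[x0, x1) x [y0, y1)` in 0-based pixel indices, x rightward, y downward.
Random state everywhere derives from one root seed (scene seed, parameter
init seed = root + 1, training seed = root + 2).

## Desk-scale benchmark

`murimetry.benchmark.run_desk_benchmark` generates 140 scenes (100 train /
20 validation / 20 test, 256x256, one or two mice each), trains the tiny
profile with the alternating protocol, and reports held-out objectness
accuracy, keypoint MSE, and the R^2 between automated and ground-truth
bone lengths. The problem sizes are chosen so the whole run completes on a
single CPU core in well under half an hour; the same entry point backs
`scripts/acceptance.py` and the acceptance tests.

## Known limitations

* The tiny profile is tuned to the synthetic contrast; real radiographs
  need the full-scale backbone and real annotations.
* The keypoint window (112 px) assumes the animal fits; a config change is
  required for much larger subjects or higher resolutions.
* Structured decoding assumes at most mirror-pair ambiguity; pathologies
  that truly displace joints beyond the adjacency radius would be decoded
  against the constraint (and then flagged by measurement refinement).
* The residual model is a stand-in strategy: the spline interface accepts a
  substitute parametric growth model where one is established.
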