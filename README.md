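# murimetry

Automated measurement of murine bone lengths from dorsal-view radiographs.

Genetic screens for skeletal phenotypes image thousands of anesthetized
mice and measure the tibia, femur and pelvis on both sides; manual
measurement is slow and operator-dependent, and downstream genetic
association mapping is only as good as the phenotype's precision.
`murimetry` automates the measurement with a two-stage keypoint detector:

1. **Detection stage** — an FPN conv backbone with a region-proposal head
   and an ROI classification head finds each mouse and scores the
   probability that the detection is a top-view animal. Detections at or
   below probability 0.5 are discarded.
2. **Keypoint stage** — a heatmap head localizes the 12 bone endpoints
   (3 bones x 2 sides x 2 endpoints) inside each detection with sub-pixel
   offset refinement and skeleton-consistent decoding.

Bone length is then the Euclidean distance between an endpoint pair,

```
L = sqrt((x1 - x0)^2 + (y1 - y0)^2)   [pixels],
```

with quality flags for outliers (median +- k*MAD), violated joint
adjacency, and left/right asymmetry. Training minimizes the combined loss

```
L = L_objectness + L_class + L_keypoints
```

(mean binary cross-entropy over proposals, mean categorical cross-entropy
over ROIs, per-box summed squared keypoint error), with an alternating
protocol: the detection headers and the keypoint header are trained in
separate phases, each freezing the other, warm-starting at learning rate
2e-4 for one epoch before 1e-3 with multi-step decay.

The statistics layer covers the phenotyping workflow: objectness accuracy
(exact mouse-count agreement), keypoint MSE, Pearson correlation between
manual and automated lengths, per-sex spline residualization of length
against age, and F-tests comparing method variances.

A synthetic-radiograph generator (stylized skeletons with exact
ground-truth endpoints on noisy backgrounds, plus an age/sex growth-curve
cohort simulator) makes every stage trainable and testable with no
external data. See `docs/methods.md` for the model, the generator's scope,
and all numerical choices.

## Worked example

```python
import numpy as np
from murimetry import (SceneConfig, generate_scene, build_model, ModelConfig,
                       TrainingSchedule, alternate_train, samples_from_scenes,
                       predict, filter_detections, measure_bones)

# two synthetic mice on a noisy 256x256 radiograph
scene = generate_scene(SceneConfig(n_mice=2, seed=3))

# desk-scale benchmark: train the tiny profile and measure held-out scenes
from murimetry.benchmark import run_desk_benchmark
result = run_desk_benchmark(seed=0)
print(f"objectness accuracy {result['objectness_accuracy']:.4f}")
print(f"keypoint MSE        {result['keypoint_mse']:.4f}")
print(f"length R^2          {result['length_r2']:.4f}")
```

On one CPU core this trains in roughly a quarter hour and prints

```
objectness accuracy 1.0000
keypoint MSE        0.3196
length R^2          0.9553
```

meaning: every held-out image yielded exactly the true number of mice
after the >0.5 top-view filter; matched keypoints landed a fraction of a
pixel from the integer-pixel ground truth on average (the mean squared
error is dominated by a single hard case of two adjacent animals — the
median squared error is an order of magnitude smaller); and the automated
bone lengths track the true lengths closely.

The same pipeline is scriptable from the shell:

```bash
murimetry simulate data/            # synthetic dataset (COCO JSON + PNGs)
murimetry train data/ run/          # alternating two-phase training
murimetry measure run/model.npz data/test/images lengths.csv
murimetry evaluate run/model.npz data/ report.json
```

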