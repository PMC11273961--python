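"""Desk-scale end-to-end benchmark: synthesize, train, evaluate.

This is the reference pipeline exercise used by the acceptance script and
the integration tests: generate a synthetic cohort of dorsal radiographs
(100 train / 20 validation / 20 test images at 256x256, one or two mice
each, integer-pixel ground truth), run the alternating two-header training
protocol with the tiny backbone, and score the held-out images.
"""

from __future__ import annotations

import hashlib

import numpy as np

from .config import desk_profile
from .measure import filter_detections, measure_bones
from .model import build_model, predict
from .stats import correlate, keypoint_mse, match_by_iou, objectness_accuracy
from .synthetic import SceneConfig, generate_scene
from .train import (samples_from_scenes, train_detection_phase,
                    train_keypoint_phase)


def desk_dataset(seed: int, n_train: int = 100, n_val: int = 20,
                 n_test: int = 20, scene: SceneConfig | None = None):
    """Generate the benchmark splits as in-memory training samples."""
    scene = scene or SceneConfig()
    total = n_train + n_val + n_test
    root = np.random.default_rng(seed)
    scene_seeds = root.integers(0, 2 ** 31 - 1, size=total)
    counts = root.integers(1, 3, size=total)
    samples = []
    from dataclasses import replace

    for i in range(total):
        cfg = replace(scene, n_mice=int(counts[i]), seed=int(scene_seeds[i]))
        samples.append(generate_scene(cfg))
    samples = samples_from_scenes(samples)
    return (samples[:n_train], samples[n_train:n_train + n_val],
            samples[n_train + n_val:])


def _checksum(group: dict) -> str:
    h = hashlib.sha256()
    for key in sorted(group):
        h.update(key.encode())
        h.update(np.ascontiguousarray(group[key]).tobytes())
    return h.hexdigest()


def run_desk_benchmark(seed: int = 0, n_train: int = 100, n_val: int = 20,
                       n_test: int = 20) -> dict:
    """Full pipeline run; returns the held-out metrics and protocol audits."""
    cfg = desk_profile(seed)
    train, val, test = desk_dataset(cfg.scene.seed, n_train, n_val, n_test,
                                    cfg.scene)
    det = build_model(cfg.model)
    data = {"train": train, "val": val}

    rng = np.random.default_rng(cfg.schedule.seed)
    kp_sum_before = _checksum(det.param_groups()["keypoint_header"])
    hist_det = train_detection_phase(det, data, cfg.schedule, rng)
    kp_sum_after = _checksum(det.param_groups()["keypoint_header"])
    roi_sum_before = _checksum(det.param_groups()["roi_header"])
    hist_kp = train_keypoint_phase(det, data, cfg.schedule, rng)
    roi_sum_after = _checksum(det.param_groups()["roi_header"])
    hist_det.extend(hist_kp)
    history = hist_det

    # held-out evaluation: detection counts, keypoint error, length agreement
    preds = predict(det, [s["image"] for s in test])
    kept = [filter_detections(p, cfg.model.score_threshold) for p in preds]
    acc = objectness_accuracy([len(s["boxes"]) for s in test], kept)

    gt_sets, pred_sets = [], []
    gt_lengths, auto_lengths = [], []
    for s, ds in zip(test, kept):
        if not ds or not len(s["boxes"]):
            continue
        pairs = match_by_iou(s["boxes"], np.array([d.box for d in ds]))
        for gi, pi in pairs:
            gt_sets.append(s["keypoints"][gi])
            pred_sets.append(ds[pi].keypoints)
            auto = measure_bones(ds[pi])
            gt_kp = s["keypoints"][gi]
            for m in auto:
                p0, p1, v0, v1 = gt_kp.endpoint_pair(m.bone, m.side)
                if m.length is not None and v0 and v1:
                    gt_lengths.append(float(np.linalg.norm(p1 - p0)))
                    auto_lengths.append(m.length)
    mse = keypoint_mse(gt_sets, pred_sets) if gt_sets else float("nan")
    n_kp = int(sum((g.visibility > 0).sum() for g in gt_sets))
    r2 = correlate(gt_lengths, auto_lengths).r2 if len(gt_lengths) >= 3 \
        else float("nan")

    return {
        "objectness_accuracy": float(acc),
        "keypoint_mse": float(mse),
        "n_test_images": len(test),
        "n_matched_keypoints": n_kp,
        "n_lengths": len(gt_lengths),
        "length_r2": float(r2),
        "history": history,
        "detector": det,
        "config": cfg,
        "test_samples": test,
        "predictions": preds,
        "keypoint_header_frozen_in_detection": kp_sum_before == kp_sum_after,
        "roi_header_frozen_in_keypoint": roi_sum_before == roi_sum_after,
    }
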