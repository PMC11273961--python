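"""Alternating two-header training protocol.

The detector is trained in two kinds of phases. A *detection* phase freezes
the keypoint header and updates backbone + ROI header from objectness,
class and box-regression losses. A *keypoint* phase freezes the ROI header
and updates backbone + keypoint header from objectness and keypoint losses
(the keypoint header is supervised through its heatmaps by default, or by
the squared-coordinate loss through a soft-argmax decode when
``keypoint_supervision='coordinate'``). Each phase starts with a warm
learning rate for one epoch, then steps to the base rate with multi-step
decay, and halts early once its validation metric plateaus.

Any non-finite loss aborts training immediately with a diagnostic naming
the phase, epoch and batch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .augment import AugmentConfig, augment
from .errors import ConfigError, TrainingDivergedError
from .measure import filter_detections
from .model import (Detector, box_iou, decode_deltas, encode_deltas, nms,
                    predict, save_checkpoint)
from .stats import keypoint_mse, match_by_iou, objectness_accuracy


@dataclass
class TrainingSchedule:
    """Learning-rate schedule and epoch budgets.

    The paper-scale budgets are 100 detection epochs and 1000 keypoint
    epochs; desk-scale profiles shrink these while keeping the warm-start
    (0.0002 for one epoch, then 0.001 with multi-step decay) intact.
    """

    warm_lr: float = 0.0002
    warm_epochs: int = 1
    base_lr: float = 0.001
    milestones: list | None = None  # epoch indices; default 60%/85% of budget
    decay_factor: float = 0.1
    detection_epochs: int = 100
    keypoint_epochs: int = 1000
    batch_size: int = 4
    patience: int = 10
    min_improvement: float = 1e-4
    optimizer: str = "adam"
    kp_backbone_lr_scale: float = 0.1  # backbone step scale in keypoint phase
    cycles: int = 1
    augment: AugmentConfig | None = None
    seed: int = 0

    def validate(self) -> None:
        if not self.warm_lr < self.base_lr:
            raise ConfigError("warm_lr must be below base_lr")
        if self.detection_epochs < 1 or self.keypoint_epochs < 1:
            raise ConfigError("epoch budgets must be >= 1")
        if self.batch_size < 1:
            raise ConfigError("batch_size must be >= 1")
        if self.optimizer != "adam":
            raise ConfigError(f"unsupported optimizer {self.optimizer!r}")

    def lr_at(self, epoch: int, budget: int) -> float:
        if epoch < self.warm_epochs:
            return self.warm_lr
        ms = self.milestones
        if ms is None:
            ms = [max(int(0.6 * budget), self.warm_epochs + 1),
                  max(int(0.85 * budget), self.warm_epochs + 2)]
        return self.base_lr * self.decay_factor ** sum(epoch >= m for m in ms)


@dataclass
class TrainingHistory:
    records: list = field(default_factory=list)

    def append(self, **rec) -> None:
        for k, v in rec.get("losses", {}).items():
            if not np.isfinite(v):
                raise TrainingDivergedError(
                    f"non-finite {k} loss in {rec.get('phase')} epoch "
                    f"{rec.get('epoch')}")
        self.records.append(rec)

    def of_phase(self, phase: str) -> list:
        return [r for r in self.records if r["phase"] == phase]

    def extend(self, other: "TrainingHistory") -> None:
        self.records.extend(other.records)

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for r in self.records:
                fh.write(json.dumps(r) + "\n")


# ------------------------------------------------------------- datasets

def samples_from_scenes(scenes) -> list[dict]:
    """Convert SyntheticScene objects to training samples."""
    out = []
    for i, sc in enumerate(scenes):
        out.append({
            "image": np.asarray(sc.image, dtype=np.float32),
            "boxes": np.array([m.box for m in sc.mice]).reshape(-1, 4),
            "labels": np.array([1 if m.top_view else 2 for m in sc.mice],
                               dtype=int),
            "keypoints": [m.keypoints for m in sc.mice],
            "image_id": i,
        })
    return out


def samples_from_coco(annotations_path, image_dir) -> list[dict]:
    from .io import load_image, read_coco_keypoints

    recs = read_coco_keypoints(annotations_path)
    out = []
    for rec in recs:
        img = load_image(Path(image_dir) / rec.file_name)
        out.append({
            "image": img,
            "boxes": np.array([m.box for m in rec.mice]).reshape(-1, 4),
            "labels": np.array([m.label for m in rec.mice], dtype=int),
            "keypoints": [m.keypoints for m in rec.mice],
            "image_id": rec.image_id,
        })
    return out


def _augment_sample(sample: dict, aug: AugmentConfig,
                    rng: np.random.Generator) -> dict:
    img, ksets, boxes = augment(sample["image"], list(sample["keypoints"]),
                                list(sample["boxes"]), aug, rng=rng)
    return {**sample, "image": img, "keypoints": ksets,
            "boxes": np.array(boxes).reshape(-1, 4)}


# ------------------------------------------------------- loss machinery

def _rpn_losses(det: Detector, rpn_out, samples, rng, with_box: bool):
    """Objectness BCE (+ box smooth-L1) over sampled anchors; returns
    (losses, dlogits_like_rpn_out)."""
    cfg = det.config
    b, _, gh, gw = rpn_out.shape
    h, w = samples[0]["image"].shape
    anchors, _, _ = det.anchor_grid(h, w)
    drpn = np.zeros_like(rpn_out)
    sel_logits, sel_labels, sel_pos = [], [], []
    for bi, s in enumerate(samples):
        gt = s["boxes"]
        n_anchor = anchors.shape[0]
        if len(gt):
            iou = box_iou(anchors, gt)  # (A, M)
            best = iou.max(axis=1)
            pos = np.flatnonzero(best >= cfg.rpn_pos_iou)
            forced = iou.argmax(axis=0)  # best anchor per gt
            if len(pos) > cfg.rpn_pos_samples:
                pos = rng.choice(pos, cfg.rpn_pos_samples, replace=False)
            pos = np.union1d(pos, forced)
            neg = np.flatnonzero(best < cfg.rpn_neg_iou)
        else:
            pos = np.array([], dtype=int)
            neg = np.arange(n_anchor)
        if len(neg) > cfg.rpn_neg_samples:
            neg = rng.choice(neg, cfg.rpn_neg_samples, replace=False)
        idx = np.concatenate([pos, neg]).astype(int)
        sel_logits.append((bi, idx))
        sel_labels.append(np.concatenate([np.ones(len(pos)), np.zeros(len(neg))]))
        if with_box and len(pos) and len(gt):
            match = box_iou(anchors[pos], gt).argmax(axis=1)
            sel_pos.append((bi, pos, encode_deltas(gt[match], anchors[pos])))

    flat_obj = rpn_out[:, 0].reshape(b, -1)
    logits = np.concatenate([flat_obj[bi, idx] for bi, idx in sel_logits])
    labels = np.concatenate(sel_labels)
    obj_loss, dlog = nn.sigmoid_bce_with_logits(logits, labels)
    ofs = 0
    for bi, idx in sel_logits:
        drpn[bi, 0].reshape(-1)[idx] += dlog[ofs:ofs + len(idx)]
        ofs += len(idx)

    box_loss = 0.0
    if with_box and sel_pos:
        preds, targets = [], []
        for bi, pos, tgt in sel_pos:
            preds.append(rpn_out[bi, 1:5].reshape(4, -1).T[pos])
            targets.append(tgt)
        pred = np.concatenate(preds)
        tgt = np.concatenate(targets)
        box_loss, dbox = nn.smooth_l1(pred, tgt, beta=0.2)
        ofs = 0
        for bi, pos, _ in sel_pos:
            n = len(pos)
            flat = drpn[bi, 1:5].reshape(4, -1)
            flat[:, pos] += dbox[ofs:ofs + n].T
            ofs += n
    return {"objectness": obj_loss, "rpn_box": box_loss}, drpn


def _decode_proposals(det: Detector, rpn_out_b, h, w):
    cfg = det.config
    anchors, _, _ = det.anchor_grid(h, w)
    logit = rpn_out_b[0].reshape(-1)  # rank by logits: sigmoid saturates
    deltas = rpn_out_b[1:5].reshape(4, -1).T
    order = np.argsort(-logit)[:cfg.rpn_pre_nms]
    boxes = decode_deltas(deltas[order], anchors[order])
    boxes[:, 0::2] = np.clip(boxes[:, 0::2], 0, w)
    boxes[:, 1::2] = np.clip(boxes[:, 1::2], 0, h)
    keep = nms(boxes, logit[order], cfg.rpn_nms_iou)[:cfg.rpn_post_nms]
    return boxes[keep]


def detection_step(det: Detector, samples: list[dict],
                   rng: np.random.Generator) -> dict:
    """One optimisation step of the detection phase on a mini-batch."""
    cfg = det.config
    imgs = np.stack([s["image"] for s in samples])[:, None].astype(np.float32)
    h, w = imgs.shape[2:]
    feats = det.backbone.forward(imgs, training=True)
    rpn_out = det.rpn.forward(feats["s8"], training=True)
    losses, drpn = _rpn_losses(det, rpn_out, samples, rng, with_box=True)

    # ROI classification on proposals + ground-truth boxes
    roi_feats, all_labels, all_tgt, backs, counts = [], [], [], [], []
    for bi, s in enumerate(samples):
        props = _decode_proposals(det, rpn_out[bi], h, w)
        extra = [props]
        if len(s["boxes"]):
            gt = s["boxes"]
            extra.append(gt)
            # jittered copies diversify positives; random anchor-sized boxes
            # give the classifier hard negatives beyond RPN output
            sizes = np.column_stack([gt[:, 2] - gt[:, 0], gt[:, 3] - gt[:, 1]])
            for _ in range(2):  # near-copies diversify positives
                noise = rng.normal(0, 0.08, (len(gt), 4)) * np.tile(sizes, 2)
                extra.append(gt + noise)
            for _ in range(2):  # off-centre copies are hard negatives:
                # a box covering half a mouse must score as background,
                # otherwise shifted duplicates survive detection NMS
                shift = rng.normal(0, 0.35, (len(gt), 2)) * sizes
                extra.append(gt + np.tile(shift, 2))
        a = cfg.anchor_size
        rand_c = rng.uniform([a / 2, a / 2], [w - a / 2, h - a / 2], (2, 2))
        extra.append(np.column_stack([rand_c - a / 2, rand_c + a / 2]))
        boxes = np.concatenate(extra)
        boxes[:, 0::2] = np.clip(boxes[:, 0::2], 0, w)
        boxes[:, 1::2] = np.clip(boxes[:, 1::2], 0, h)
        if len(boxes) > cfg.roi_samples:
            boxes = boxes[rng.permutation(len(boxes))[:cfg.roi_samples]]
        labels = np.zeros(len(boxes), dtype=int)
        tgt = np.zeros((len(boxes), 4))
        if len(s["boxes"]):
            iou = box_iou(boxes, s["boxes"])
            best = iou.argmax(axis=1)
            fg = iou.max(axis=1) >= 0.5
            labels[fg] = s["labels"][best[fg]]
            tgt[fg] = encode_deltas(s["boxes"][best[fg]], boxes[fg])
        rf, back = nn.roi_align(feats["s4"][bi], boxes / 4.0, cfg.roi_size)
        roi_feats.append(rf)
        all_labels.append(labels)
        all_tgt.append(tgt)
        backs.append(back)
        counts.append(len(boxes))

    rf_all = np.concatenate(roi_feats).astype(np.float32)
    labels_all = np.concatenate(all_labels)
    tgt_all = np.concatenate(all_tgt)
    out = det.roi_head.forward(rf_all, training=True)  # (R, C + 4)
    cls_loss, dcls = nn.softmax_cross_entropy(out[:, :cfg.n_classes],
                                              labels_all)
    dout = np.zeros_like(out)
    dout[:, :cfg.n_classes] = dcls
    fg = labels_all > 0
    roi_box_loss = 0.0
    if fg.any():
        roi_box_loss, dbox = nn.smooth_l1(out[fg, cfg.n_classes:],
                                          tgt_all[fg], beta=0.2)
        dout[fg, cfg.n_classes:] = dbox
    droi = det.roi_head.backward(dout, rf_all.shape)

    dp8 = det.rpn.backward(drpn)
    dp4 = np.zeros_like(feats["s4"])
    ofs = 0
    for bi in range(len(samples)):
        n = counts[bi]
        if n:
            dp4[bi] += backs[bi](droi[ofs:ofs + n])
        ofs += n
    det.backbone.backward({"s4": dp4, "s8": dp8})
    losses.update({"class": cls_loss, "roi_box": roi_box_loss})
    return losses


def keypoint_step(det: Detector, samples: list[dict],
                  rng: np.random.Generator,
                  sigma: float | None = None) -> dict:
    """One optimisation step of the keypoint phase on a mini-batch.

    Uses ground-truth boxes to place the keypoint windows (standard R-CNN
    practice for keypoint-head training); the RPN objectness loss keeps the
    shared backbone aligned with the frozen detection stage.
    """
    cfg = det.config
    imgs = np.stack([s["image"] for s in samples])[:, None].astype(np.float32)
    # frozen-BN backbone pass: running statistics, as detection fine-tuning
    # conventionally does, so the keypoint head sees a stable feature scale
    # (conv/BN weights still receive gradients and updates)
    feats = det.backbone.forward(imgs, training=False)
    rpn_out = det.rpn.forward(feats["s8"], training=False)
    losses, drpn = _rpn_losses(det, rpn_out, samples, rng, with_box=False)

    k = cfg.heatmap_size
    nk = cfg.n_keypoints
    wins, origins, owners, boxes_used, others_used, tgts, rels, valids = \
        [], [], [], [], [], [], [], []
    for bi, s in enumerate(samples):
        for mi, box in enumerate(s["boxes"]):
            if s["labels"][mi] != 1 or s["keypoints"][mi] is None:
                continue
            others = [b for j, b in enumerate(s["boxes"]) if j != mi]
            # jitter the window/mask box: at inference the window comes
            # from a proposal, not the exact ground-truth box, and edge
            # re-decodes shift windows by up to ~16 px
            box = np.asarray(box, dtype=float) + rng.uniform(-12, 12, 4)
            x0, y0 = det.kp_window_origin(box)
            wins.append(det.crop_kp_window(feats["s2"][bi], x0, y0, box,
                                           others))
            origins.append((x0, y0))
            owners.append(bi)
            boxes_used.append(box)
            others_used.append(others)
            ks = s["keypoints"][mi]
            rel = ks.coords - (x0, y0)
            bins = np.round(rel).astype(int)
            valid = ((ks.visibility > 0) & (bins[:, 0] >= 0) & (bins[:, 0] < k)
                     & (bins[:, 1] >= 0) & (bins[:, 1] < k))
            tgts.append(np.clip(bins, 0, k - 1))
            rels.append(rel)
            valids.append(valid)
    if not wins:
        det.backbone.backward({"s8": det.rpn.backward(drpn)})
        losses["keypoint"] = 0.0
        return losses

    win_batch = np.stack(wins).astype(np.float32)
    logits = det.kp_head.forward(win_batch, training=True)
    hm = logits[:, :nk]
    tgt = np.stack(tgts)
    rel = np.stack(rels)
    valid = np.stack(valids)
    if cfg.keypoint_supervision == "heatmap":
        kp_loss, dhm = nn.spatial_softmax_cross_entropy(
            hm, tgt, valid,
            sigma=cfg.heatmap_target_sigma if sigma is None else sigma)
    else:
        kp_loss, dhm = _coordinate_loss(hm, tgt.astype(float), valid)
    dlogits = np.zeros_like(logits)
    dlogits[:, :nk] = dhm
    losses["keypoint"] = kp_loss

    if cfg.keypoint_offsets:
        # per-bin offset regression: bins near the target learn the exact
        # continuous displacement to the keypoint
        r = logits.shape[0]
        off = logits[:, nk:].reshape(r, nk, 2, k, k)
        doff = np.zeros_like(off)
        chunks = []
        for dxb in range(-2, 3):
            for dyb in range(-2, 3):
                bx = tgt[..., 0] + dxb
                by = tgt[..., 1] + dyb
                ok = valid & (bx >= 0) & (bx < k) & (by >= 0) & (by < k)
                if not ok.any():
                    continue
                ri, ki = np.nonzero(ok)
                bins = np.stack([bx[ok], by[ok]], axis=1)
                chunks.append((ri, ki, bins,
                               off[ri, ki, :, by[ok], bx[ok]],
                               rel[ri, ki] - bins))
        if chunks:
            pred = np.concatenate([c[3] for c in chunks])
            target = np.concatenate([c[4] for c in chunks])
            off_loss, dpred = nn.smooth_l1(pred, target, beta=0.25)
            ofs = 0
            for ri, ki, bins, p, _t in chunks:
                n = len(ri)
                doff[ri, ki, :, bins[:, 1], bins[:, 0]] = dpred[ofs:ofs + n]
                ofs += n
            dlogits[:, nk:] = doff.reshape(r, 2 * nk, k, k)
            losses["keypoint_offset"] = off_loss

    dwins = det.kp_head.backward(dlogits)
    dp2 = np.zeros_like(feats["s2"])
    for ri, (x0, y0) in enumerate(origins):
        det.paste_kp_window_grad(dp2[owners[ri]], dwins[ri], x0, y0,
                                 boxes_used[ri], others_used[ri])
    dp8 = det.rpn.backward(drpn)
    det.backbone.backward({"s2": dp2, "s8": dp8})
    return losses


def _coordinate_loss(logits: np.ndarray, gt: np.ndarray, valid: np.ndarray):
    """Squared-coordinate keypoint loss through a soft-argmax decode.

    Per box, squared distances summed over keypoints, averaged over boxes
    (the divisor is the box count, not box*keypoint).
    """
    r, k, hh, ww = logits.shape
    flat = logits.reshape(r * k, hh * ww)
    p = nn.softmax(flat, axis=1)
    gx, gy = np.meshgrid(np.arange(ww, dtype=float),
                         np.arange(hh, dtype=float))
    grid = np.stack([gx.reshape(-1), gy.reshape(-1)], axis=1)  # (HW, 2)
    pred = p @ grid  # (r*k, 2)
    diff = (pred - gt.reshape(r * k, 2)) * valid.reshape(-1, 1)
    loss = float(np.sum(diff ** 2) / r)
    dpred = 2.0 * diff / r  # (r*k, 2)
    inner = grid @ dpred.T  # (HW, r*k)
    center = np.sum(pred * dpred, axis=1)  # (r*k,)
    dflat = p * (inner.T - center[:, None])
    return loss, dflat.reshape(r, k, hh, ww).astype(np.float32)


# ------------------------------------------------------------ evaluation

def evaluate_detection(det: Detector, samples: list[dict]) -> float:
    """Validation objectness accuracy: exact mouse-count agreement."""
    preds = predict(det, [s["image"] for s in samples])
    kept = [filter_detections(p, det.config.score_threshold) for p in preds]
    truth = [len(s["boxes"]) for s in samples]
    return objectness_accuracy(truth, kept)


def evaluate_keypoints(det: Detector, samples: list[dict],
                       return_median: bool = False):
    """Validation keypoint MSE over IoU-matched detections (None if no match).

    With ``return_median`` also returns the median squared error — a robust
    companion used for plateau detection, where a single flickering outlier
    should not stop training.
    """
    preds = predict(det, [s["image"] for s in samples])
    errs = []
    for s, dets in zip(samples, preds):
        kept = filter_detections(dets, det.config.score_threshold)
        if not kept or not len(s["boxes"]):
            continue
        pairs = match_by_iou(s["boxes"], np.array([d.box for d in kept]))
        for gi, pi in pairs:
            g = s["keypoints"][gi]
            p = kept[pi].keypoints
            vis = (g.visibility > 0) & (p.visibility > 0)
            errs.extend(np.sum((g.coords[vis] - p.coords[vis]) ** 2, axis=1))
    if not errs:
        return (None, None) if return_median else None
    errs = np.asarray(errs)
    if return_median:
        return float(errs.mean()), float(np.median(errs))
    return float(errs.mean())


# --------------------------------------------------------------- phases

def _merged(groups: dict, names) -> dict:
    out = {}
    for n in names:
        out.update(groups[n])
    return out


def _run_phase(det: Detector, data: dict, schedule: TrainingSchedule,
               phase: str, budget: int, rng: np.random.Generator,
               epoch_offset: int = 0) -> TrainingHistory:
    schedule.validate()
    train = data["train"]
    val = data.get("val", [])
    if not train:
        raise ConfigError(f"{phase} phase needs a non-empty training set")
    head = "roi_header" if phase == "detection" else "keypoint_header"
    groups = det.param_groups()
    grad_groups = det.grad_groups()
    opts = [nn.Adam(groups[head], grad_groups[head], lr=schedule.base_lr),
            nn.Adam(groups["backbone"], grad_groups["backbone"],
                    lr=schedule.base_lr)]
    # the shared backbone takes smaller steps in the keypoint phase so the
    # frozen ROI header keeps seeing the features it was trained on
    backbone_scale = 1.0 if phase == "detection" \
        else schedule.kp_backbone_lr_scale
    step_fn = detection_step if phase == "detection" else keypoint_step

    history = TrainingHistory()
    best = -np.inf
    stale = 0
    for epoch in range(budget):
        lr = schedule.lr_at(epoch_offset + epoch, budget)
        opts[0].lr = lr
        opts[1].lr = lr * backbone_scale
        order = rng.permutation(len(train))
        losses_sum: dict[str, float] = {}
        n_batches = 0
        step_kwargs = {}
        if phase == "keypoint" and det.config.keypoint_supervision == "heatmap":
            # anneal the soft-label width: broad targets early spread the
            # gradient, narrow targets late sharpen the blobs for sub-pixel
            # centroid decoding
            frac = epoch / max(budget - 1, 1)
            step_kwargs["sigma"] = (det.config.heatmap_target_sigma
                                    + frac * (det.config.heatmap_target_sigma_end
                                              - det.config.heatmap_target_sigma))
        for start in range(0, len(order), schedule.batch_size):
            batch = [train[i] for i in order[start:start + schedule.batch_size]]
            if schedule.augment is not None:
                batch = [_augment_sample(s, schedule.augment, rng)
                         for s in batch]
            det.zero_grad()
            losses = step_fn(det, batch, rng, **step_kwargs)
            for k, v in losses.items():
                if not np.isfinite(v):
                    raise TrainingDivergedError(
                        f"non-finite {k} loss in {phase} epoch {epoch}, "
                        f"batch starting at sample {start}")
                losses_sum[k] = losses_sum.get(k, 0.0) + float(v)
            n_batches += 1
            for opt in opts:
                opt.step()
        det.zero_grad()
        mean_losses = {k: v / max(n_batches, 1) for k, v in losses_sum.items()}
        # periodic validation runs without the inference-time flip ensemble
        # and window-refine pass (they would triple validation cost); the
        # recorded numbers are therefore slightly pessimistic
        saved = (det.config.flip_tta, det.config.window_refine)
        det.config.flip_tta = det.config.window_refine = False
        try:
            acc = evaluate_detection(det, val) if val else None
            kmse = kmed = None
            if val and phase == "keypoint":
                kmse, kmed = evaluate_keypoints(det, val, return_median=True)
        finally:
            det.config.flip_tta, det.config.window_refine = saved
        history.append(phase=phase, epoch=epoch_offset + epoch,
                       lr=lr, losses=mean_losses,
                       val_objectness_accuracy=acc, val_keypoint_mse=kmse,
                       val_keypoint_mse_median=kmed)
        metric = None
        if phase == "detection" and acc is not None:
            metric = acc
        elif phase == "keypoint" and kmed is not None:
            metric = -kmed  # robust to a single flickering outlier
        if metric is not None:
            if metric > best + schedule.min_improvement:
                best = metric
                stale = 0
            else:
                stale += 1
                if stale >= schedule.patience:
                    break
    return history


def train_detection_phase(det: Detector, detection_data: dict,
                          schedule: TrainingSchedule,
                          rng: np.random.Generator | None = None,
                          epoch_offset: int = 0) -> TrainingHistory:
    """Freeze the keypoint header; train backbone + ROI header."""
    rng = rng or np.random.default_rng(schedule.seed)
    return _run_phase(det, detection_data, schedule, "detection",
                      schedule.detection_epochs, rng, epoch_offset)


def train_keypoint_phase(det: Detector, keypoint_data: dict,
                         schedule: TrainingSchedule,
                         rng: np.random.Generator | None = None,
                         epoch_offset: int = 0) -> TrainingHistory:
    """Freeze the ROI header; train backbone + keypoint header."""
    rng = rng or np.random.default_rng(schedule.seed)
    return _run_phase(det, keypoint_data, schedule, "keypoint",
                      schedule.keypoint_epochs, rng, epoch_offset)


def alternate_train(det: Detector, detection_data: dict, keypoint_data: dict,
                    schedule: TrainingSchedule,
                    checkpoint_path=None) -> tuple[Detector, TrainingHistory]:
    """Alternate detection and keypoint phases (``schedule.cycles`` rounds)."""
    if not detection_data.get("train") or not keypoint_data.get("train"):
        raise ConfigError("both datasets must be non-empty")
    rng = np.random.default_rng(schedule.seed)
    history = TrainingHistory()
    for _cycle in range(schedule.cycles):
        history.extend(train_detection_phase(det, detection_data, schedule,
                                             rng))
        history.extend(train_keypoint_phase(det, keypoint_data, schedule,
                                            rng))
    if checkpoint_path is not None:
        save_checkpoint(det, checkpoint_path)
    return det, history
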