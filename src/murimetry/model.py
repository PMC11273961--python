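"""Two-stage keypoint detector: FPN backbone, RPN + ROI classification stage,
and a heatmap keypoint head.

Architecture
------------
* Backbone: a conv/BN/ReLU pyramid with lateral FPN connections producing
  feature levels at strides 2, 4 and 8. The ``tiny_fpn`` profile is small
  enough to train on one CPU; ``efficientnet_b3_fpn`` instantiates the same
  design at B3-like depth/width for full-scale use.
* Region proposal head (stride-8 level): per-cell objectness logit and box
  deltas against a single square anchor sized for an adult mouse.
* ROI classification head: bilinear ROI-align of the stride-8 features to a
  fixed grid, then an MLP giving class probabilities (background / top-view
  mouse / optional non-top-view) and a box refinement.
* Keypoint head: a fixed-size, integer-aligned window around each detection
  is cropped from the stride-2 level and passed through
  ``keypoint_head_blocks`` conv+BN+ReLU blocks and one transposed
  convolution, yielding one heatmap per keypoint in 1:1 registration with
  image pixels. Decoding is heatmap argmax with parabolic sub-pixel
  refinement.

The three parameter groups {backbone, roi_header, keypoint_header} are
disjoint and cover every trainable parameter; the training protocol freezes
one header at a time by excluding its group from the optimizer.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import nn
from .errors import ConfigError
from .io import KeypointSet

BACKBONES = {
    # name: (stem_ch, [(width, depth)] per further stride-2 stage, fpn_ch);
    # the stride-2 stem output is the first pyramid level
    "tiny_fpn": (8, [(16, 1), (32, 1)], 8),
    "efficientnet_b3_fpn": (40, [(96, 3), (232, 4)], 64),
}


@dataclass
class ModelConfig:
    backbone: str = "tiny_fpn"
    n_classes: int = 2  # background + top-view mouse (+ optional non-top-view)
    n_keypoints: int = 12
    keypoint_head_blocks: int = 8
    keypoint_head_channels: int = 8
    heatmap_size: int = 112  # keypoint window side in px (even)
    score_threshold: float = 0.5
    min_detection_score: float = 0.05
    anchor_size: float = 96.0
    rpn_pos_iou: float = 0.5
    rpn_neg_iou: float = 0.3
    rpn_pos_samples: int = 16
    rpn_neg_samples: int = 32
    rpn_pre_nms: int = 64
    rpn_post_nms: int = 8
    rpn_nms_iou: float = 0.5
    roi_size: int = 7
    roi_hidden: int = 64
    roi_samples: int = 16
    detection_nms_iou: float = 0.1  # mice never overlap in dorsal scans
    subpixel: bool = True
    keypoint_offsets: bool = True  # per-bin continuous offset regression
    structured_decode: bool = True  # skeleton-consistent peak picking
    tie_joints: bool = True  # decode exactly-articulated joints as one node
    decode_adjacency_radius: float = 9.0
    decode_exclusion_radius: float = 4.0
    window_mask_margin: float = 16.0  # feature mask beyond the box, px
    subpixel_mode: str = "offset"  # or "centroid"
    flip_tta: bool = True  # average logits with the mirrored window
    window_refine: bool = True  # re-decode with a keypoint-recentred window
    keypoint_supervision: str = "heatmap"  # or "coordinate" (squared-error)
    heatmap_target_sigma: float = 1.5  # soft-label width in bins (0 = one-hot)
    heatmap_target_sigma_end: float = 0.7  # annealed width at end of phase
    resize_longest: int | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.backbone not in BACKBONES:
            raise ConfigError(f"unknown backbone {self.backbone!r}; "
                              f"choose from {sorted(BACKBONES)}")
        if self.keypoint_head_blocks < 1:
            raise ConfigError("keypoint_head_blocks must be >= 1")
        if self.n_keypoints != 12:
            raise ConfigError("the measurement scheme requires 12 keypoints")
        if not 0.0 <= self.score_threshold <= 1.0:
            raise ConfigError("score_threshold must be in [0, 1]")
        if self.heatmap_size % 2 or self.heatmap_size < 32:
            raise ConfigError("heatmap_size must be an even integer >= 32")
        if self.keypoint_supervision not in ("heatmap", "coordinate"):
            raise ConfigError("keypoint_supervision must be 'heatmap' or "
                              "'coordinate'")


@dataclass
class MouseDetection:
    """One detected mouse: box, top-view probability, scored keypoints."""

    box: np.ndarray  # (4,) xyxy
    top_view_prob: float
    keypoints: KeypointSet

    def __post_init__(self):
        if not 0.0 <= self.top_view_prob <= 1.0:
            raise ConfigError("top_view_prob must be in [0, 1]")


# ------------------------------------------------------------- backbone

class FPNBackbone:
    """Stride-2 stem + two stride-2 stages; FPN over the three levels."""

    def __init__(self, stem_ch, stages, fpn_ch, rng):
        self.stem = nn.Sequential(nn.Conv2d(1, stem_ch, 3, 2, rng=rng),
                                  nn.BatchNorm2d(stem_ch), nn.ReLU())
        self.stages = []
        in_ch = stem_ch
        for width, depth in stages:
            layers = []
            for d in range(depth):
                layers += [nn.Conv2d(in_ch if d == 0 else width, width, 3,
                                     2 if d == 0 else 1, rng=rng),
                           nn.BatchNorm2d(width), nn.ReLU()]
            self.stages.append(nn.Sequential(*layers))
            in_ch = width
        widths = [stem_ch] + [w for w, _ in stages]
        self.laterals = [nn.Conv2d(w, fpn_ch, 1, 1, pad=0, rng=rng)
                         for w in widths]
        self.smooths = [nn.Sequential(nn.Conv2d(fpn_ch, fpn_ch, 3, 1, rng=rng))
                        for _ in widths]
        self.fpn_ch = fpn_ch

    def modules(self):
        mods = {"stem": self.stem}
        for i, s in enumerate(self.stages):
            mods[f"stage{i + 1}"] = s
        for i, l in enumerate(self.laterals):
            mods[f"lateral{i + 1}"] = l
        for i, s in enumerate(self.smooths):
            mods[f"smooth{i + 1}"] = s
        return mods

    def forward(self, x, training=False):
        c = self.stem.forward(x, training)
        cs = [c]
        for stage in self.stages:
            c = stage.forward(c, training)
            cs.append(c)
        t = None
        ts = [None] * len(cs)
        for i in reversed(range(len(cs))):
            lat = self.laterals[i].forward(cs[i], training)
            t = lat if t is None else lat + nn.upsample2x_nearest(t)
            ts[i] = t
        ps = [self.smooths[i].forward(ts[i], training) for i in range(len(ts))]
        return {"s2": ps[0], "s4": ps[1], "s8": ps[2]}

    def backward(self, dps: dict) -> None:
        # top-down FPN gradients: high-resolution levels feed lower ones
        dts = []
        prev = None
        for i, key in enumerate(("s2", "s4", "s8")):
            d = dps.get(key)
            dt = None if d is None else self.smooths[i].backward(d)
            if prev is not None:
                extra = nn.upsample2x_nearest_backward(prev)
                dt = extra if dt is None else dt + extra
            dts.append(dt)
            prev = dt
        dcs = [None if dts[i] is None else self.laterals[i].backward(dts[i])
               for i in range(3)]
        dc = None
        for i in reversed(range(len(self.stages))):  # levels 1..n -> stages
            contrib = dcs[i + 1]
            if dc is None:
                dc = contrib
            elif contrib is not None:
                dc = dc + contrib
            if dc is not None:
                dc = self.stages[i].backward(dc)
        if dcs[0] is not None:
            dc = dcs[0] if dc is None else dc + dcs[0]
        if dc is not None:
            self.stem.backward(dc)


# ---------------------------------------------------------------- heads

class RPNHead:
    """Separate objectness and box-delta towers over the stride-8 level.

    Keeping the towers separate stops the (dense, low-variance) box-delta
    gradients from washing out the objectness features.
    """

    def __init__(self, fpn_ch, rng):
        self.obj = nn.Sequential(nn.Conv2d(fpn_ch, fpn_ch, 3, 1, rng=rng),
                                 nn.ReLU(),
                                 nn.Conv2d(fpn_ch, 1, 1, 1, pad=0, rng=rng))
        self.box = nn.Sequential(nn.Conv2d(fpn_ch, fpn_ch, 3, 1, rng=rng),
                                 nn.ReLU(),
                                 nn.Conv2d(fpn_ch, 4, 1, 1, pad=0, rng=rng))
        self.net = _Pair(self.obj, self.box)  # parameter container

    def forward(self, p8, training=False):
        o = self.obj.forward(p8, training)
        b = self.box.forward(p8, training)
        return np.concatenate([o, b], axis=1)

    def backward(self, dout):
        return self.obj.backward(dout[:, :1]) + self.box.backward(dout[:, 1:])


class _Pair:
    """Expose two sequentials as one named parameter collection."""

    def __init__(self, a, b):
        self.a, self.b = a, b

    def params(self):
        return {**{f"obj.{k}": v for k, v in self.a.params().items()},
                **{f"box.{k}": v for k, v in self.b.params().items()}}

    def grads(self):
        return {**{f"obj.{k}": v for k, v in self.a.grads().items()},
                **{f"box.{k}": v for k, v in self.b.grads().items()}}

    def buffers(self):
        return {**{f"obj.{k}": v for k, v in self.a.buffers().items()},
                **{f"box.{k}": v for k, v in self.b.buffers().items()}}


class ROIHead:
    """Classification + box refinement over stride-4 ROI-aligned features."""

    def __init__(self, fpn_ch, roi_size, hidden, n_classes, rng):
        self.roi_size = roi_size
        self.n_classes = n_classes
        self.net = nn.Sequential(nn.Linear(fpn_ch * roi_size * roi_size,
                                           2 * hidden, rng=rng),
                                 nn.ReLU(),
                                 nn.Linear(2 * hidden, hidden, rng=rng),
                                 nn.ReLU(),
                                 nn.Linear(hidden, n_classes + 4, rng=rng))

    def forward(self, roi_feats, training=False):
        r = roi_feats.shape[0]
        return self.net.forward(roi_feats.reshape(r, -1), training)

    def backward(self, dout, feat_shape):
        return self.net.backward(dout).reshape(feat_shape)


class KeypointHead:
    """``n_blocks`` conv+BN+ReLU blocks then one transposed convolution.

    The input window is mouse-centred, so two coordinate channels are
    appended to the cropped features: they give the translation-equivariant
    convolutions the absolute within-window position needed to tell left
    from right and one bone's endpoint from another's.
    """

    def __init__(self, fpn_ch, cfg: ModelConfig, rng):
        ch = cfg.keypoint_head_channels
        layers = []
        for b in range(cfg.keypoint_head_blocks):
            layers += [nn.Conv2d(fpn_ch + 2 if b == 0 else ch, ch, 3, 1,
                                 rng=rng),
                       nn.BatchNorm2d(ch), nn.ReLU()]
        self.n_blocks = cfg.keypoint_head_blocks
        # channel layout: K heatmap logits [+ 2K per-bin (dx, dy) offsets]
        out_ch = cfg.n_keypoints * (3 if cfg.keypoint_offsets else 1)
        self.deconv = nn.ConvTranspose2d(ch, out_ch, 4, 2, 1, rng=rng)
        self.net = nn.Sequential(*layers, self.deconv)

    def forward(self, x, training=False):
        return self.net.forward(x, training)

    def backward(self, dout):
        return self.net.backward(dout)


# ------------------------------------------------------------ box utils

def box_iou(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between (M,4) and (N,4) xyxy boxes."""
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    tl = np.maximum(a[:, None, :2], b[None, :, :2])
    br = np.minimum(a[:, None, 2:], b[None, :, 2:])
    wh = np.clip(br - tl, 0, None)
    inter = wh[..., 0] * wh[..., 1]
    area_a = np.clip(a[:, 2] - a[:, 0], 0, None) * np.clip(a[:, 3] - a[:, 1], 0, None)
    area_b = np.clip(b[:, 2] - b[:, 0], 0, None) * np.clip(b[:, 3] - b[:, 1], 0, None)
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / np.maximum(union, 1e-12), 0.0)


def nms(boxes: np.ndarray, scores: np.ndarray, iou_thr: float) -> list[int]:
    order = list(np.argsort(-scores))
    keep = []
    while order:
        i = order.pop(0)
        keep.append(i)
        if not order:
            break
        ious = box_iou(boxes[i], boxes[order])[0]
        order = [o for o, v in zip(order, ious) if v <= iou_thr]
    return keep


def encode_deltas(boxes, refs):
    """(x0,y0,x1,y1) boxes -> (dx,dy,dw,dh) against reference boxes."""
    bw = refs[:, 2] - refs[:, 0]
    bh = refs[:, 3] - refs[:, 1]
    cx = (refs[:, 0] + refs[:, 2]) / 2
    cy = (refs[:, 1] + refs[:, 3]) / 2
    gw = np.clip(boxes[:, 2] - boxes[:, 0], 1e-3, None)
    gh = np.clip(boxes[:, 3] - boxes[:, 1], 1e-3, None)
    gx = (boxes[:, 0] + boxes[:, 2]) / 2
    gy = (boxes[:, 1] + boxes[:, 3]) / 2
    return np.stack([(gx - cx) / bw, (gy - cy) / bh,
                     np.log(gw / bw), np.log(gh / bh)], axis=1)


def decode_deltas(deltas, refs):
    bw = refs[:, 2] - refs[:, 0]
    bh = refs[:, 3] - refs[:, 1]
    cx = (refs[:, 0] + refs[:, 2]) / 2
    cy = (refs[:, 1] + refs[:, 3]) / 2
    d = np.clip(deltas, -4.0, 4.0)
    gx = cx + d[:, 0] * bw
    gy = cy + d[:, 1] * bh
    gw = bw * np.exp(d[:, 2])
    gh = bh * np.exp(d[:, 3])
    return np.stack([gx - gw / 2, gy - gh / 2, gx + gw / 2, gy + gh / 2], axis=1)


# -------------------------------------------------------------- detector

class Detector:
    def __init__(self, config: ModelConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        stem, stages, fpn_ch = BACKBONES[config.backbone]
        self.backbone = FPNBackbone(stem, stages, fpn_ch, rng)
        self.rpn = RPNHead(fpn_ch, rng)
        self.roi_head = ROIHead(fpn_ch, config.roi_size, config.roi_hidden,
                                config.n_classes, rng)
        self.kp_head = KeypointHead(fpn_ch, config, rng)

    # ---- parameter bookkeeping

    def param_groups(self) -> dict[str, dict[str, np.ndarray]]:
        groups = {"backbone": {}, "roi_header": {}, "keypoint_header": {}}
        for name, mod in self.backbone.modules().items():
            for k, v in mod.params().items():
                groups["backbone"][f"backbone.{name}.{k}"] = v
        for k, v in self.rpn.net.params().items():
            groups["roi_header"][f"rpn.{k}"] = v
        for k, v in self.roi_head.net.params().items():
            groups["roi_header"][f"roi.{k}"] = v
        for k, v in self.kp_head.net.params().items():
            groups["keypoint_header"][f"kp.{k}"] = v
        return groups

    def grad_groups(self) -> dict[str, dict[str, np.ndarray]]:
        groups = {"backbone": {}, "roi_header": {}, "keypoint_header": {}}
        for name, mod in self.backbone.modules().items():
            for k, v in mod.grads().items():
                groups["backbone"][f"backbone.{name}.{k}"] = v
        for k, v in self.rpn.net.grads().items():
            groups["roi_header"][f"rpn.{k}"] = v
        for k, v in self.roi_head.net.grads().items():
            groups["roi_header"][f"roi.{k}"] = v
        for k, v in self.kp_head.net.grads().items():
            groups["keypoint_header"][f"kp.{k}"] = v
        return groups

    def buffers(self) -> dict[str, np.ndarray]:
        out = {}
        for name, mod in self.backbone.modules().items():
            for k, v in mod.buffers().items():
                out[f"backbone.{name}.{k}"] = v
        for k, v in self.kp_head.net.buffers().items():
            out[f"kp.{k}"] = v
        return out

    def all_params(self) -> dict[str, np.ndarray]:
        out = {}
        for g in self.param_groups().values():
            out.update(g)
        return out

    def zero_grad(self) -> None:
        for g in self.grad_groups().values():
            for arr in g.values():
                arr[...] = 0.0

    # ---- geometry helpers

    def anchor_grid(self, h: int, w: int):
        gh, gw = h // 8, w // 8
        ys, xs = np.mgrid[0:gh, 0:gw]
        cx = xs.reshape(-1) * 8.0 + 4.0
        cy = ys.reshape(-1) * 8.0 + 4.0
        a = self.config.anchor_size / 2
        return np.stack([cx - a, cy - a, cx + a, cy + a], axis=1), gh, gw

    def kp_window_origin(self, box) -> tuple[int, int]:
        k = self.config.heatmap_size
        cx = (box[0] + box[2]) / 2.0
        cy = (box[1] + box[3]) / 2.0
        x0 = int(round(cx - k / 2))
        y0 = int(round(cy - k / 2))
        return x0 - x0 % 2, y0 - y0 % 2

    def _window_box_mask(self, x0: int, y0: int, box,
                         others=None) -> np.ndarray | None:
        """Boolean (half, half) mask of usable feature bins.

        Wide margin around the detection's own box (box regression is only
        accurate to a few px) minus the other detections' boxes (shrunk
        slightly), so a neighbouring mouse is suppressed without risking
        cutting off this mouse's own extremities.
        """
        if box is None:
            return None
        half = self.config.heatmap_size // 2
        m = self.config.window_mask_margin
        mask = np.zeros((half, half), dtype=bool)

        def bins(b, pad):
            return (int(np.floor((b[0] - pad - x0) / 2)),
                    int(np.floor((b[1] - pad - y0) / 2)),
                    int(np.ceil((b[2] + pad - x0) / 2)),
                    int(np.ceil((b[3] + pad - y0) / 2)))

        bx0, by0, bx1, by1 = bins(box, m)
        mask[max(by0, 0):max(by1, 0), max(bx0, 0):max(bx1, 0)] = True
        for other in others or []:
            ox0, oy0, ox1, oy1 = bins(other, -4.0)  # shrink by 4 px
            mask[max(oy0, 0):max(oy1, 0), max(ox0, 0):max(ox1, 0)] = False
        return mask

    def crop_kp_window(self, p2: np.ndarray, x0: int, y0: int,
                       box=None, others=None) -> np.ndarray:
        """Crop the stride-2 window (zero padded at image borders), zero
        features outside the detection box (so a neighbouring mouse cannot
        attract a keypoint), and append normalized coordinate channels."""
        half = self.config.heatmap_size // 2
        c, hf, wf = p2.shape
        fx0, fy0 = x0 // 2, y0 // 2
        out = np.zeros((c + 2, half, half), dtype=p2.dtype)
        sx0, sy0 = max(fx0, 0), max(fy0, 0)
        sx1, sy1 = min(fx0 + half, wf), min(fy0 + half, hf)
        if sx1 > sx0 and sy1 > sy0:
            out[:c, sy0 - fy0:sy1 - fy0, sx0 - fx0:sx1 - fx0] = \
                p2[:, sy0:sy1, sx0:sx1]
        mask = self._window_box_mask(x0, y0, box, others)
        if mask is not None:
            out[:c] *= mask
        ramp = np.linspace(-1.0, 1.0, half, dtype=p2.dtype)
        out[c] = ramp[None, :]
        out[c + 1] = ramp[:, None]
        return out

    def paste_kp_window_grad(self, dp2: np.ndarray, dwin: np.ndarray,
                             x0: int, y0: int, box=None,
                             others=None) -> None:
        half = self.config.heatmap_size // 2
        _, hf, wf = dp2.shape
        fx0, fy0 = x0 // 2, y0 // 2
        sx0, sy0 = max(fx0, 0), max(fy0, 0)
        sx1, sy1 = min(fx0 + half, wf), min(fy0 + half, hf)
        c = dp2.shape[0]
        if sx1 <= sx0 or sy1 <= sy0:
            return
        d = dwin[:c]  # coord channels carry no feature grad
        mask = self._window_box_mask(x0, y0, box, others)
        if mask is not None:
            d = d * mask
        dp2[:, sy0:sy1, sx0:sx1] += \
            d[:, sy0 - fy0:sy1 - fy0, sx0 - fx0:sx1 - fx0]

    # ---- inference

    def propose(self, feats, h, w):
        """RPN proposals for a single image's features."""
        cfg = self.config
        rpn_out = self.rpn.forward(feats["s8"], training=False)[0]
        anchors, gh, gw = self.anchor_grid(h, w)
        logit = rpn_out[0].reshape(-1)  # rank by logits: sigmoid saturates
        deltas = rpn_out[1:5].reshape(4, -1).T
        order = np.argsort(-logit)[:cfg.rpn_pre_nms]
        boxes = decode_deltas(deltas[order], anchors[order])
        boxes[:, 0::2] = np.clip(boxes[:, 0::2], 0, w)
        boxes[:, 1::2] = np.clip(boxes[:, 1::2], 0, h)
        ok = ((boxes[:, 2] - boxes[:, 0] > 8) & (boxes[:, 3] - boxes[:, 1] > 8))
        boxes, scores = boxes[ok], logit[order][ok]
        keep = nms(boxes, scores, cfg.rpn_nms_iou)[:cfg.rpn_post_nms]
        # box voting: the score-weighted mean of all overlapping proposals
        # halves single-anchor regression noise
        voted = []
        for i in keep:
            sel = box_iou(boxes[i], boxes)[0] > 0.5
            wgt = nn.sigmoid(scores[sel])
            voted.append((boxes[sel] * wgt[:, None]).sum(0) / wgt.sum())
        return np.array(voted), nn.sigmoid(scores[keep])

    def detect_image(self, image: np.ndarray) -> list[MouseDetection]:
        cfg = self.config
        if image.ndim != 2:
            raise ConfigError("predict expects 2-D grayscale rasters")
        scale = 1.0
        if cfg.resize_longest and max(image.shape) != cfg.resize_longest:
            from scipy.ndimage import zoom

            scale = cfg.resize_longest / max(image.shape)
            image = zoom(image, scale, order=1)
        h, w = image.shape
        x = np.asarray(image, dtype=np.float32)[None, None]
        feats = self.backbone.forward(x, training=False)
        s2_views = {(False, False): feats["s2"]}
        if cfg.flip_tta:
            # mirror-ensemble views, each through the backbone (convs do
            # not commute with mirroring, so features must be recomputed)
            for fx, fy in ((True, False), (False, True), (True, True)):
                xv = x
                if fx:
                    xv = xv[:, :, :, ::-1]
                if fy:
                    xv = xv[:, :, ::-1, :]
                s2_views[(fx, fy)] = self.backbone.forward(
                    np.ascontiguousarray(xv), training=False)["s2"]
        proposals, _ = self.propose(feats, h, w)
        if len(proposals) == 0:
            return []
        roi_feats, _ = nn.roi_align(feats["s4"][0], proposals / 4.0,
                                    cfg.roi_size)
        out = self.roi_head.forward(roi_feats, training=False)
        probs = nn.softmax(out[:, :cfg.n_classes], axis=1)
        top_prob = probs[:, 1]
        # duplicates are resolved on the proposal boxes: the RPN's
        # per-anchor regression is the detector's most reliable localizer
        # at this scale, and ground-truth animals never overlap, so a low
        # NMS threshold cleanly removes shifted copies
        ok = ((top_prob >= cfg.min_detection_score)
              & (proposals[:, 2] - proposals[:, 0] >= 16)
              & (proposals[:, 3] - proposals[:, 1] >= 16))
        boxes, top_prob = proposals[ok], top_prob[ok]
        if len(boxes) == 0:
            return []
        keep = nms(boxes, top_prob, cfg.detection_nms_iou)
        boxes, top_prob = boxes[keep], top_prob[keep]

        detections = []
        for di, (box, prob) in enumerate(zip(boxes, top_prob)):
            others = [boxes[j] for j in range(len(boxes)) if j != di]
            coords, scores = self._decode_window(s2_views, box,
                                                 others, w, h)
            if cfg.window_refine:
                # keypoints hugging a window edge mean the window probably
                # truncates the animal (the box centre sits off the true
                # centre); shift the window toward that edge and re-decode
                kk = cfg.heatmap_size
                x0a, y0a = self.kp_window_origin(box)
                rel = coords - (x0a, y0a)
                sx = -16 if rel[:, 0].min() < 6 else \
                    (16 if rel[:, 0].max() > kk - 6 else 0)
                sy = -16 if rel[:, 1].min() < 6 else \
                    (16 if rel[:, 1].max() > kk - 6 else 0)
                if sx or sy:
                    coords, scores = self._decode_window(
                        s2_views, box, others, w, h,
                        origin=(x0a + sx, y0a + sy))
            grown = _grow_box(box, coords, w, h)
            if cfg.window_refine:
                # the head is window-placement sensitive (CoordConv); a
                # second pass with the window centred on the keypoint-grown
                # box reproduces the training-time placement
                x0a, y0a = self.kp_window_origin(box)
                x0b, y0b = self.kp_window_origin(grown)
                if abs(x0a - x0b) > 2 or abs(y0a - y0b) > 2:
                    coords, scores = self._decode_window(s2_views, grown,
                                                         others, w, h)
                    grown = _grow_box(grown, coords, w, h)
            detections.append(MouseDetection(
                box=grown / scale, top_view_prob=float(prob),
                keypoints=KeypointSet(coords / scale, np.full(12, 2), scores)))
        detections.sort(key=lambda d: -d.top_view_prob)
        return detections

    def _decode_window(self, s2_views, box, others, w, h, origin=None):
        cfg = self.config
        kk = cfg.heatmap_size
        x0, y0 = self.kp_window_origin(box) if origin is None else origin
        wins, flips = [], []
        for (fx, fy), s2 in s2_views.items():
            bv = np.asarray(box, dtype=float).copy()
            ov = [np.asarray(b, dtype=float).copy() for b in others]
            xv, yv = x0, y0
            if fx:
                xv = w - (x0 + kk)
                bv = np.array([w - bv[2], bv[1], w - bv[0], bv[3]])
                ov = [np.array([w - b[2], b[1], w - b[0], b[3]]) for b in ov]
            if fy:
                yv = h - (y0 + kk)
                bv = np.array([bv[0], h - bv[3], bv[2], h - bv[1]])
                ov = [np.array([b[0], h - b[3], b[2], h - b[1]]) for b in ov]
            wins.append(self.crop_kp_window(s2[0], xv, yv, bv, ov))
            flips.append((fx, fy))
        outs = self.kp_head.forward(np.stack(wins), training=False)
        if len(wins) == 1:
            logits = outs[0]
        else:
            logits = _merge_views(list(outs), flips, cfg.n_keypoints)
        if cfg.subpixel_mode == "centroid":
            logits = split_head_output(logits, cfg.n_keypoints)[0]
        if cfg.structured_decode:
            coords, scores = decode_keypoints_structured(
                logits, x0, y0, subpixel=cfg.subpixel,
                adjacency_radius=cfg.decode_adjacency_radius,
                exclusion_radius=cfg.decode_exclusion_radius,
                tie_joints=cfg.tie_joints)
        else:
            coords, scores = decode_heatmaps(logits, x0, y0,
                                             subpixel=cfg.subpixel)
        coords[:, 0] = np.clip(coords[:, 0], 0.0, w - 1.0)
        coords[:, 1] = np.clip(coords[:, 1], 0.0, h - 1.0)
        return coords, scores


def _grow_box(box, coords, w, h):
    """Box grown to cover the decoded keypoints (then clipped to image).

    The sub-pixel keypoints are far more precise than any box regression,
    and clipping keypoints into an under-sized box would corrupt them.
    """
    grown = np.array([min(box[0], coords[:, 0].min() - 2),
                      min(box[1], coords[:, 1].min() - 2),
                      max(box[2], coords[:, 0].max() + 2),
                      max(box[3], coords[:, 1].max() + 2)])
    grown[0::2] = np.clip(grown[0::2], 0, w)
    grown[1::2] = np.clip(grown[1::2], 0, h)
    return grown


def _merge_views(view_logits: list, flips: list, n_keypoints: int):
    """Average head outputs over mirror views of the input window.

    A mirrored window shows a side-swapped mouse (for a single mirror), so
    each view is unflipped spatially, its left/right channel labels swapped
    when exactly one axis is mirrored, and mirrored offset components
    negated, before averaging the logits. A side confusion in one view is
    rarely repeated in the others, so inconsistent peaks cancel and
    consistent ones sharpen.
    """
    from .io import LR_SWAP

    swap = np.asarray(LR_SWAP)
    hms, offs = [], []
    for logits, (fx, fy) in zip(view_logits, flips):
        hm, off = split_head_output(logits, n_keypoints)
        if fx != fy:  # single mirror: anatomical sides exchange
            hm = hm[swap]
            off = None if off is None else off[swap]
        if fx:
            hm = hm[:, :, ::-1]
            if off is not None:
                off = np.stack([-off[:, 0, :, ::-1], off[:, 1, :, ::-1]],
                               axis=1)
        if fy:
            hm = hm[:, ::-1, :]
            if off is not None:
                off = np.stack([off[:, 0, ::-1, :], -off[:, 1, ::-1, :]],
                               axis=1)
        hms.append(hm)
        offs.append(off)
    merged_hm = np.mean(hms, axis=0)
    if offs[0] is None:
        return merged_hm
    merged_off = np.mean(offs, axis=0)
    k, hh, ww = merged_hm.shape
    return np.concatenate([merged_hm, merged_off.reshape(2 * k, hh, ww)])


def split_head_output(logits_all: np.ndarray, n_keypoints: int = 12):
    """Split keypoint-head channels into (heatmaps, offsets-or-None)."""
    if logits_all.shape[0] == n_keypoints:
        return logits_all, None
    hm = logits_all[:n_keypoints]
    off = logits_all[n_keypoints:].reshape(n_keypoints, 2,
                                           *logits_all.shape[1:])
    return hm, off


def _peak(hm: np.ndarray, mask: np.ndarray | None):
    """Integer argmax bin, optionally restricted to a boolean mask."""
    hh, ww = hm.shape
    if mask is not None and mask.any():
        flat = np.where(mask.reshape(-1), hm.reshape(-1), -np.inf)
    else:
        flat = hm.reshape(-1)
    idx = int(np.argmax(flat))
    py, px = divmod(idx, ww)
    return px, py, float(hm[py, px])


def _subpixel(hm: np.ndarray, off: np.ndarray | None, px: int, py: int,
              radius: int = 3):
    """Refine an integer bin to continuous coordinates.

    With a learned offset field, add the predicted (dx, dy) at the peak bin
    (clipped to a small range). Otherwise take the softmax-weighted centroid
    of the heatmap logits around the peak — for a log-Gaussian blob this is
    an unbiased estimator of the blob centre.
    """
    if off is not None:
        dx = float(np.clip(off[0, py, px], -3.0, 3.0))
        dy = float(np.clip(off[1, py, px], -3.0, 3.0))
        return px + dx, py + dy
    hh, ww = hm.shape
    x0, x1 = max(px - radius, 0), min(px + radius + 1, ww)
    y0, y1 = max(py - radius, 0), min(py + radius + 1, hh)
    patch = hm[y0:y1, x0:x1].astype(np.float64)
    w = np.exp(patch - patch.max())
    ys, xs = np.mgrid[y0:y1, x0:x1]
    return float((xs * w).sum() / w.sum()), float((ys * w).sum() / w.sum())


def _disk_mask(hh: int, ww: int, cx: float, cy: float, radius: float,
               invert: bool = False) -> np.ndarray:
    ys, xs = np.ogrid[0:hh, 0:ww]
    d2 = (xs - cx) ** 2 + (ys - cy) ** 2
    return d2 > radius ** 2 if invert else d2 <= radius ** 2


# each side is a kinematic chain; consecutive entries are linked either by
# an articulation ("joint": the next bone starts where the previous ends)
# or by a bone segment ("bone": endpoints of one rigid bone)
_CHAIN = ("pelvis_{s}_start", "pelvis_{s}_end", "femur_{s}_start",
          "femur_{s}_end", "tibia_{s}_start", "tibia_{s}_end")
_LINKS = ("bone", "joint", "bone", "joint", "bone")

# with exactly articulated joints the chain collapses to four nodes; each
# node lists the keypoint channels that share its location
_TIED_CHAIN = ((0,), (1, 2), (3, 4), (5,))  # indices into _CHAIN
_TIED_LINKS = ("bone", "bone", "bone")


def _local_maxima(hm: np.ndarray, n: int = 4, suppress: float = 5.0):
    """Top-n peaks of a heatmap with non-maximum suppression."""
    work = hm.astype(np.float64).copy()
    hh, ww = hm.shape
    out = []
    for _ in range(n):
        idx = int(np.argmax(work))
        py, px = divmod(idx, ww)
        val = work[py, px]
        if not np.isfinite(val):
            break
        out.append((px, py, float(hm[py, px])))
        work[_disk_mask(hh, ww, px, py, suppress)] = -np.inf
    return out


def _decode_chain(hm, node_channels, links, adjacency_radius, bone_min,
                  bone_max, taken: list, exclusion_radius: float,
                  link_bounds: list | None = None, n_candidates: int = 4):
    """Viterbi decode of one side's chain over candidate peaks.

    Each node may pool several keypoint channels that share a location
    (exactly articulated joints); its unary map is their summed logits.
    Maximizes the summed peak logits subject to articulation proximity and
    plausible bone extent; infeasible transitions and candidates close to an
    already-taken mirror location incur a large penalty rather than being
    removed, so a decode always exists.
    """
    cands = []
    for step, channels in enumerate(node_channels):
        unary = hm[channels[0]] if len(channels) == 1 \
            else np.sum(hm[list(channels)], axis=0)
        cl = _local_maxima(unary, n=n_candidates)
        penal = []
        for (px, py, val) in cl:
            pen = 0.0
            for (tx, ty) in taken[step]:
                if np.hypot(px - tx, py - ty) < exclusion_radius:
                    pen -= 50.0
            penal.append((px, py, val + pen))
        cands.append(penal)

    n_steps = len(cands)
    score = [np.array([c[2] for c in cands[0]])]
    back = []
    for step in range(1, n_steps):
        prev = np.array([(c[0], c[1]) for c in cands[step - 1]])
        cur = np.array([(c[0], c[1]) for c in cands[step]])
        dist = np.hypot(prev[:, None, 0] - cur[None, :, 0],
                        prev[:, None, 1] - cur[None, :, 1])
        if links[step - 1] == "joint":
            feas = dist <= adjacency_radius
        else:
            lo, hi = (bone_min, bone_max) if link_bounds is None \
                else link_bounds[step - 1]
            feas = (dist >= lo) & (dist <= hi)
            # caudal monotonicity: in a head-up dorsal view every leg bone
            # points downward, which rules out start/end reversals
            feas &= (cur[None, :, 1] - prev[:, None, 1]) >= 1.0
        trans = np.where(feas, 0.0, -50.0)
        total = score[-1][:, None] + trans
        best_prev = total.argmax(axis=0)
        unary = np.array([c[2] for c in cands[step]])
        score.append(total.max(axis=0) + unary)
        back.append(best_prev)
    # backtrack
    sel = [int(np.argmax(score[-1]))]
    for step in range(n_steps - 2, -1, -1):
        sel.append(int(back[step][sel[-1]]))
    sel.reverse()
    positions = [(cands[i][sel[i]][0], cands[i][sel[i]][1])
                 for i in range(n_steps)]
    return positions, float(score[-1].max())


def decode_keypoints_structured(logits_all: np.ndarray, x0: int, y0: int,
                                subpixel: bool = True,
                                adjacency_radius: float = 9.0,
                                exclusion_radius: float = 4.0,
                                bone_min: float = 6.0,
                                bone_max: float = 60.0,
                                tie_joints: bool = True):
    """Skeleton-consistent heatmap decoding.

    Each side's keypoints form a chain decoded jointly by dynamic
    programming over candidate peaks: a single confused heatmap then loses
    to the chain combination that keeps articulations adjacent and bone
    extents plausible. With ``tie_joints`` (the default; scenes articulate
    bones exactly) the two keypoints at each joint are decoded as one node
    from their summed heatmaps. The higher-scoring side commits first; the
    other side's candidates near the committed mirror locations are
    penalized (left and right tips are locally indistinguishable and must
    not collapse onto one point).
    """
    from .io import KEYPOINT_NAMES

    hm, off = split_head_output(logits_all)
    k, hh, ww = hm.shape
    coords = np.zeros((k, 2))
    scores = np.zeros(k)
    name_to_idx = {n: i for i, n in enumerate(KEYPOINT_NAMES)}
    chains = {s: [name_to_idx[t.format(s=s)] for t in _CHAIN]
              for s in ("L", "R")}
    if tie_joints:
        nodes = {s: [[chains[s][i] for i in grp] for grp in _TIED_CHAIN]
                 for s in ("L", "R")}
        links = _TIED_LINKS
    else:
        nodes = {s: [[ki] for ki in chains[s]] for s in ("L", "R")}
        links = _LINKS

    empty = [[] for _ in nodes["L"]]
    first = {s: _decode_chain(hm, nodes[s], links, adjacency_radius,
                              bone_min, bone_max, empty, exclusion_radius)
             for s in ("L", "R")}
    lead = "L" if first["L"][1] >= first["R"][1] else "R"
    trail = "R" if lead == "L" else "L"
    pos = {lead: first[lead][0]}
    score = {lead: first[lead][1]}
    pos[trail], score[trail] = _decode_chain(
        hm, nodes[trail], links, adjacency_radius, bone_min, bone_max,
        [[p] for p in pos[lead]], exclusion_radius)

    if tie_joints:
        # bilateral symmetry pass: legs are near-symmetric, so a bone that
        # disagrees with its mirror by >35% marks a suspect chain, which is
        # re-decoded with length bounds borrowed from the stronger side
        def seg_lengths(p):
            return [float(np.hypot(p[i + 1][0] - p[i][0],
                                   p[i + 1][1] - p[i][1]))
                    for i in range(len(p) - 1)]

        len_l, len_r = seg_lengths(pos["L"]), seg_lengths(pos["R"])
        asym = any(abs(a - b) > 0.35 * max(0.5 * (a + b), 1e-6)
                   for a, b in zip(len_l, len_r))
        if asym:
            suspect = "L" if score["L"] < score["R"] else "R"
            other = "R" if suspect == "L" else "L"
            bounds = [(0.65 * l, 1.45 * l)
                      for l in seg_lengths(pos[other])]
            new_pos, new_score = _decode_chain(
                hm, nodes[suspect], links, adjacency_radius, bone_min,
                bone_max, [[p] for p in pos[other]], exclusion_radius,
                link_bounds=bounds, n_candidates=8)
            pos[suspect], score[suspect] = new_pos, new_score

    for side, positions in pos.items():
        for channels, (px, py) in zip(nodes[side], positions):
            if subpixel:
                fxy = [np.asarray(_subpixel(
                    hm[ki], None if off is None else off[ki], px, py))
                    for ki in channels]
                fx, fy = np.mean(fxy, axis=0)
            else:
                fx, fy = float(px), float(py)
            for ki in channels:
                coords[ki] = (x0 + fx, y0 + fy)
                p = nn.softmax(hm[ki].reshape(-1))
                scores[ki] = float(p.max())
    return coords, scores


def decode_heatmaps(logits_all: np.ndarray, x0: int, y0: int, subpixel=True):
    """Independent per-keypoint argmax + sub-pixel refinement."""
    hm, off = split_head_output(logits_all)
    k, hh, ww = hm.shape
    coords = np.zeros((k, 2))
    scores = np.zeros(k)
    for i in range(k):
        px, py, _val = _peak(hm[i], None)
        fx, fy = _subpixel(hm[i], None if off is None else off[i],
                           px, py) if subpixel else (px, py)
        coords[i] = (x0 + fx, y0 + fy)
        p = nn.softmax(hm[i].reshape(-1))
        scores[i] = float(p.max())
    return coords, scores


def build_model(config: ModelConfig) -> Detector:
    """Construct a detector; same seed gives bit-identical parameters."""
    return Detector(config)


def predict(detector: Detector, images: list) -> list[list[MouseDetection]]:
    """Run inference; per image, detections sorted by top-view probability."""
    return [detector.detect_image(img) for img in images]


# ----------------------------------------------------------- checkpoints

def save_checkpoint(detector: Detector, path) -> None:
    """Single-archive checkpoint with the config embedded."""
    arrays = {f"param/{k}": v for k, v in detector.all_params().items()}
    arrays.update({f"buffer/{k}": v for k, v in detector.buffers().items()})
    buf = _io.BytesIO()
    np.savez(buf, __config__=json.dumps(asdict(detector.config)), **arrays)
    with open(path, "wb") as fh:
        fh.write(buf.getvalue())


def load_checkpoint(path) -> Detector:
    with np.load(path, allow_pickle=False) as data:
        cfg_json = json.loads(str(data["__config__"]))
        cfg = ModelConfig(**cfg_json)
        det = Detector(cfg)
        params = det.all_params()
        buffers = det.buffers()
        for key in data.files:
            if key.startswith("param/"):
                params[key[6:]][...] = data[key]
            elif key.startswith("buffer/"):
                buffers[key[7:]][...] = data[key]
    return det
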