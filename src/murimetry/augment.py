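"""Training-time augmentation applied identically to image, boxes, keypoints.

Geometric transforms are shift-scale-rotate about the image centre plus
horizontal/vertical flips; photometric transforms adjust brightness and
contrast only. Flips additionally swap the anatomical left/right keypoint
labels so a mirrored mouse keeps its sides correct — a mirrored left tibia
is a right tibia. Keypoints transformed out of frame are marked invisible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ConfigError
from .io import LR_SWAP, KeypointSet


@dataclass
class AugmentConfig:
    shift_limit: float = 0.0625  # fraction of image size
    scale_limit: float = 0.1
    rotate_limit: float = 15.0  # degrees
    p_geometric: float = 0.8
    p_hflip: float = 0.5
    p_vflip: float = 0.5
    brightness_limit: float = 0.15
    contrast_limit: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        for name in ("p_geometric", "p_hflip", "p_vflip"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be a probability, got {v}")
        for name in ("shift_limit", "scale_limit", "rotate_limit",
                     "brightness_limit", "contrast_limit"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")


def _apply_affine(image, coords, angle_deg, scale, shift_xy):
    """Forward map p' = C + s*R(p - C) + t applied to image and coordinates."""
    h, w = image.shape
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    th = math.radians(angle_deg)
    ca, sa = math.cos(th), math.sin(th)
    fwd = scale * np.array([[ca, -sa], [sa, ca]])
    tx, ty = shift_xy
    # inverse map for the image resample
    inv = np.linalg.inv(fwd)
    # output pixel (r, c) pulls from input (row, col):
    # [x, y] = inv @ ([c, r] - [cx + tx, cy + ty]) + [cx, cy]
    m = np.array([[inv[1, 1], inv[1, 0]], [inv[0, 1], inv[0, 0]]])
    off = (np.array([cy, cx])
           - m @ np.array([cy + ty, cx + tx]))
    fill = float(np.median(image))
    warped = ndimage.affine_transform(image, m, offset=off, order=1,
                                      mode="constant", cval=fill,
                                      output=np.float32)
    new_coords = (coords - [cx, cy]) @ fwd.T + [cx + tx, cy + ty]
    return warped, new_coords


def augment(image: np.ndarray, keypoint_sets: list, boxes: list,
            config: AugmentConfig, rng: np.random.Generator | None = None,
            force: dict | None = None):
    """Return (image, keypoint_sets, boxes) with one sampled augmentation.

    ``force`` overrides sampled parameters by name (``hflip``, ``vflip``,
    ``angle``, ``scale``, ``shift``, ``brightness``, ``contrast``) — used for
    deterministic tests and deterministic replay.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    force = force or {}
    h, w = image.shape

    do_geo = force.get("geometric", rng.random() < config.p_geometric)
    angle = force.get("angle", rng.uniform(-config.rotate_limit,
                                           config.rotate_limit) if do_geo else 0.0)
    scale = force.get("scale", 1.0 + rng.uniform(-config.scale_limit,
                                                 config.scale_limit) if do_geo else 1.0)
    shift = force.get("shift",
                      (rng.uniform(-config.shift_limit, config.shift_limit) * w,
                       rng.uniform(-config.shift_limit, config.shift_limit) * h)
                      if do_geo else (0.0, 0.0))
    hflip = force.get("hflip", rng.random() < config.p_hflip)
    vflip = force.get("vflip", rng.random() < config.p_vflip)
    brightness = force.get("brightness",
                           rng.uniform(-config.brightness_limit,
                                       config.brightness_limit))
    contrast = force.get("contrast",
                         rng.uniform(-config.contrast_limit,
                                     config.contrast_limit))

    coords = np.concatenate([ks.coords for ks in keypoint_sets]) \
        if keypoint_sets else np.zeros((0, 2))
    vis = np.concatenate([ks.visibility for ks in keypoint_sets]) \
        if keypoint_sets else np.zeros(0, dtype=int)
    boxes = [np.asarray(b, dtype=float).copy() for b in boxes]

    identity_affine = (angle == 0.0 and scale == 1.0 and shift == (0.0, 0.0))
    if not identity_affine:
        image, coords = _apply_affine(image, coords, angle, scale, shift)
        new_boxes = []
        for b in boxes:
            corners = np.array([[b[0], b[1]], [b[2], b[1]],
                                [b[0], b[3]], [b[2], b[3]]])
            cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
            th = math.radians(angle)
            fwd = scale * np.array([[math.cos(th), -math.sin(th)],
                                    [math.sin(th), math.cos(th)]])
            tc = (corners - [cx, cy]) @ fwd.T + [cx + shift[0], cy + shift[1]]
            nb = np.array([tc[:, 0].min(), tc[:, 1].min(),
                           tc[:, 0].max(), tc[:, 1].max()])
            new_boxes.append(np.array([max(nb[0], 0), max(nb[1], 0),
                                       min(nb[2], w), min(nb[3], h)]))
        boxes = new_boxes

    n_per = len(coords) // max(len(keypoint_sets), 1) if keypoint_sets else 0
    if hflip:
        image = np.ascontiguousarray(image[:, ::-1])
        coords[:, 0] = (w - 1) - coords[:, 0]
        boxes = [np.array([w - b[2], b[1], w - b[0], b[3]]) for b in boxes]
    if vflip:
        image = np.ascontiguousarray(image[::-1, :])
        coords[:, 1] = (h - 1) - coords[:, 1]
        boxes = [np.array([b[0], h - b[3], b[2], h - b[1]]) for b in boxes]
    if hflip != vflip:  # single mirror: anatomical sides exchange
        swap = np.asarray(LR_SWAP)
        coords = coords.reshape(len(keypoint_sets), n_per, 2)[:, swap].reshape(-1, 2) \
            if keypoint_sets else coords
        vis = vis.reshape(len(keypoint_sets), n_per)[:, swap].reshape(-1) \
            if keypoint_sets else vis

    if brightness != 0.0 or contrast != 0.0:
        image = np.clip(image * (1.0 + contrast) + brightness, 0.0, 1.0
                        ).astype(np.float32)

    out_sets = []
    if keypoint_sets:
        coords = coords.reshape(len(keypoint_sets), n_per, 2)
        vis = vis.reshape(len(keypoint_sets), n_per).copy()
        inside = ((coords[..., 0] >= 0) & (coords[..., 0] <= w - 1)
                  & (coords[..., 1] >= 0) & (coords[..., 1] <= h - 1))
        vis[~inside] = 0
        for i in range(len(keypoint_sets)):
            safe = np.where(inside[i][:, None], coords[i], 0.0)
            out_sets.append(KeypointSet(safe, vis[i]))
    return image, out_sets, boxes
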