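"""Radiograph-like synthetic scenes of stylized mouse skeletons.

A scene is a noisy background plus 0-2 bright mouse silhouettes rendered in a
dorsal (top-view) pose: an elliptical body and six bright bone segments
(left/right tibia, femur, pelvis) whose exact endpoints are recorded as
ground-truth keypoints. Rendering uses anti-aliased capsules with a light
Gaussian blur so edges carry the soft gradients of real radiographs without
any attempt at physical X-ray simulation.

The geometry emulates a prone mouse on a scanner bed: the spine is roughly
vertical with a small random tilt, the pelvis flares outward from the hip,
the femur continues outward-down and the tibia turns back inward — so the
femur starts where the pelvis ends and the tibia starts where the femur ends
(within a small articulation jitter).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import ConfigError, PlacementError
from .io import (BONES, SIDES, AnnotatedMouse, ImageAnnotations, KeypointSet,
                 keypoint_index, save_image, write_coco_keypoints)

DEFAULT_LENGTH_MEANS = {"tibia": 26.0, "femur": 22.0, "pelvis": 18.0}


@dataclass
class SceneConfig:
    """Parameters of one synthetic radiograph.

    Lengths and thicknesses are in pixels, intensities in [0, 1] units of the
    rendered raster.
    """

    image_width: int = 256
    image_height: int = 256
    n_mice: int = 1
    background_level: float = 0.08
    background_noise_sd: float = 0.03
    bone_intensity: float = 0.55
    body_intensity: float = 0.28
    bone_thickness: float = 3.0
    length_means: dict = field(default_factory=lambda: dict(DEFAULT_LENGTH_MEANS))
    length_sd: float = 1.5
    integer_keypoints: bool = True
    blur_sigma: float = 0.8
    rotation_limit_deg: float = 12.0
    adjacency_jitter: float = 0.0  # joints articulate exactly (see docs)
    body_halfwidth: float = 13.0
    body_length: float = 36.0
    decoy_prob: float = 0.0  # chance of replacing a mouse by a non-top-view decoy
    box_pad: float = 4.0
    margin: int = 6
    max_place_attempts: int = 200
    pixel_spacing: float = 1.0  # mm per pixel, metadata only
    seed: int = 0

    def validate(self) -> None:
        if self.n_mice not in (0, 1, 2):
            raise ConfigError(f"n_mice must be 0, 1 or 2, got {self.n_mice}")
        if self.image_width < 64 or self.image_height < 64:
            raise ConfigError("image dimensions must be at least 64")
        if self.length_sd < 0:
            raise ConfigError("length_sd must be non-negative")
        for bone, mean in self.length_means.items():
            if mean <= 2 * self.bone_thickness:
                raise ConfigError(
                    f"{bone} mean length {mean} must exceed twice the bone "
                    f"thickness ({2 * self.bone_thickness})")


@dataclass
class GroundTruthMouse:
    box: np.ndarray  # (4,) xyxy half-open
    keypoints: KeypointSet
    top_view: bool = True
    lengths: dict = field(default_factory=dict)  # (bone, side) -> pixels


@dataclass
class SyntheticScene:
    image: np.ndarray  # (H, W) float32 in [0, 1]
    mice: list
    pixel_spacing: float = 1.0
    config: SceneConfig | None = None


def _rot(theta: float) -> np.ndarray:
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, -s], [s, c]])


def _sample_skeleton(cfg: SceneConfig, rng: np.random.Generator):
    """Keypoints (12, 2) in a local frame plus sampled bone lengths."""
    coords = np.zeros((12, 2))
    lengths = {}
    for side, sgn in (("L", -1.0), ("R", 1.0)):
        angles = {
            "pelvis": sgn * math.radians(32.0 + rng.uniform(-5, 5)),
            "femur": sgn * math.radians(58.0 + rng.uniform(-8, 8)),
            "tibia": sgn * math.radians(10.0 + rng.uniform(-10, 10)),
        }
        start = np.array([sgn * 3.0, 0.0])
        for bone in ("pelvis", "femur", "tibia"):
            mean = cfg.length_means[bone]
            length = max(rng.normal(mean, cfg.length_sd), 2 * cfg.bone_thickness + 1)
            a = angles[bone]
            end = start + length * np.array([math.sin(a), math.cos(a)])
            coords[keypoint_index(bone, side, "start")] = start
            coords[keypoint_index(bone, side, "end")] = end
            lengths[(bone, side)] = length
            jitter = rng.uniform(-1, 1, 2)
            nrm = np.linalg.norm(jitter)
            if nrm > 1e-9:
                jitter *= rng.uniform(0, cfg.adjacency_jitter) / nrm
            start = end + jitter  # next bone articulates here
    return coords, lengths


def _capsule(canvas: np.ndarray, p0: np.ndarray, p1: np.ndarray,
             radius: float, value: float) -> None:
    """Max-composite an anti-aliased capsule (segment with round caps)."""
    h, w = canvas.shape
    lo = np.floor(np.minimum(p0, p1) - radius - 2).astype(int)
    hi = np.ceil(np.maximum(p0, p1) + radius + 2).astype(int)
    x0, y0 = np.clip(lo, 0, [w - 1, h - 1])
    x1, y1 = np.clip(hi, 0, [w - 1, h - 1])
    if x1 <= x0 or y1 <= y0:
        return
    ys, xs = np.mgrid[y0:y1 + 1, x0:x1 + 1]
    pts = np.stack([xs, ys], axis=-1).astype(float)
    d = p1 - p0
    denom = float(d @ d)
    if denom < 1e-12:
        dist = np.linalg.norm(pts - p0, axis=-1)
    else:
        t = np.clip(((pts - p0) @ d) / denom, 0.0, 1.0)
        proj = p0 + t[..., None] * d
        dist = np.linalg.norm(pts - proj, axis=-1)
    alpha = np.clip(radius + 0.5 - dist, 0.0, 1.0)
    region = canvas[y0:y1 + 1, x0:x1 + 1]
    np.maximum(region, alpha * value, out=region)


def _ellipse(canvas: np.ndarray, center: np.ndarray, axes: tuple,
             theta: float, value: float) -> None:
    h, w = canvas.shape
    a, b = axes
    r = max(a, b) + 2
    x0, y0 = np.clip(np.floor(center - r).astype(int), 0, [w - 1, h - 1])
    x1, y1 = np.clip(np.ceil(center + r).astype(int), 0, [w - 1, h - 1])
    if x1 <= x0 or y1 <= y0:
        return
    ys, xs = np.mgrid[y0:y1 + 1, x0:x1 + 1]
    rel = np.stack([xs - center[0], ys - center[1]], axis=-1) @ _rot(theta)
    q = (rel[..., 0] / a) ** 2 + (rel[..., 1] / b) ** 2
    alpha = np.clip((1.0 - q) * 4.0, 0.0, 1.0)  # soft edge
    region = canvas[y0:y1 + 1, x0:x1 + 1]
    np.maximum(region, alpha * value, out=region)


def _boxes_overlap(a, b) -> bool:
    return not (a[2] <= b[0] or b[2] <= a[0] or a[3] <= b[1] or b[3] <= a[1])


def generate_scene(config: SceneConfig) -> SyntheticScene:
    """Render one scene deterministically from ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    h, w = config.image_height, config.image_width
    image = config.background_level + rng.normal(
        0.0, config.background_noise_sd, (h, w))

    mice: list[GroundTruthMouse] = []
    layer = np.zeros((h, w))
    boxes_so_far: list[np.ndarray] = []
    for _ in range(config.n_mice):
        is_decoy = bool(rng.random() < config.decoy_prob)
        placed = False
        for _attempt in range(config.max_place_attempts):
            coords, lengths = _sample_skeleton(config, rng)
            theta = math.radians(rng.uniform(-config.rotation_limit_deg,
                                             config.rotation_limit_deg))
            rot = _rot(theta)
            coords = coords @ rot.T
            body_c = np.array([0.0, -config.body_length / 2 + 4.0]) @ rot.T
            # bounding half-extent of the rotated body ellipse
            a, b = config.body_halfwidth, config.body_length / 2
            brx = math.hypot(a * math.cos(theta), b * math.sin(theta))
            bry = math.hypot(a * math.sin(theta), b * math.cos(theta))
            ext_lo = np.minimum(coords.min(axis=0), body_c - [brx, bry])
            ext_hi = np.maximum(coords.max(axis=0), body_c + [brx, bry])
            lo = config.margin + config.box_pad - ext_lo
            hi = np.array([w, h]) - config.margin - config.box_pad - ext_hi
            if np.any(hi <= lo):
                raise ConfigError("image too small for the configured mouse size")
            center = np.array([rng.uniform(lo[0], hi[0]),
                               rng.uniform(lo[1], hi[1])])
            pts = coords + center
            if config.integer_keypoints:
                pts = np.round(pts)
            body_center = body_c + center
            all_x = np.concatenate([pts[:, 0], [body_center[0] - config.body_halfwidth,
                                                body_center[0] + config.body_halfwidth]])
            all_y = np.concatenate([pts[:, 1], [body_center[1] - config.body_length / 2 - 2,
                                                body_center[1] + config.body_length / 2 + 2]])
            box = np.array([all_x.min() - config.box_pad, all_y.min() - config.box_pad,
                            all_x.max() + config.box_pad + 1, all_y.max() + config.box_pad + 1])
            box = np.array([max(box[0], 0), max(box[1], 0),
                            min(box[2], w), min(box[3], h)])
            if any(_boxes_overlap(box, b) for b in boxes_so_far):
                continue
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place mouse without overlap in "
                f"{config.max_place_attempts} attempts")
        boxes_so_far.append(box)
        _ellipse(layer, body_center, (config.body_halfwidth, config.body_length / 2),
                 theta, config.body_intensity * (0.6 if is_decoy else 1.0))
        if not is_decoy:
            for side in SIDES:
                for bone in BONES:
                    p0 = pts[keypoint_index(bone, side, "start")]
                    p1 = pts[keypoint_index(bone, side, "end")]
                    _capsule(layer, p0, p1, config.bone_thickness / 2,
                             config.bone_intensity)
        gt_lengths = {
            (bone, side): float(np.linalg.norm(
                pts[keypoint_index(bone, side, "end")]
                - pts[keypoint_index(bone, side, "start")]))
            for bone in BONES for side in SIDES}
        mice.append(GroundTruthMouse(
            box=box.astype(float),
            keypoints=KeypointSet(pts.copy()),
            top_view=not is_decoy,
            lengths=gt_lengths))

    if config.blur_sigma > 0:
        layer = gaussian_filter(layer, config.blur_sigma)
    image = np.clip(image + layer, 0.0, 1.0).astype(np.float32)
    return SyntheticScene(image=image, mice=mice,
                          pixel_spacing=config.pixel_spacing, config=config)


def split_sizes(n_images: int, fractions) -> list[int]:
    """Largest-remainder rounding of ``fractions`` to integer split sizes."""
    fractions = [float(f) for f in fractions]
    if abs(sum(fractions) - 1.0) > 1e-6:
        raise ConfigError(f"split fractions must sum to 1, got {sum(fractions)}")
    raw = [f * n_images for f in fractions]
    sizes = [int(math.floor(r)) for r in raw]
    rem = n_images - sum(sizes)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - sizes[i], reverse=True)
    for i in order[:rem]:
        sizes[i] += 1
    return sizes


SPLIT_NAMES = ("train", "val", "test")


def generate_dataset(n_images: int, split_fractions, config: SceneConfig,
                     out_dir, mice_counts=None) -> pd.DataFrame:
    """Write a split dataset (PNG images + per-split COCO JSON + manifest CSV).

    mice_counts: optional explicit per-image mouse counts; by default each
    image holds 1 or 2 mice with equal probability, mirroring source
    radiographs that image one or two animals at a time.
    """
    if n_images < 3:
        raise ConfigError("need at least 3 images (one per split)")
    sizes = split_sizes(n_images, split_fractions)
    out_dir = Path(out_dir)
    rng = np.random.default_rng(config.seed)
    seeds = rng.integers(0, 2 ** 31 - 1, size=n_images)
    if mice_counts is None:
        mice_counts = rng.choice([1, 2], size=n_images)
    elif len(mice_counts) != n_images:
        raise ConfigError("mice_counts must have one entry per image")

    rows = []
    idx = 0
    for split, size in zip(SPLIT_NAMES, sizes):
        img_dir = out_dir / split / "images"
        img_dir.mkdir(parents=True, exist_ok=True)
        annots = []
        for j in range(size):
            cfg = replace(config, n_mice=int(mice_counts[idx]),
                          seed=int(seeds[idx]))
            scene = generate_scene(cfg)
            fname = f"img_{idx:04d}.png"
            save_image(img_dir / fname, scene.image)
            rec = ImageAnnotations(image_id=idx, file_name=fname,
                                   width=cfg.image_width, height=cfg.image_height)
            for m in scene.mice:
                rec.mice.append(AnnotatedMouse(m.keypoints, m.box,
                                               1 if m.top_view else 2))
            annots.append(rec)
            rows.append({"split": split,
                         "image_path": str(Path(split) / "images" / fname),
                         "n_mice": len(scene.mice)})
            idx += 1
        write_coco_keypoints(out_dir / split / "annotations.json", annots)
    manifest = pd.DataFrame(rows, columns=["split", "image_path", "n_mice"])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


# ----------------------------------------------------- cohort simulation

def growth_curve(age_days, sex, bone: str) -> np.ndarray:
    """Expected bone length (pixels) as a saturating function of age.

    A Michaelis-Menten-shaped curve with a small male/female asymptote gap —
    a deliberately simple stand-in for murine long-bone growth, adequate for
    exercising age/sex residualization.
    """
    asym = {"tibia": 30.0, "femur": 26.0, "pelvis": 21.0}[bone]
    sexfac = np.where(np.asarray(sex) == "M", 1.04, 1.0)
    age = np.asarray(age_days, dtype=float)
    return asym * sexfac * age / (age + 11.0)


def generate_cohort(n_mice: int, seed: int = 0, noise_sd: float = 0.3,
                    source: str = "automated",
                    age_range: tuple = (30.0, 120.0)) -> pd.DataFrame:
    """Simulate a phenotyping cohort table (one row per mouse).

    Bone lengths follow :func:`growth_curve` for the drawn age/sex plus i.i.d.
    Gaussian measurement noise of ``noise_sd`` pixels.
    """
    rng = np.random.default_rng(seed)
    ages = rng.uniform(*age_range, size=n_mice)
    sexes = rng.choice(["M", "F"], size=n_mice)
    rows = {"mouse_id": [f"m{seed}_{i:05d}" for i in range(n_mice)],
            "age": ages, "sex": sexes, "source": source}
    for bone in BONES:
        base = growth_curve(ages, sexes, bone)
        for side in SIDES:
            rows[f"{bone}_{side}"] = base + rng.normal(0.0, noise_sd, n_mice)
    return pd.DataFrame(rows)
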