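"""Post-processing: detection filtering, bone measurement, quality flags.

The measurement step converts a detected mouse's 12 keypoints into six bone
lengths (left/right tibia, femur, pelvis). Refinement never deletes or
alters measurements — it only attaches flags:

* ``low_confidence`` — an endpoint's keypoint score fell below threshold;
* ``length_outlier`` — length deviates from the cohort median by more than
  ``k`` median-absolute-deviations for that bone;
* ``abnormal_geometry`` — a missing/degenerate endpoint, a violated joint
  adjacency (femur must start near the ipsilateral pelvis end, tibia near
  the ipsilateral femur end), or left/right asymmetry beyond tolerance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError
from .io import BONES, SIDES, keypoint_index
from .model import MouseDetection

LOW_CONFIDENCE = "low_confidence"
LENGTH_OUTLIER = "length_outlier"
ABNORMAL_GEOMETRY = "abnormal_geometry"


@dataclass
class BoneMeasurement:
    image_id: str
    mouse_index: int
    bone: str
    side: str
    start: np.ndarray | None
    end: np.ndarray | None
    length: float | None
    top_view_prob: float = 1.0
    flags: set = field(default_factory=set)

    def __post_init__(self):
        if self.length is not None:
            if self.length < 0:
                raise ConfigError("length must be non-negative")
            if self.start is not None and self.end is not None:
                d = float(np.linalg.norm(np.asarray(self.end)
                                         - np.asarray(self.start)))
                if abs(d - self.length) > 1e-9:
                    raise ConfigError(
                        f"length {self.length} inconsistent with endpoints "
                        f"(distance {d})")


def filter_detections(detections: list[MouseDetection],
                      threshold: float = 0.5) -> list[MouseDetection]:
    """Keep detections with top-view probability strictly above threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ConfigError("threshold must be in [0, 1]")
    return [d for d in detections if d.top_view_prob > threshold]


def measure_bones(detection: MouseDetection, image_id: str = "",
                  mouse_index: int = 0,
                  score_threshold: float = 0.0) -> list[BoneMeasurement]:
    """One measurement per (bone, side) from the detection's keypoints."""
    ks = detection.keypoints
    out = []
    for bone in BONES:
        for side in SIDES:
            p0, p1, v0, v1 = ks.endpoint_pair(bone, side)
            flags: set[str] = set()
            if not (v0 and v1):
                out.append(BoneMeasurement(image_id, mouse_index, bone, side,
                                           None, None, None,
                                           detection.top_view_prob,
                                           {ABNORMAL_GEOMETRY}))
                continue
            length = float(np.linalg.norm(p1 - p0))
            if length < 1e-9:
                flags.add(ABNORMAL_GEOMETRY)
            if ks.scores is not None and score_threshold > 0:
                s0 = ks.scores[keypoint_index(bone, side, "start")]
                s1 = ks.scores[keypoint_index(bone, side, "end")]
                if min(s0, s1) < score_threshold:
                    flags.add(LOW_CONFIDENCE)
            out.append(BoneMeasurement(image_id, mouse_index, bone, side,
                                       p0.copy(), p1.copy(), length,
                                       detection.top_view_prob, flags))
    return out


ADJACENT = {"femur": "pelvis", "tibia": "femur"}  # bone -> its proximal parent


def refine_measurements(measurements: list[BoneMeasurement],
                        reference_stats: dict | None = None,
                        k: float = 5.0,
                        adjacency_radius: float | None = None,
                        asymmetry_tol: float = 0.25) -> list[BoneMeasurement]:
    """Flag outliers and abnormal geometries; lengths are never modified.

    reference_stats: optional {bone: (median, mad)}; computed from the batch
    when absent. ``adjacency_radius`` defaults to half the median femur
    length.
    """
    out = [replace(m, flags=set(m.flags),
                   start=None if m.start is None else np.asarray(m.start),
                   end=None if m.end is None else np.asarray(m.end))
           for m in measurements]

    # per-bone robust reference stats
    stats = dict(reference_stats) if reference_stats else {}
    for bone in BONES:
        if bone in stats:
            continue
        vals = np.array([m.length for m in out
                         if m.bone == bone and m.length is not None
                         and ABNORMAL_GEOMETRY not in m.flags])
        if len(vals) < 3:
            warnings.warn(f"fewer than 3 usable {bone} lengths; outlier rule "
                          f"skipped for this bone", stacklevel=2)
            continue
        med = float(np.median(vals))
        mad = float(np.median(np.abs(vals - med)))
        stats[bone] = (med, mad)

    for m in out:
        if m.bone in stats and m.length is not None:
            med, mad = stats[m.bone]
            if abs(m.length - med) > k * mad:
                m.flags.add(LENGTH_OUTLIER)

    if adjacency_radius is None:
        adjacency_radius = 0.5 * stats["femur"][0] if "femur" in stats else None

    by_mouse: dict[tuple, dict] = {}
    for m in out:
        by_mouse.setdefault((m.image_id, m.mouse_index), {})[(m.bone, m.side)] = m
    for group in by_mouse.values():
        if adjacency_radius is not None:
            for bone, parent in ADJACENT.items():
                for side in SIDES:
                    child = group.get((bone, side))
                    par = group.get((parent, side))
                    if child is None or par is None:
                        continue
                    if child.start is None or par.end is None:
                        continue
                    gap = float(np.linalg.norm(child.start - par.end))
                    if gap > adjacency_radius:
                        child.flags.add(ABNORMAL_GEOMETRY)
                        par.flags.add(ABNORMAL_GEOMETRY)
        for bone in BONES:
            left = group.get((bone, "L"))
            right = group.get((bone, "R"))
            if (left is None or right is None or left.length is None
                    or right.length is None):
                continue
            mean = 0.5 * (left.length + right.length)
            if mean > 0 and abs(left.length - right.length) > asymmetry_tol * mean:
                left.flags.add(ABNORMAL_GEOMETRY)
                right.flags.add(ABNORMAL_GEOMETRY)
    return out
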