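"""On-disk formats: radiograph images, COCO-keypoints JSON, CSV tables.

The canonical keypoint scheme is 12 landmarks per mouse: start/end of the
tibia, femur and pelvis on the left then the right side. All coordinates are
0-based pixel indices (origin top-left, x rightward, y downward); boxes are
half-open ``[x0, x1) x [y0, y1)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .errors import SchemaError

BONES = ("tibia", "femur", "pelvis")
SIDES = ("L", "R")

#: Canonical order of the 12 keypoints.
KEYPOINT_NAMES = tuple(
    f"{bone}_{side}_{which}"
    for side in SIDES
    for bone in BONES
    for which in ("start", "end")
)

#: 1-based index pairs connecting each bone's start to its end (COCO skeleton).
SKELETON_EDGES = tuple((i * 2 + 1, i * 2 + 2) for i in range(6))


def keypoint_index(bone: str, side: str, which: str) -> int:
    return KEYPOINT_NAMES.index(f"{bone}_{side}_{which}")


#: Indices exchanged when anatomical left/right swap under a flip.
LR_SWAP = tuple(
    keypoint_index(name.split("_")[0], "R" if name.split("_")[1] == "L" else "L",
                   name.split("_")[2])
    for name in KEYPOINT_NAMES
)


@dataclass
class KeypointSet:
    """The 12 named bone-endpoint coordinates of one mouse.

    coords: (12, 2) array of (x, y); visibility: (12,) COCO flags
    (0 = absent, 1 = labeled but invisible, 2 = visible); scores: optional
    per-keypoint confidences in [0, 1].
    """

    coords: np.ndarray
    visibility: np.ndarray = None
    scores: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 2)
        if self.coords.shape[0] != len(KEYPOINT_NAMES):
            raise SchemaError(
                f"KeypointSet needs {len(KEYPOINT_NAMES)} keypoints, "
                f"got {self.coords.shape[0]}")
        if self.visibility is None:
            self.visibility = np.full(len(KEYPOINT_NAMES), 2, dtype=int)
        self.visibility = np.asarray(self.visibility, dtype=int).reshape(-1)
        if self.visibility.shape[0] != len(KEYPOINT_NAMES):
            raise SchemaError("visibility must have 12 entries")
        if self.scores is not None:
            self.scores = np.asarray(self.scores, dtype=float).reshape(-1)
        vis = self.visibility > 0
        pts = self.coords[vis]
        if pts.size and (not np.all(np.isfinite(pts)) or np.any(pts < 0)):
            raise SchemaError("visible keypoints must be finite and non-negative")

    def endpoint_pair(self, bone: str, side: str):
        i = keypoint_index(bone, side, "start")
        j = keypoint_index(bone, side, "end")
        return self.coords[i], self.coords[j], self.visibility[i] > 0, self.visibility[j] > 0


@dataclass
class CohortRecord:
    """One mouse in a phenotyping cohort."""

    mouse_id: str
    age: float  # days
    sex: str  # 'M' or 'F'
    lengths: dict = field(default_factory=dict)  # (bone, side) -> pixels
    source: str = "automated"  # or 'manual'

    def __post_init__(self):
        if self.age <= 0:
            raise SchemaError(f"age must be positive, got {self.age}")
        if self.sex not in ("M", "F"):
            raise SchemaError(f"sex must be 'M' or 'F', got {self.sex!r}")
        for key, v in self.lengths.items():
            if v is not None and not (v > 0):
                raise SchemaError(f"length for {key} must be positive, got {v}")


@dataclass
class AnnotatedMouse:
    keypoints: KeypointSet
    box: np.ndarray  # (4,) xyxy, half-open
    label: int = 1  # category id: 1 = top-view mouse, 2 = non-top-view


@dataclass
class ImageAnnotations:
    image_id: int
    file_name: str
    width: int
    height: int
    mice: list = field(default_factory=list)


# ---------------------------------------------------------------- images

def save_image(path, image: np.ndarray) -> None:
    """Write a [0, 1] float raster as 8-bit grayscale PNG."""
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    Image.fromarray((arr * 255.0 + 0.5).astype(np.uint8), mode="L").save(path)


def load_image(path) -> np.ndarray:
    """Read a grayscale PNG/TIFF to float32 in [0, 1].

    8-bit input is divided by 255; 16-bit input is linearly rescaled by the
    image's own min/max.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = np.asarray(tifffile.imread(path), dtype=np.float64)
    else:
        arr = np.asarray(Image.open(path).convert("I"), dtype=np.float64)
    if arr.ndim != 2:
        raise SchemaError(f"{path.name}: expected a 2-D grayscale raster")
    if arr.max() > 255:  # 16-bit: rescale by own range
        lo, hi = arr.min(), arr.max()
        arr = (arr - lo) / max(hi - lo, 1e-12)
    else:
        arr = arr / 255.0
    return arr.astype(np.float32)


# ------------------------------------------------------- COCO keypoints

_CATEGORIES = [
    {"id": 1, "name": "mouse_top", "keypoints": list(KEYPOINT_NAMES),
     "skeleton": [list(e) for e in SKELETON_EDGES]},
    {"id": 2, "name": "mouse_nontop", "keypoints": list(KEYPOINT_NAMES),
     "skeleton": [list(e) for e in SKELETON_EDGES]},
]


def write_coco_keypoints(path, images: list[ImageAnnotations]) -> None:
    doc = {"images": [], "annotations": [], "categories": _CATEGORIES}
    ann_id = 1
    for rec in images:
        doc["images"].append({"id": int(rec.image_id), "file_name": rec.file_name,
                              "width": int(rec.width), "height": int(rec.height)})
        for mouse in rec.mice:
            x0, y0, x1, y1 = (float(v) for v in mouse.box)
            kps = []
            for (x, y), v in zip(mouse.keypoints.coords, mouse.keypoints.visibility):
                kps.extend([float(x), float(y), int(v)])
            doc["annotations"].append({
                "id": ann_id, "image_id": int(rec.image_id),
                "category_id": int(mouse.label),
                "bbox": [x0, y0, x1 - x0, y1 - y0],
                "area": (x1 - x0) * (y1 - y0), "iscrowd": 0,
                "keypoints": kps,
                "num_keypoints": int(np.sum(mouse.keypoints.visibility > 0)),
            })
            ann_id += 1
    Path(path).write_text(json.dumps(doc, indent=1))


def read_coco_keypoints(path) -> list[ImageAnnotations]:
    """Parse a COCO-keypoints file; rejects malformed records loudly."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid JSON ({exc})") from exc
    for key in ("images", "annotations", "categories"):
        if key not in doc:
            raise SchemaError(f"{path}: missing top-level '{key}' section")
    known = {c["id"] for c in doc["categories"]}
    out: dict[int, ImageAnnotations] = {}
    for im in doc["images"]:
        out[im["id"]] = ImageAnnotations(im["id"], im["file_name"],
                                         im["width"], im["height"])
    for ann in doc["annotations"]:
        aid = ann.get("id", "?")
        if ann.get("category_id") not in known:
            raise SchemaError(f"annotation {aid}: unknown category "
                              f"{ann.get('category_id')}")
        kps = ann.get("keypoints", [])
        if len(kps) != 3 * len(KEYPOINT_NAMES):
            raise SchemaError(
                f"annotation {aid}: expected {len(KEYPOINT_NAMES)} keypoints, "
                f"got {len(kps) // 3}")
        if ann["image_id"] not in out:
            raise SchemaError(f"annotation {aid}: unknown image_id {ann['image_id']}")
        arr = np.asarray(kps, dtype=float).reshape(-1, 3)
        ks = KeypointSet(arr[:, :2], arr[:, 2].astype(int))
        x, y, w, h = ann["bbox"]
        out[ann["image_id"]].mice.append(
            AnnotatedMouse(ks, np.array([x, y, x + w, y + h], dtype=float),
                           int(ann["category_id"])))
    return [out[k] for k in sorted(out)]


# ------------------------------------------------------------ CSV tables

MEASUREMENT_COLUMNS = ["image", "mouse_index", "bone", "side", "start_x",
                       "start_y", "end_x", "end_y", "length_px",
                       "top_view_prob", "flags"]


def _fmt(v) -> str:
    return "" if v is None or (isinstance(v, float) and np.isnan(v)) else f"{v:.4f}"


def write_measurements(records, path, header_comment: str | None = None) -> None:
    """One CSV row per (mouse, bone, side); lengths at fixed 4-decimal precision."""
    rows = []
    for m in records:
        rows.append({
            "image": m.image_id, "mouse_index": m.mouse_index,
            "bone": m.bone, "side": m.side,
            "start_x": _fmt(None if m.start is None else m.start[0]),
            "start_y": _fmt(None if m.start is None else m.start[1]),
            "end_x": _fmt(None if m.end is None else m.end[0]),
            "end_y": _fmt(None if m.end is None else m.end[1]),
            "length_px": _fmt(m.length),
            "top_view_prob": _fmt(m.top_view_prob),
            "flags": "|".join(sorted(m.flags)),
        })
    frame = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        frame.to_csv(fh, index=False)


def read_measurements(path) -> list:
    from .measure import BoneMeasurement  # local import avoids a cycle

    df = pd.read_csv(path, keep_default_na=False, comment="#")
    missing = set(MEASUREMENT_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for _, r in df.iterrows():
        def num(v):
            return None if v == "" else float(v)

        start = (num(r["start_x"]), num(r["start_y"]))
        end = (num(r["end_x"]), num(r["end_y"]))
        out.append(BoneMeasurement(
            image_id=str(r["image"]), mouse_index=int(r["mouse_index"]),
            bone=str(r["bone"]), side=str(r["side"]),
            start=None if start[0] is None else np.array(start),
            end=None if end[0] is None else np.array(end),
            length=num(r["length_px"]),
            top_view_prob=num(r["top_view_prob"]) or 0.0,
            flags=set(f for f in str(r["flags"]).split("|") if f)))
    return out


COHORT_COLUMNS = ["mouse_id", "age", "sex", "source"] + [
    f"{bone}_{side}" for bone in BONES for side in SIDES]


def write_cohort(records_or_frame, path) -> None:
    frame = cohort_frame(records_or_frame)
    frame.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    if (df["age"] <= 0).any():
        raise SchemaError(f"{path}: non-positive ages present")
    bad_sex = set(df["sex"]) - {"M", "F"}
    if bad_sex:
        raise SchemaError(f"{path}: invalid sex values {sorted(bad_sex)}")
    return df


def cohort_frame(records_or_frame) -> pd.DataFrame:
    """Normalize a list of CohortRecord (or a DataFrame) to the cohort schema."""
    if isinstance(records_or_frame, pd.DataFrame):
        return records_or_frame[COHORT_COLUMNS]
    rows = []
    for r in records_or_frame:
        row = {"mouse_id": r.mouse_id, "age": r.age, "sex": r.sex,
               "source": r.source}
        for bone in BONES:
            for side in SIDES:
                row[f"{bone}_{side}"] = r.lengths.get((bone, side), np.nan)
        rows.append(row)
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)
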