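"""Evaluation metrics and cohort statistics.

Detection is scored by *objectness accuracy* — the fraction of images whose
retained-detection count equals the true mouse count — and keypoint quality
by the mean squared pixel distance between matched predicted and true
keypoints. Cohort analyses compare automated and manual bone lengths by
Pearson correlation, residualize lengths against age per sex with a
regression spline, and compare method variances with a two-sided F-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import interpolate
from scipy import stats as sps

from .errors import ConfigError
from .io import BONES, SIDES, cohort_frame
from .model import box_iou


# ------------------------------------------------------------- matching

def match_by_iou(gt_boxes: np.ndarray, pred_boxes: np.ndarray,
                 iou_threshold: float = 0.5) -> list[tuple[int, int]]:
    """Greedy one-to-one matching by descending IoU above threshold."""
    gt_boxes = np.atleast_2d(np.asarray(gt_boxes, dtype=float))
    pred_boxes = np.atleast_2d(np.asarray(pred_boxes, dtype=float))
    if gt_boxes.size == 0 or pred_boxes.size == 0:
        return []
    iou = box_iou(gt_boxes, pred_boxes)
    pairs = []
    used_g, used_p = set(), set()
    order = np.dstack(np.unravel_index(np.argsort(-iou, axis=None), iou.shape))[0]
    for gi, pi in order:
        if iou[gi, pi] <= iou_threshold:
            break
        if gi in used_g or pi in used_p:
            continue
        pairs.append((int(gi), int(pi)))
        used_g.add(int(gi))
        used_p.add(int(pi))
    return pairs


def keypoint_mse(gt: list, pred: list, matching=None) -> float:
    """Mean squared pixel distance over matched visible keypoints."""
    if matching is None:
        if len(gt) != len(pred):
            raise ConfigError("without explicit matching, gt and pred must "
                              "pair elementwise")
        matching = list(zip(range(len(gt)), range(len(pred))))
    if not matching:
        raise ConfigError("no matched pairs: keypoint MSE undefined")
    errs = []
    for gi, pi in matching:
        g, p = gt[gi], pred[pi]
        vis = (g.visibility > 0) & (p.visibility > 0)
        d = g.coords[vis] - p.coords[vis]
        errs.append(np.sum(d ** 2, axis=1))
    errs = np.concatenate(errs)
    if errs.size == 0:
        raise ConfigError("no visible matched keypoints")
    return float(np.mean(errs))


def objectness_accuracy(true_counts, predictions, threshold=None) -> float:
    """Fraction of images whose detection count equals the true mouse count.

    ``predictions`` items are either integers or lists of detections (which
    are filtered at ``threshold`` first when one is given).
    """
    from .measure import filter_detections

    if len(true_counts) != len(predictions):
        raise ConfigError("true_counts and predictions must align")
    if len(true_counts) == 0:
        raise ConfigError("no images to score")
    hits = 0
    for t, p in zip(true_counts, predictions):
        if not isinstance(p, (int, np.integer)):
            p = len(filter_detections(p, threshold) if threshold is not None
                    else p)
        hits += int(p == int(t))
    return hits / len(true_counts)


# ----------------------------------------------------------- correlation

@dataclass
class CorrelationResult:
    r: float
    r2: float
    p_value: float
    n: int
    slope: float
    intercept: float


def correlate(manual, automated) -> CorrelationResult:
    """Pearson correlation + least-squares line between paired lengths."""
    x = np.asarray(manual, dtype=float)
    y = np.asarray(automated, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigError("correlate expects two equal-length 1-D vectors")
    if len(x) < 3:
        raise ConfigError("need at least 3 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ConfigError("non-finite values in correlation input")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ConfigError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    reg = sps.linregress(x, y)
    return CorrelationResult(float(r), float(r) ** 2, float(p), len(x),
                             float(reg.slope), float(reg.intercept))


# ---------------------------------------------------------- residualize

def _spline_design(age: np.ndarray, df: int):
    """Intercept + cubic B-spline basis (first basis column dropped)."""
    degree = 3
    uniq = np.unique(age)
    df = int(min(df, max(len(uniq) - 1, 1)))
    n_inner = max(df - degree - 1, 0)
    if n_inner:
        qs = np.linspace(0, 1, n_inner + 2)[1:-1]
        inner = np.quantile(age, qs)
    else:
        inner = np.array([])
    deg = min(degree, df)
    t = np.r_[[age.min()] * (deg + 1), inner, [age.max()] * (deg + 1)]
    basis = interpolate.BSpline.design_matrix(
        np.clip(age, age.min(), age.max()), t, deg).toarray()
    return np.column_stack([np.ones(len(age)), basis[:, 1:]])


def residualize(records, bone: str, side: str, df: int = 5,
                penalty: float = 0.0, min_per_sex: int = 20) -> np.ndarray:
    """Residual bone length after a per-sex smooth fit of length vs age.

    Fits, separately within each sex, a cubic regression B-spline of length
    on age (optionally ridge-penalized on the non-intercept coefficients;
    the intercept is never penalized, so residuals are exactly mean-zero per
    sex). Returns residuals aligned with the input order.
    """
    frame = records if isinstance(records, pd.DataFrame) else cohort_frame(records)
    col = f"{bone}_{side}"
    if col not in frame.columns:
        raise ConfigError(f"no column {col!r} in cohort data")
    resid = np.full(len(frame), np.nan)
    for sex in ("M", "F"):
        mask = (frame["sex"] == sex).to_numpy()
        sub = frame.loc[mask]
        if len(sub) < min_per_sex:
            raise ConfigError(f"stratum sex={sex}: only {len(sub)} records "
                              f"(need >= {min_per_sex})")
        age = sub["age"].to_numpy(dtype=float)
        y = sub[col].to_numpy(dtype=float)
        if len(np.unique(age)) < 2:
            raise ConfigError(f"stratum sex={sex}: ages must span at least "
                              f"2 distinct values")
        X = _spline_design(age, df)
        if penalty > 0:
            pen = np.sqrt(penalty) * np.eye(X.shape[1])
            pen[0, 0] = 0.0  # intercept unpenalized -> mean-zero residuals
            Xa = np.vstack([X, pen])
            ya = np.r_[y, np.zeros(X.shape[1])]
        else:
            Xa, ya = X, y
        beta, *_ = np.linalg.lstsq(Xa, ya, rcond=None)
        resid[mask] = y - X @ beta
    return resid


# --------------------------------------------------------------- F-test

@dataclass
class FTestResult:
    F: float
    p_value: float
    ratio: float
    df: tuple[int, int]


def variance_f_test(residuals_a, residuals_b) -> FTestResult:
    """Two-sided F-test comparing sample variances (a over b)."""
    a = np.asarray(residuals_a, dtype=float)
    b = np.asarray(residuals_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ConfigError("need at least 3 observations per sample")
    va = np.var(a, ddof=1)
    vb = np.var(b, ddof=1)
    if vb == 0:
        raise ConfigError("zero variance in denominator sample")
    f = float(va / vb)
    dfa, dfb = len(a) - 1, len(b) - 1
    cdf = sps.f.cdf(f, dfa, dfb)
    p = float(2.0 * min(cdf, 1.0 - cdf))
    return FTestResult(f, min(p, 1.0), f, (dfa, dfb))


# ------------------------------------------------------------ reporting

@dataclass
class EvaluationReport:
    objectness_accuracy: float
    keypoint_mse: float | None
    per_bone_correlation: dict = field(default_factory=dict)
    variance_tests: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.objectness_accuracy <= 1.0:
            raise ConfigError("accuracy must be in [0, 1]")
        if self.keypoint_mse is not None and self.keypoint_mse < 0:
            raise ConfigError("keypoint MSE must be non-negative")

    def to_dict(self) -> dict:
        return {
            "objectness_accuracy": self.objectness_accuracy,
            # squared pixel distance; source tables label the column 'pixels'
            "keypoint_mse": self.keypoint_mse,
            "per_bone_correlation": {
                k: vars(v) if isinstance(v, CorrelationResult) else v
                for k, v in self.per_bone_correlation.items()},
            "variance_tests": {
                k: {**vars(v), "df": list(v.df)} if isinstance(v, FTestResult)
                else v
                for k, v in self.variance_tests.items()},
        }


def evaluation_report(gt_samples: list[dict], predictions: list,
                      threshold: float = 0.5) -> EvaluationReport:
    """Score predictions against ground truth samples.

    gt_samples: dicts with 'boxes' and 'keypoints' (see training samples);
    predictions: per-image lists of MouseDetection (unfiltered).
    """
    from .measure import filter_detections, measure_bones

    kept = [filter_detections(p, threshold) for p in predictions]
    acc = objectness_accuracy([len(s["boxes"]) for s in gt_samples], kept)

    gt_sets, pred_sets = [], []
    gt_len: dict[str, list] = {b: [] for b in BONES}
    auto_len: dict[str, list] = {b: [] for b in BONES}
    for s, dets in zip(gt_samples, kept):
        if not dets or not len(s["boxes"]):
            continue
        pairs = match_by_iou(s["boxes"], np.array([d.box for d in dets]))
        for gi, pi in pairs:
            gt_sets.append(s["keypoints"][gi])
            pred_sets.append(dets[pi].keypoints)
            gm = {(m.bone, m.side): m.length for m in measure_bones(
                _as_detection(s, gi))}
            am = {(m.bone, m.side): m.length for m in measure_bones(dets[pi])}
            for bone in BONES:
                for side in SIDES:
                    if gm[(bone, side)] is not None and am[(bone, side)] is not None:
                        gt_len[bone].append(gm[(bone, side)])
                        auto_len[bone].append(am[(bone, side)])

    kmse = keypoint_mse(gt_sets, pred_sets) if gt_sets else None
    corr = {}
    for bone in BONES:
        if len(gt_len[bone]) >= 3 and np.var(gt_len[bone]) > 0:
            corr[bone] = correlate(gt_len[bone], auto_len[bone])
    return EvaluationReport(acc, kmse, corr)


def _as_detection(sample: dict, index: int):
    from .model import MouseDetection

    return MouseDetection(box=np.asarray(sample["boxes"][index], dtype=float),
                          top_view_prob=1.0,
                          keypoints=sample["keypoints"][index])
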