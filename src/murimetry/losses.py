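"""The detector's combined loss: objectness + class + keypoint terms.

These are the reference, evaluation-facing definitions operating on plain
arrays. ``objectness_loss`` is the mean binary cross-entropy over predicted
boxes, ``class_loss`` the mean categorical cross-entropy, and
``keypoint_loss`` the per-box summed squared coordinate error averaged over
boxes. The keypoint term is implemented with positive sign (a squared error
can only be a loss when non-negative). During full detector training the
keypoint head is supervised either by this coordinate loss through a
soft-argmax decode or, by default, by per-keypoint heatmap cross-entropy;
see :mod:`murimetry.train`.

Each function has an analytic gradient companion (``*_grad``) used for
finite-difference verification and for the coordinate-supervision path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError

EPS = 1e-7  # probability clamp before logs


@dataclass
class LossBatch:
    """All quantities entering the combined loss for one batch.

    y: (N,) objectness labels in {0,1}; p: (N,) objectness scores;
    Y: (N, C) one-hot class labels; P: (N, C) class probabilities;
    pred/gt: (N, K, 2) keypoint coordinates; visibility: optional (N, K)
    mask — invisible keypoints are excluded from the keypoint sum while the
    divisor stays N.
    """

    y: np.ndarray
    p: np.ndarray
    Y: np.ndarray
    P: np.ndarray
    pred: np.ndarray
    gt: np.ndarray
    visibility: np.ndarray | None = None

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float).reshape(-1)
        self.p = np.clip(np.asarray(self.p, dtype=float).reshape(-1), EPS, 1 - EPS)
        self.Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        self.P = np.clip(np.atleast_2d(np.asarray(self.P, dtype=float)), EPS, 1 - EPS)
        self.pred = np.asarray(self.pred, dtype=float)
        self.gt = np.asarray(self.gt, dtype=float)
        if self.pred.ndim == 2:
            self.pred = self.pred[None]
        if self.gt.ndim == 2:
            self.gt = self.gt[None]
        n = self.y.shape[0]
        if n == 0:
            raise ConfigError("LossBatch requires N >= 1 predicted boxes")
        if not np.all(np.isin(self.y, (0.0, 1.0))):
            raise ConfigError("objectness labels must be in {0, 1}")
        if self.Y.shape != self.P.shape:
            raise ConfigError("Y and P must have the same (N, C) shape")
        rowsums = self.Y.sum(axis=1)
        if not (np.allclose(rowsums, 1.0) and np.all(np.isin(self.Y, (0.0, 1.0)))):
            raise ConfigError("rows of Y must be one-hot")
        if not np.allclose(self.P.sum(axis=1), 1.0, atol=1e-5):
            raise ConfigError("rows of P must sum to 1")
        if self.pred.shape != self.gt.shape:
            raise ConfigError("pred and gt must have the same (N, K, 2) shape")
        if self.visibility is not None:
            self.visibility = np.asarray(self.visibility, dtype=bool)
            if self.visibility.shape != self.pred.shape[:2]:
                raise ConfigError("visibility must have shape (N, K)")

    @property
    def n_boxes(self) -> int:
        return self.y.shape[0]


def objectness_loss(batch: LossBatch) -> float:
    """Mean binary cross-entropy between objectness labels and scores."""
    y, p = batch.y, batch.p
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def objectness_loss_grad(batch: LossBatch) -> np.ndarray:
    """d(objectness_loss)/dp."""
    y, p = batch.y, batch.p
    return (-(y / p) + (1 - y) / (1 - p)) / batch.n_boxes


def class_loss(batch: LossBatch) -> float:
    """Mean categorical cross-entropy between one-hot labels and class probs."""
    return float(-np.sum(batch.Y * np.log(batch.P)) / batch.n_boxes)


def class_loss_grad(batch: LossBatch) -> np.ndarray:
    """d(class_loss)/dP."""
    return -(batch.Y / batch.P) / batch.n_boxes


def keypoint_loss(batch: LossBatch) -> float:
    """Per-box summed squared keypoint error, averaged over boxes."""
    sq = np.sum((batch.pred - batch.gt) ** 2, axis=2)  # (N, K)
    if batch.visibility is not None:
        sq = sq * batch.visibility
    return float(np.sum(sq) / batch.n_boxes)


def keypoint_loss_grad(batch: LossBatch) -> np.ndarray:
    """d(keypoint_loss)/dpred."""
    d = 2.0 * (batch.pred - batch.gt) / batch.n_boxes
    if batch.visibility is not None:
        d = d * batch.visibility[..., None]
    return d


def total_loss(batch: LossBatch) -> float:
    """Sum of the objectness, class and keypoint terms."""
    return objectness_loss(batch) + class_loss(batch) + keypoint_loss(batch)
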