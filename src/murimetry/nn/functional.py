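"""Stateless ops: activations, losses with analytic gradients, ROI align.

Loss helpers return ``(scalar_loss, dlogits)`` so training code never has to
re-derive gradients.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def sigmoid_bce_with_logits(logits: np.ndarray, targets: np.ndarray):
    """Mean binary cross-entropy; returns (loss, dlogits)."""
    p = sigmoid(logits)
    n = max(logits.size, 1)
    loss = float(np.mean(np.clip(logits, 0, None) - logits * targets
                         + np.log1p(np.exp(-np.abs(logits)))))
    return loss, ((p - targets) / n).astype(F32)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """logits (N,C), integer labels (N,); mean CE and dlogits."""
    n = logits.shape[0]
    p = softmax(logits, axis=1)
    eps = 1e-12
    loss = float(-np.mean(np.log(p[np.arange(n), labels] + eps)))
    d = p.copy()
    d[np.arange(n), labels] -= 1.0
    return loss, (d / n).astype(F32)


def spatial_softmax_cross_entropy(logits: np.ndarray, targets: np.ndarray,
                                  valid: np.ndarray, sigma: float = 0.0):
    """Per-keypoint heatmap classification over all spatial bins.

    logits: (R, K, H, W); targets: (R, K, 2) integer (col, row) bin indices;
    valid: (R, K) bool. Mean CE over valid keypoints and dlogits.

    With ``sigma > 0`` the one-hot target is replaced by a normalized
    Gaussian centred on the target bin (soft label); the symmetric peak
    keeps the argmax at the target bin while spreading gradient signal.
    """
    r, k, h, w = logits.shape
    flat = logits.reshape(r * k, h * w)
    p = softmax(flat, axis=1)
    v = valid.reshape(-1)
    nv = max(int(v.sum()), 1)
    eps = 1e-12
    tx = targets[..., 0].reshape(-1)
    ty = targets[..., 1].reshape(-1)
    if sigma > 0:
        ax = np.arange(w, dtype=float)
        ay = np.arange(h, dtype=float)
        qx = np.exp(-0.5 * ((ax[None, :] - tx[:, None]) / sigma) ** 2)
        qy = np.exp(-0.5 * ((ay[None, :] - ty[:, None]) / sigma) ** 2)
        q = qy[:, :, None] * qx[:, None, :]
        q = (q / q.sum(axis=(1, 2), keepdims=True)).reshape(r * k, h * w)
        loss = float(-np.sum(q * np.log(p + eps) * v[:, None]) / nv)
        d = p - q
    else:
        idx = np.clip(ty * w + tx, 0, h * w - 1)
        loss = float(-np.sum(np.log(p[np.arange(r * k), idx] + eps) * v) / nv)
        d = p
        d[np.arange(r * k), idx] -= 1.0
    d = d * (v / nv)[:, None]
    return loss, d.reshape(r, k, h, w).astype(F32)


def smooth_l1(pred: np.ndarray, target: np.ndarray, beta: float = 1.0):
    """Mean smooth-L1 (Huber); returns (loss, dpred)."""
    diff = pred - target
    a = np.abs(diff)
    n = max(pred.size, 1)
    loss = float(np.sum(np.where(a < beta, 0.5 * diff ** 2 / beta, a - 0.5 * beta)) / n)
    d = np.where(a < beta, diff / beta, np.sign(diff)) / n
    return loss, d.astype(F32)


def roi_align(feat: np.ndarray, boxes: np.ndarray, out_size: int):
    """Bilinear ROI align, one sample per output bin.

    feat: (C, H, W); boxes: (R, 4) as (x0, y0, x1, y1) in feature coordinates.
    Returns (out (R, C, S, S), backward) where backward(dout) -> dfeat.
    """
    c, h, w = feat.shape
    rno = boxes.shape[0]
    s = out_size
    out = np.zeros((rno, c, s, s), dtype=F32)
    caches = []
    for ri in range(rno):
        x0, y0, x1, y1 = boxes[ri]
        bw = max(x1 - x0, 1e-3)
        bh = max(y1 - y0, 1e-3)
        xs = x0 + (np.arange(s) + 0.5) * bw / s - 0.5
        ys = y0 + (np.arange(s) + 0.5) * bh / s - 0.5
        gx, gy = np.meshgrid(xs, ys)  # (s,s)
        x0i = np.clip(np.floor(gx).astype(int), 0, w - 1)
        y0i = np.clip(np.floor(gy).astype(int), 0, h - 1)
        x1i = np.clip(x0i + 1, 0, w - 1)
        y1i = np.clip(y0i + 1, 0, h - 1)
        fx = np.clip(gx - x0i, 0.0, 1.0)
        fy = np.clip(gy - y0i, 0.0, 1.0)
        w00 = (1 - fx) * (1 - fy)
        w01 = fx * (1 - fy)
        w10 = (1 - fx) * fy
        w11 = fx * fy
        out[ri] = (feat[:, y0i, x0i] * w00 + feat[:, y0i, x1i] * w01
                   + feat[:, y1i, x0i] * w10 + feat[:, y1i, x1i] * w11)
        caches.append((x0i, y0i, x1i, y1i, w00, w01, w10, w11))

    def backward(dout: np.ndarray) -> np.ndarray:
        dfeat = np.zeros_like(feat)
        for ri in range(rno):
            x0i, y0i, x1i, y1i, w00, w01, w10, w11 = caches[ri]
            for ch in range(c):
                d = dout[ri, ch]
                np.add.at(dfeat[ch], (y0i, x0i), d * w00)
                np.add.at(dfeat[ch], (y0i, x1i), d * w01)
                np.add.at(dfeat[ch], (y1i, x0i), d * w10)
                np.add.at(dfeat[ch], (y1i, x1i), d * w11)
        return dfeat

    return out, backward
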