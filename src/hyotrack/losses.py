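"""Focal loss for class-imbalanced per-pixel classification.

FL(p_t) = -alpha * (1 - p_t)^gamma * log(p_t), averaged over pixels, where
p_t is the predicted probability of the pixel's true class.  gamma = 0
recovers alpha-scaled cross-entropy; gamma > 0 down-weights easy (mostly
background) pixels so the small hyoid/coin regions dominate the gradient.
"""

from __future__ import annotations

import numpy as np

from .nn import tensor as T
from .nn.tensor import Tensor

_P_FLOOR = 1e-7
_LOG_P_FLOOR = float(np.log(_P_FLOOR))


def _one_hot(labels: np.ndarray, num_classes: int) -> np.ndarray:
    return np.eye(num_classes, dtype=np.float32)[labels.astype(np.int64)]


def focal_loss(probs, labels: np.ndarray, alpha: float = 0.25,
               gamma: float = 2.0) -> Tensor:
    """Focal loss from channel-last class probabilities.

    Parameters
    ----------
    probs : Tensor or ndarray, shape (..., K)
        Per-pixel class probabilities (each pixel's vector on the simplex).
    labels : ndarray of int, shape (...)
        True class index per pixel.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    if not isinstance(probs, Tensor):
        probs = Tensor(probs)
    k = probs.shape[-1]
    onehot = _one_hot(labels, k)
    pt = T.tsum(T.mul(probs, Tensor(onehot)), axis=-1)
    pt = T.clamp_min(pt, _P_FLOOR)
    log_pt = T.tlog(pt)
    if gamma == 0:
        weighted = T.mul_scalar(log_pt, -alpha)
    else:
        base = T.clamp_min(T.add(Tensor(np.float32(1.0)), T.mul_scalar(pt, -1.0)), _P_FLOOR)
        mod = T.pow_scalar(base, gamma) if gamma != 1 else base
        weighted = T.mul_scalar(T.mul(mod, log_pt), -alpha)
    return T.tmean(weighted)


def focal_loss_from_logits(logits: Tensor, labels: np.ndarray, alpha: float,
                           gamma: float) -> Tensor:
    """Numerically stable focal loss from NCHW logits (training path)."""
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    n, k, h, w = logits.shape
    log_probs = T.log_softmax(logits, axis=1)
    onehot = _one_hot(labels, k).transpose(0, 3, 1, 2)  # (N, K, H, W)
    log_pt = T.clamp_min(T.tsum(T.mul(log_probs, Tensor(onehot)), axis=1), _LOG_P_FLOOR)
    if gamma == 0:
        weighted = T.mul_scalar(log_pt, -alpha)
    else:
        pt = T.texp(log_pt)
        base = T.clamp_min(T.add(Tensor(np.float32(1.0)), T.mul_scalar(pt, -1.0)), _P_FLOOR)
        mod = T.pow_scalar(base, gamma) if gamma != 1 else base
        weighted = T.mul_scalar(T.mul(mod, log_pt), -alpha)
    return T.tmean(weighted)
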