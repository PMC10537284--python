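"""Training objective and evaluation metrics.

WMAE is the weighted mean absolute error (1/sum w) * sum_i w_i |yp_i - yt_i|.
The accuracy scores are regression-style: the Top-1 score compares the
predicted content of the most probable class against its reference value,
1 - |Xp - Xr| / Xr, clamped at 0 (a nutrient predicted absent scores 0);
the Top-5 score averages the clamped per-class scores over the five classes
with the largest predicted probability.  Background stability is the
population variance, per nutrient class, of predictions for one foreground
rendered over different backgrounds — smaller is better.
"""

from __future__ import annotations

import numpy as np
from scipy import special as _sp

__all__ = [
    "wmae",
    "gelu",
    "top1_acc",
    "top5_acc",
    "top1_from_vectors",
    "top5_from_vectors",
    "stability_variance",
]


def wmae(w: np.ndarray, y_pred: np.ndarray, y_true: np.ndarray) -> float:
    """(1/sum w) * sum_i w_i |y_pred_i - y_true_i|; weights must be positive."""
    w = np.asarray(w, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    y_true = np.asarray(y_true, dtype=np.float64)
    if not (w.shape == y_pred.shape == y_true.shape):
        raise ValueError(f"length mismatch: w{w.shape}, pred{y_pred.shape}, true{y_true.shape}")
    if (w <= 0).any():
        raise ValueError("weights must be strictly positive")
    return float(np.sum(w * np.abs(y_pred - y_true)) / np.sum(w))


def gelu(x):
    """x * Phi(x) with Phi the exact standard-normal CDF (erf-based)."""
    x = np.asarray(x, dtype=np.float64)
    out = x * 0.5 * (1.0 + _sp.erf(x / np.sqrt(2.0)))
    return float(out) if out.ndim == 0 else out


def _score(xp: float, xr: float) -> float:
    if xr <= 0:
        raise ValueError(f"reference content must be positive, got {xr}")
    return max(0.0, 1.0 - abs(xp - xr) / xr)


def top1_acc(xp: float, xr: float) -> float:
    """max(0, 1 - |Xp - Xr| / Xr) for the most probable class's content."""
    return _score(float(xp), float(xr))


def top5_acc(xp: np.ndarray, xr: np.ndarray) -> float:
    """Mean of the five per-class clamped scores."""
    xp = np.asarray(xp, dtype=np.float64)
    xr = np.asarray(xr, dtype=np.float64)
    if xp.shape != (5,) or xr.shape != (5,):
        raise ValueError("top5_acc requires exactly five paired values")
    return float(np.mean([_score(p, r) for p, r in zip(xp, xr)]))


def top1_from_vectors(pred: np.ndarray, true: np.ndarray) -> float:
    """Top-1 score of a predicted distribution against the reference vector:
    the class with the largest predicted probability is scored on content."""
    pred = np.asarray(pred, dtype=np.float64)
    true = np.asarray(true, dtype=np.float64)
    j = int(np.argmax(pred))
    return top1_acc(pred[j], true[j])


def top5_from_vectors(pred: np.ndarray, true: np.ndarray) -> float:
    """Top-5 score over the five classes with largest predicted probability."""
    pred = np.asarray(pred, dtype=np.float64)
    true = np.asarray(true, dtype=np.float64)
    if pred.size < 5:
        raise ValueError(f"need at least five classes, got {pred.size}")
    top = np.argsort(pred, kind="stable")[::-1][:5]
    return top5_acc(pred[top], true[top])


def stability_variance(preds) -> np.ndarray:
    """Population variance per nutrient class across background variants."""
    preds = np.asarray(preds, dtype=np.float64)
    if preds.ndim != 2 or preds.shape[0] < 2:
        raise ValueError("stability needs at least two prediction vectors")
    return preds.var(axis=0)  # ddof=0: population variance
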