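"""Overlap and boundary metrics for vessel masks.

The Tversky index generalizes Dice with asymmetric false-negative /
false-positive weights; its soft form is the training loss of the
segmenter.  The BF (boundary-F1) score measures how well predicted mask
boundaries align with reference boundaries within a pixel tolerance.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

log = logging.getLogger(__name__)

_EPS = 1e-8


def tversky_index(
    pred: np.ndarray, target: np.ndarray, alpha: float = 0.5, beta: float = 0.5
) -> float:
    """Soft Tversky index TP / (TP + alpha*FN + beta*FP) on probabilities.

    With alpha = beta = 0.5 this equals the Dice coefficient.  An empty
    target with an empty prediction is perfect agreement (index 1).
    """
    p = np.asarray(pred, dtype=float)
    t = np.asarray(target, dtype=float)
    if p.shape != t.shape:
        raise ValueError("pred and target shapes differ")
    if alpha < 0 or beta < 0:
        raise ValueError("alpha and beta must be non-negative")
    tp = float((p * t).sum())
    fn = float(((1.0 - p) * t).sum())
    fp = float((p * (1.0 - t)).sum())
    denom = tp + alpha * fn + beta * fp
    if denom == 0.0:
        if fn == 0.0 and fp == 0.0:
            log.info("empty target and prediction: Tversky index defined as 1")
            return 1.0
        return 0.0  # only reachable with zero alpha/beta weights on errors
    return tp / denom


def tversky_loss(pred, target, alpha=0.7, beta=0.3) -> float:
    return 1.0 - tversky_index(pred, target, alpha, beta)


def clean_mask(mask: np.ndarray, min_area: int = 200) -> np.ndarray:
    """Remove connected components smaller than ``min_area`` pixels.

    Area opening: components with area >= min_area survive untouched.
    """
    if min_area < 0:
        raise ValueError("min_area must be >= 0")
    m = np.asarray(mask).astype(bool)
    labels, n = ndimage.label(m, structure=np.ones((3, 3)))
    if n == 0:
        return m
    areas = np.bincount(labels.ravel())
    keep = areas >= min_area
    keep[0] = False
    return keep[labels]


def _boundary(mask: np.ndarray) -> np.ndarray:
    m = mask.astype(bool)
    return m & ~ndimage.binary_erosion(m, structure=np.ones((3, 3)), border_value=0)


def bf_score(pred: np.ndarray, truth: np.ndarray, tolerance_px: float | None = None) -> float:
    """Boundary-F1: F-measure over boundary pixels matched within a tolerance.

    Default tolerance is 0.75% of the image diagonal.  Both masks empty is
    perfect agreement (1.0); exactly one empty boundary scores 0.
    """
    p = np.asarray(pred).astype(bool)
    t = np.asarray(truth).astype(bool)
    if p.shape != t.shape:
        raise ValueError("shape mismatch")
    if tolerance_px is None:
        tolerance_px = 0.0075 * float(np.hypot(*p.shape))
    bp, bt = _boundary(p), _boundary(t)
    if not bp.any() and not bt.any():
        log.info("both boundaries empty: BF score defined as 1")
        return 1.0
    if not bp.any() or not bt.any():
        return 0.0
    dist_to_t = ndimage.distance_transform_edt(~bt)
    dist_to_p = ndimage.distance_transform_edt(~bp)
    precision = float((dist_to_t[bp] <= tolerance_px).mean())
    recall = float((dist_to_p[bt] <= tolerance_px).mean())
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def dice_score(pred: np.ndarray, truth: np.ndarray) -> float:
    """Hard Dice coefficient on binary masks."""
    return tversky_index(np.asarray(pred).astype(float), np.asarray(truth).astype(float), 0.5, 0.5)
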