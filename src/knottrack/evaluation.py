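"""Accuracy metrics against ground truth.

Detection accuracy is scored with a tolerance-based Sorensen-Dice
index: a detected skeleton pixel within 2 px (the point-spread-function
scale) of any ground-truth pixel is a true positive, the rest are
false positives, and truth pixels with no detection within tolerance
are false negatives.  Curve similarity is the discrete Frechet
distance — the minimum over monotone couplings of the maximum pointwise
Euclidean separation — which, unlike set metrics, is sensitive to the
ordering of contour indices.  Per-pixel position error is the nearest
distance from each detected pixel to the truth set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "MatchCounts",
    "match_pixels",
    "dice_index",
    "frechet_distance",
    "position_error",
]


@dataclass(frozen=True)
class MatchCounts:
    """Tolerance-matched detection counts."""

    tp: int
    fp: int
    fn: int
    tolerance_px: float = 2.0

    def __post_init__(self) -> None:
        if self.tp < 0 or self.fp < 0 or self.fn < 0:
            raise ValueError("counts must be nonnegative")
        if self.tolerance_px <= 0:
            raise ValueError("tolerance_px must be positive")


def _as_points(pixels) -> np.ndarray:
    arr = np.asarray(list(pixels) if isinstance(pixels, (set, frozenset))
                     else pixels, dtype=float)
    return arr.reshape(-1, 2)


def match_pixels(detected, truth, tolerance_px: float = 2.0) -> MatchCounts:
    """Count TP/FP/FN under a nearest-distance tolerance.

    TP: detected pixels within ``tolerance_px`` of some truth pixel;
    FP: the remaining detected pixels; FN: truth pixels with no
    detected pixel within tolerance.
    """
    if tolerance_px <= 0:
        raise ValueError("tolerance_px must be positive")
    det = _as_points(detected)
    tru = _as_points(truth)
    if len(det) == 0:
        return MatchCounts(0, 0, len(tru), tolerance_px)
    if len(tru) == 0:
        return MatchCounts(0, len(det), 0, tolerance_px)
    d_det = cKDTree(tru).query(det)[0]
    d_tru = cKDTree(det).query(tru)[0]
    tp = int((d_det <= tolerance_px).sum())
    fp = len(det) - tp
    fn = int((d_tru > tolerance_px).sum())
    return MatchCounts(tp, fp, fn, tolerance_px)


def dice_index(counts: MatchCounts) -> float:
    """Sorensen-Dice index 2*TP / (2*TP + FP + FN) from matched counts.

    The degenerate all-zero case (nothing detected, nothing to detect)
    is defined as a perfect score of 1 and logged.
    """
    denom = 2 * counts.tp + counts.fp + counts.fn
    if denom == 0:
        warnings.warn("Dice of two empty sets defined as 1", stacklevel=2)
        return 1.0
    return 2.0 * counts.tp / denom


def frechet_distance(curve_a, curve_b) -> float:
    """Discrete Frechet distance between two ordered point sequences.

    Dynamic program over monotone couplings: the minimum, over all
    couplings that traverse both curves in order, of the maximum
    pointwise Euclidean distance.  Zero iff the curves coincide point
    by point in the same order.
    """
    a = _as_points(curve_a)
    b = _as_points(curve_b)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("curves must be non-empty")
    diff = a[:, None, :] - b[None, :, :]
    d = np.sqrt((diff ** 2).sum(axis=2))
    n, m = d.shape
    ca = np.empty((n, m))
    ca[0, 0] = d[0, 0]
    for j in range(1, m):
        ca[0, j] = max(ca[0, j - 1], d[0, j])
    for i in range(1, n):
        ca[i, 0] = max(ca[i - 1, 0], d[i, 0])
        row_prev = ca[i - 1]
        row = ca[i]
        for j in range(1, m):
            row[j] = max(min(row_prev[j - 1], row_prev[j], row[j - 1]),
                         d[i, j])
    return float(ca[-1, -1])


def position_error(detected, truth) -> np.ndarray:
    """Distance from each detected pixel to its nearest truth pixel.

    Returns the per-pixel distances; summarize with mean and SD (the
    parameters of a normal fit to the unbinned errors).
    """
    tru = _as_points(truth)
    if len(tru) == 0:
        raise ValueError("truth must be non-empty")
    det = _as_points(detected)
    if len(det) == 0:
        warnings.warn("no detected pixels; empty error vector", stacklevel=2)
        return np.empty(0)
    return cKDTree(tru).query(det)[0]
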