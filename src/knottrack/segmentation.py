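"""Frame segmentation: grayscale image -> one-pixel-wide skeleton.

The chain is contrast saturation (clip top/bottom 1% of intensities),
3x3 median filtering, Otsu (or user) thresholding with largest-component
selection, Chan-Vese active-contour refinement seeded by the threshold
mask, and medial-axis skeletonization with short-spur pruning.
Everything here is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import medial_axis
from skimage.segmentation import morphological_chan_vese

__all__ = [
    "SegmentationParams",
    "Skeleton",
    "SegmentationError",
    "preprocess",
    "binarize",
    "refine_chan_vese",
    "skeletonize_mask",
    "segment_frame",
]

_MOORE = np.ones((3, 3), dtype=int)


class SegmentationError(RuntimeError):
    """Raised when a frame cannot be segmented (empty foreground)."""


@dataclass(frozen=True)
class SegmentationParams:
    """Headless segmentation parameters.

    ``intensity_threshold`` is a normalized threshold in [0, 1] or the
    string ``"auto"`` for Otsu's method.  ``contraction_bias`` biases
    the active contour inward (> 0 shrinks) and ``smooth_factor``
    weighs boundary regularization, mirroring the usual active-contour
    controls.  ``saturate_frac`` is the clipped fraction per intensity
    tail and ``median_kernel`` the median-filter window (odd).
    """

    intensity_threshold: float | str = "auto"
    ac_iterations: int = 10
    contraction_bias: float = 0.0
    smooth_factor: float = 0.2
    saturate_frac: float = 0.01
    median_kernel: int = 3
    prune_len: int = 5
    tip_extend: bool = True

    def __post_init__(self) -> None:
        if isinstance(self.intensity_threshold, str):
            if self.intensity_threshold != "auto":
                raise ValueError("intensity_threshold must be numeric or 'auto'")
        elif not 0.0 <= float(self.intensity_threshold) <= 1.0:
            raise ValueError("numeric intensity_threshold must be in [0, 1]")
        if self.ac_iterations < 0:
            raise ValueError("ac_iterations must be >= 0")
        if self.median_kernel < 1 or self.median_kernel % 2 == 0:
            raise ValueError("median_kernel must be odd and >= 1")
        if not 0.0 <= self.saturate_frac < 0.5:
            raise ValueError("saturate_frac must be in [0, 0.5)")


@dataclass
class Skeleton:
    """A one-pixel-wide 8-connected binary contour raster.

    ``radius``, when available, is the medial-axis distance map of the
    source mask: the local half-width of the imaged filament at each
    skeleton pixel (diagnostic metadata; wide spots mark fused
    crossings).
    """

    mask: np.ndarray  # boolean (rows, cols)
    radius: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def pixels(self) -> np.ndarray:
        """(N, 2) array of lit (row, col) coordinates."""
        return np.argwhere(self.mask)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    def _neighbor_counts(self) -> np.ndarray:
        """3x3 Moore sums (center included) at every pixel."""
        return ndimage.convolve(self.mask.astype(int), _MOORE, mode="constant")

    @property
    def endpoints(self) -> np.ndarray:
        """Lit pixels with exactly one lit Moore neighbor."""
        counts = self._neighbor_counts()
        return np.argwhere(self.mask & (counts == 2))

    @property
    def branch_pixels(self) -> np.ndarray:
        """Lit pixels whose Moore sum (center included) is >= 4."""
        counts = self._neighbor_counts()
        return np.argwhere(self.mask & (counts >= 4))

    @property
    def is_branched(self) -> bool:
        return len(self.branch_pixels) > 0


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def preprocess(image: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Saturate intensity tails, rescale to [0, 1], median filter."""
    image = np.asarray(image, dtype=float)
    if not np.isfinite(image).all():
        raise ValueError("image must be finite")
    lo = np.quantile(image, params.saturate_frac)
    hi = np.quantile(image, 1.0 - params.saturate_frac)
    if hi <= lo:
        return np.zeros_like(image)
    out = np.clip(image, lo, hi)
    out = (out - lo) / (hi - lo)
    return ndimage.median_filter(out, size=params.median_kernel)


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels = label(mask, connectivity=2)
    if labels.max() == 0:
        return mask
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    return labels == sizes.argmax()


def binarize(image: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Threshold (Otsu or override) and keep the largest component."""
    image = np.asarray(image, dtype=float)
    if params.intensity_threshold == "auto":
        if image.min() == image.max():
            raise SegmentationError("constant image; no foreground")
        thr = threshold_otsu(image)
    else:
        thr = float(params.intensity_threshold)
    mask = image > thr
    if not mask.any():
        raise SegmentationError("empty foreground after thresholding")
    return _largest_component(mask)


def refine_chan_vese(image: np.ndarray, seed_mask: np.ndarray,
                     params: SegmentationParams) -> np.ndarray:
    """Refine a seed mask with a two-phase piecewise-constant model.

    Runs a morphological Chan-Vese evolution for ``ac_iterations``
    iterations from ``seed_mask``.  ``smooth_factor`` sets the number
    of boundary-smoothing passes per iteration; ``contraction_bias``
    re-weights the inside/outside data terms so positive values favor
    shrinkage.  If the evolution empties the mask, the seed is
    returned unchanged.
    """
    seed_mask = np.asarray(seed_mask, dtype=bool)
    if not seed_mask.any():
        raise ValueError("seed_mask must be non-empty")
    if params.ac_iterations == 0:
        return seed_mask.copy()
    smoothing = int(round(params.smooth_factor * 10))
    lam1 = max(1.0 + params.contraction_bias, 1e-3)
    lam2 = max(1.0 - params.contraction_bias, 1e-3)
    refined = morphological_chan_vese(
        np.asarray(image, dtype=float),
        num_iter=params.ac_iterations,
        init_level_set=seed_mask,
        smoothing=smoothing,
        lambda1=lam1,
        lambda2=lam2,
    ).astype(bool)
    if not refined.any():
        return seed_mask.copy()
    return _largest_component(refined)


def _prune_spurs(mask: np.ndarray, prune_len: int) -> np.ndarray:
    """Remove terminal branches shorter than ``prune_len`` pixels.

    Walks inward from each endpoint; if a branch pixel is met within
    ``prune_len`` steps the walked spur is deleted.  Repeats until
    stable so nested spurs collapse.
    """
    mask = mask.copy()
    if prune_len <= 0:
        return mask
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
               (0, 1), (1, -1), (1, 0), (1, 1)]
    changed = True
    while changed:
        changed = False
        counts = ndimage.convolve(mask.astype(int), _MOORE, mode="constant")
        branch = mask & (counts >= 4)
        endpoints = np.argwhere(mask & (counts == 2))
        for ep in endpoints:
            path = [tuple(ep)]
            prev = None
            cur = tuple(ep)
            hit_branch = False
            while len(path) <= prune_len:
                nxt = None
                for dr, dc in offsets:
                    r, c = cur[0] + dr, cur[1] + dc
                    if (r, c) == prev or not (0 <= r < mask.shape[0]
                                              and 0 <= c < mask.shape[1]):
                        continue
                    if mask[r, c] and (r, c) != prev:
                        if branch[r, c]:
                            hit_branch = True
                            nxt = None
                            break
                        if (r, c) not in path:
                            nxt = (r, c)
                if hit_branch or nxt is None:
                    break
                prev, cur = cur, nxt
                path.append(cur)
            if hit_branch and len(path) <= prune_len:
                for r, c in path:
                    mask[r, c] = False
                changed = True
    return mask


def _extend_tips(skel: np.ndarray, mask: np.ndarray,
                 max_ext: float = 8.0) -> np.ndarray:
    """Grow each skeleton endpoint along its outward tangent to the mask edge.

    The medial axis of a round-capped tube stops about one half-width
    short of the cap; walking the tangent ray until it leaves the
    refined mask restores the filament tip (the active-contour
    boundary sits at the true tip to sub-pixel accuracy).
    """
    skel = skel.copy()
    if skel.sum() < 10:
        return skel
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
               (0, 1), (1, -1), (1, 0), (1, 1)]
    counts = ndimage.convolve(skel.astype(int), _MOORE, mode="constant")
    pix = np.argwhere(skel)
    for ep in np.argwhere(skel & (counts == 2)).astype(float):
        d = np.hypot(pix[:, 0] - ep[0], pix[:, 1] - ep[1])
        near = pix[(d > 0) & (d <= 6)]
        if len(near) == 0:
            continue
        tang = ep - near.mean(axis=0)
        norm = np.linalg.norm(tang)
        if norm == 0:
            continue
        tang /= norm
        prev = tuple(ep.astype(int))
        t = 0.5
        while t <= max_ext:
            q = tuple(np.round(ep + tang * t).astype(int))
            t += 0.5
            if q == prev:
                continue
            if not (0 <= q[0] < mask.shape[0] and 0 <= q[1] < mask.shape[1]):
                break
            if not mask[q] or skel[q]:
                break
            # keep the extension a single-pixel chain: the new pixel may
            # touch only its predecessor, otherwise it would thicken the
            # tip into a spurious junction
            nb = sum(skel[q[0] + dr, q[1] + dc]
                     for dr, dc in offsets
                     if 0 <= q[0] + dr < skel.shape[0]
                     and 0 <= q[1] + dc < skel.shape[1])
            if nb > 1:
                break
            skel[q] = True
            prev = q
    return skel


def skeletonize_mask(mask: np.ndarray,
                     params: SegmentationParams | None = None) -> Skeleton:
    """Medial-axis skeleton of a mask, spur-pruned, tips restored."""
    params = params or SegmentationParams()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise SegmentationError("empty mask")
    # fixed rng: medial_axis permutes its boundary-peeling order
    skel, dist = medial_axis(mask, return_distance=True, rng=0)
    skel = _prune_spurs(skel, params.prune_len)
    skel = _largest_component(skel)
    if params.tip_extend:
        skel = _extend_tips(skel, mask)
    if not skel.any():
        raise SegmentationError("mask skeletonized to empty")
    return Skeleton(skel, radius=dist)


def segment_frame(image: np.ndarray,
                  params: SegmentationParams | None = None) -> Skeleton:
    """Full segmentation chain for one frame."""
    params = params or SegmentationParams()
    pre = preprocess(image, params)
    mask = binarize(pre, params)
    mask = refine_chan_vese(pre, mask, params)
    return skeletonize_mask(mask, params)
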