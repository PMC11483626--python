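"""Geometry and dynamics of resolved contours.

Contours are smoothed coordinate-wise with a Savitzky-Golay filter,
differentiated by finite differences to get the tangent angle psi and
the signed-magnitude curvature kappa (Frenet-Serret in the plane), and
summarized per frame (arc length, tip angle, end-to-end distance).
Tip-angle time series are analysed by a one-sided FFT amplitude
spectrum; for motor-driven clamped filaments the dominant peak sits in
the millihertz range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .skeleton_graph import PixelContour

__all__ = [
    "SmoothCurve",
    "FrameStats",
    "smooth_contour",
    "tangent_and_curvature",
    "end_to_end_distance",
    "arc_length",
    "power_spectrum",
    "tip_angle_series",
    "tangent_kymograph",
    "compute_frame_stats",
]


@dataclass
class SmoothCurve:
    """A smoothed real-valued (x, y) curve."""

    points: np.ndarray
    window: int
    polyorder: int

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)


@dataclass
class FrameStats:
    """Per-frame scalar summary of a resolved contour."""

    frame: int
    length_px: float
    tip_angle_rad: float
    end_to_end_px: float


def smooth_contour(contour: PixelContour | np.ndarray,
                   window: int = 11, polyorder: int = 3) -> SmoothCurve:
    """Savitzky-Golay smooth the x and y coordinates independently.

    Edge windows use polynomial extrapolation (``mode='interp'``), so
    a curve sampled from a polynomial of degree <= polyorder is
    reproduced exactly.  A contour shorter than the window shrinks the
    window to the largest valid odd value with a warning.
    """
    pts = contour.xy if isinstance(contour, PixelContour) \
        else np.asarray(contour, dtype=float)
    n = len(pts)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window == 1:
        return SmoothCurve(pts.copy(), window=1, polyorder=polyorder)
    if n <= window:
        new_win = n - 1 if (n - 1) % 2 == 1 else n - 2
        new_win = max(new_win, 1)
        warnings.warn(
            f"contour ({n} points) shorter than window {window}; "
            f"shrinking to {new_win}", stacklevel=2)
        window = new_win
        if window <= polyorder:
            polyorder = max(window - 1, 0)
    if window == 1:
        return SmoothCurve(pts.copy(), window=1, polyorder=polyorder)
    x = savgol_filter(pts[:, 0], window, polyorder, mode="interp")
    y = savgol_filter(pts[:, 1], window, polyorder, mode="interp")
    return SmoothCurve(np.column_stack([x, y]), window=window,
                       polyorder=polyorder)


def _dedup(points: np.ndarray) -> np.ndarray:
    keep = np.ones(len(points), dtype=bool)
    keep[1:] = np.any(np.diff(points, axis=0) != 0, axis=1)
    return points[keep]


def tangent_and_curvature(curve: SmoothCurve) -> tuple[np.ndarray, np.ndarray]:
    """Tangent angle psi (unwrapped, radians) and curvature kappa (1/px).

    Derivatives are central finite differences (one-sided at the
    ends); psi = atan2(y', x') unwrapped along arc length and
    kappa = |x'y'' - y'x''| / (x'^2 + y'^2)^(3/2).
    """
    pts = _dedup(curve.points)
    if len(pts) < 3:
        raise ValueError("need at least 3 distinct points")
    x, y = pts[:, 0], pts[:, 1]
    dx, dy = np.gradient(x), np.gradient(y)
    ddx, ddy = np.gradient(dx), np.gradient(dy)
    psi = np.unwrap(np.arctan2(dy, dx))
    denom = (dx ** 2 + dy ** 2) ** 1.5
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.abs(dx * ddy - dy * ddx) / denom
    kappa[~np.isfinite(kappa)] = 0.0
    return psi, kappa


def end_to_end_distance(curve: SmoothCurve | np.ndarray) -> float:
    """Euclidean distance between the first and last curve points."""
    pts = curve.points if isinstance(curve, SmoothCurve) else np.asarray(curve)
    if len(pts) < 2:
        raise ValueError("need at least 2 points")
    return float(np.linalg.norm(pts[-1] - pts[0]))


def arc_length(curve: SmoothCurve | np.ndarray) -> float:
    pts = curve.points if isinstance(curve, SmoothCurve) else np.asarray(curve)
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def power_spectrum(series: np.ndarray, dt_s: float,
                   times: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """One-sided FFT amplitude spectrum of a uniformly sampled series.

    The mean is subtracted before transforming; returns (frequency in
    Hz on the grid k / (N * dt), amplitude).
    """
    series = np.asarray(series, dtype=float)
    if len(series) < 4:
        raise ValueError("need at least 4 samples")
    if times is not None:
        steps = np.diff(np.asarray(times, dtype=float))
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise ValueError("non-uniform sampling")
    n = len(series)
    spec = np.fft.rfft(series - series.mean())
    freq = np.fft.rfftfreq(n, d=dt_s)
    amp = np.abs(spec) * 2.0 / n
    amp[0] = np.abs(spec[0]) / n
    if n % 2 == 0:
        amp[-1] = np.abs(spec[-1]) / n
    return freq, amp


# --------------------------------------------------------------------------
# track-level summaries
# --------------------------------------------------------------------------

def compute_frame_stats(contours, window: int = 11, polyorder: int = 3,
                        subtract_base_angle: bool = False) -> list[FrameStats]:
    """FrameStats for each resolved contour (None entries skipped).

    The tip angle is the tangent angle at the free end (last contour
    index), in absolute image-frame radians unless
    ``subtract_base_angle`` is set, in which case the angle at the
    clamped base is subtracted.
    """
    stats = []
    for k, contour in enumerate(contours):
        if contour is None:
            continue
        sc = smooth_contour(contour, window=window, polyorder=polyorder)
        psi, _ = tangent_and_curvature(sc)
        tip = psi[-1] - (psi[0] if subtract_base_angle else 0.0)
        stats.append(FrameStats(frame=k,
                                length_px=arc_length(sc),
                                tip_angle_rad=float(tip),
                                end_to_end_px=end_to_end_distance(sc)))
    return stats


def tip_angle_series(stats: list[FrameStats]) -> tuple[np.ndarray, np.ndarray]:
    """(frame indices, temporally unwrapped tip angles) from FrameStats."""
    frames = np.array([s.frame for s in stats])
    angles = np.unwrap(np.array([s.tip_angle_rad for s in stats]))
    return frames, angles


def tangent_kymograph(contours, n_bins: int = 50, window: int = 11,
                      polyorder: int = 3) -> np.ndarray:
    """Frames x arc-length-bins matrix of tangent angle (radians).

    Each resolved contour's psi is resampled onto ``n_bins`` uniform
    normalized arc-length positions; skipped frames are rows of NaN.
    """
    grid = np.linspace(0.0, 1.0, n_bins)
    out = np.full((len(contours), n_bins), np.nan)
    for k, contour in enumerate(contours):
        if contour is None:
            continue
        sc = smooth_contour(contour, window=window, polyorder=polyorder)
        pts = _dedup(sc.points)
        if len(pts) < 3:
            continue
        psi, _ = tangent_and_curvature(sc)
        s = np.concatenate([[0.0], np.cumsum(
            np.linalg.norm(np.diff(pts, axis=0), axis=1))])
        out[k] = np.interp(grid * s[-1], s, psi)
    return out
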