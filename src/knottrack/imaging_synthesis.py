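"""Synthetic ground truth and microscopy-like image formation.

Generates oscillating clamped-filament contours with a parametric
traveling-wave tangent-angle model, rasterizes them to one-pixel-wide
skeletons, and renders microscopy-like frames: dilation with a
diamond-shaped structuring element (radius 2), convolution with a 3x3
Gaussian point-spread function (sigma 2), and additive noise at a
requested signal-to-noise ratio.

The wave model stands in for motor-driven filament mechanics: the
tangent angle along arc length s at time t is

    psi(s, t) = base_angle + A(s) * sin(2*pi*(s/lambda - t/T))

with an amplitude ramp A(s) = amplitude * s / L, so the clamped base
stays fixed while the free end beats with the largest excursion, the
phenomenology of a plus-end-pinned microtubule driven by surface
motors. High amplitudes produce self-intersecting ("knotted") frames.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.morphology import diamond, thin

__all__ = [
    "WaveParams",
    "FilamentCurve",
    "SyntheticFrame",
    "generate_beating_filament",
    "generate_loop_closure",
    "auto_canvas",
    "rasterize_skeleton",
    "render_image",
    "snr_db_to_linear",
    "add_gaussian_noise",
    "add_salt_pepper_noise",
    "synthesize_series",
    "write_series",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class WaveParams:
    """Parameters of the traveling-wave filament generator.

    Attributes
    ----------
    length_um : float
        Filament contour length in micrometres (5-50 supported).
    pixel_size_um : float
        Micrometres per pixel.
    amplitude_rad : float
        Peak tangent-angle amplitude (radians) reached at the free end.
    wavelength_um : float
        Spatial wavelength of the traveling wave (micrometres).
    period_s : float
        Temporal oscillation period (seconds).
    n_frames : int
        Number of frames (default 120).
    dt_s : float
        Frame interval in seconds (default 10).
    base_xy : tuple
        Fixed clamp position in pixels, (x, y) = (column, row).
    base_angle_rad : float
        Clamp orientation (radians, image frame).
    curl_rad : float
        Static intrinsic curl: total tangent rotation from base to tip
        of the resting shape (radians).  A nonzero curl makes the rest
        shape an arc, as pinned filaments rarely relax to a straight
        line, and breaks the mirror symmetry of the beat.
    seed : int
        Seed for any downstream stochastic rendering.
    """

    length_um: float = 20.0
    pixel_size_um: float = 0.1
    amplitude_rad: float = 1.0
    wavelength_um: float = 15.0
    period_s: float = 200.0
    n_frames: int = 120
    dt_s: float = 10.0
    base_xy: tuple[float, float] = (30.0, 30.0)
    base_angle_rad: float = 0.0
    curl_rad: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        vals = (self.length_um, self.pixel_size_um, self.amplitude_rad,
                self.wavelength_um, self.period_s, self.dt_s,
                *self.base_xy, self.base_angle_rad)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("WaveParams fields must be finite")
        if self.length_um <= 0:
            raise ValueError("length_um must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.wavelength_um <= 0:
            raise ValueError("wavelength_um must be positive")
        if self.period_s <= 0:
            raise ValueError("period_s must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")

    @property
    def length_px(self) -> float:
        return self.length_um / self.pixel_size_um


@dataclass
class FilamentCurve:
    """Ordered sub-pixel 2-D point sequence along a filament.

    ``points`` is an (N, 2) float array of (x, y) pixel positions; the
    first point is the clamped base.  ``arc_step_px`` is the sampling
    interval along arc length.
    """

    points: np.ndarray
    arc_step_px: float = 0.5

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (N, 2) array")
        if len(self.points) < 2:
            raise ValueError("a curve needs at least 2 points")
        steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if steps.max() > 1.5 * self.arc_step_px:
            raise ValueError("consecutive point spacing exceeds 1.5 * arc_step_px")

    @property
    def arc_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    @property
    def end_to_end(self) -> float:
        return float(np.linalg.norm(self.points[-1] - self.points[0]))


@dataclass
class SyntheticFrame:
    """One rendered frame together with its ground truth."""

    truth_curve: FilamentCurve
    truth_skeleton: np.ndarray  # binary raster (row, col)
    image: np.ndarray           # grayscale raster in [0, 1]
    snr_db: float | None = None


# --------------------------------------------------------------------------
# ground-truth generation
# --------------------------------------------------------------------------

def generate_beating_filament(params: WaveParams) -> list[FilamentCurve]:
    """Generate one ground-truth contour per frame.

    The tangent angle follows a traveling wave with a linear amplitude
    ramp from the clamped base (zero excursion, fixed orientation) to
    the free end.  Positions come from cumulative integration of
    (cos psi, sin psi) at a fixed arc-length step, so the contour is
    inextensible by construction.
    """
    arc_step = 0.5  # px; fine enough for sub-pixel rasterization
    L = params.length_px
    n_pts = max(int(round(L / arc_step)) + 1, 2)
    s = np.linspace(0.0, L, n_pts)
    lam = params.wavelength_um / params.pixel_size_um
    base = np.asarray(params.base_xy, dtype=float)

    curves = []
    for k in range(params.n_frames):
        t = k * params.dt_s
        amp = params.amplitude_rad * s / L
        psi = params.base_angle_rad + params.curl_rad * s / L \
            + amp * np.sin(2.0 * np.pi * (s / lam - t / params.period_s))
        # midpoint rule keeps arc length exact per step
        psi_mid = 0.5 * (psi[:-1] + psi[1:])
        ds = np.diff(s)
        dx = np.cos(psi_mid) * ds
        dy = np.sin(psi_mid) * ds
        pts = np.empty((n_pts, 2))
        pts[0] = base
        pts[1:, 0] = base[0] + np.cumsum(dx)
        pts[1:, 1] = base[1] + np.cumsum(dy)
        curves.append(FilamentCurve(pts, arc_step_px=arc_step))
    return curves


def generate_loop_closure(closure_fracs: Sequence[float] = (0.72, 1.0),
                          tail_px: float = 60.0,
                          arc_px: float = 104.0,
                          exit_px: float = 45.0,
                          turn_rad: float = 1.5 * np.pi,
                          base_xy: tuple[float, float] = (40.0, 150.0),
                          base_angle_rad: float = 0.0) -> list[FilamentCurve]:
    """Generate a filament looping over itself: the knot-formation scenario.

    Each frame is a "hook": a straight tail, a circular arc of total
    turn ``turn_rad`` scaled by that frame's closure fraction, and a
    straight exit.  At closure 1 with the default 3*pi/2 turn the exit
    strand crosses the tail perpendicularly, producing a transversal
    self-intersection (a figure-of-eight-like knot); fractions below
    about 0.8 leave an open, unbranched hook.  The default two-frame
    sequence is the canonical template-then-knot test case.
    """
    step = 0.5
    total = tail_px + arc_px + exit_px
    n = int(total / step) + 1
    s = np.linspace(0.0, total, n)
    turn = float(turn_rad)
    psi_full = np.where(s < tail_px, 0.0,
                        np.where(s < tail_px + arc_px,
                                 turn * (s - tail_px) / arc_px, turn))
    base = np.asarray(base_xy, dtype=float)
    curves = []
    for frac in closure_fracs:
        psi = base_angle_rad + frac * psi_full
        psi_mid = 0.5 * (psi[:-1] + psi[1:])
        ds = np.diff(s)
        pts = np.empty((n, 2))
        pts[0] = base
        pts[1:, 0] = base[0] + np.cumsum(np.cos(psi_mid) * ds)
        pts[1:, 1] = base[1] + np.cumsum(np.sin(psi_mid) * ds)
        curves.append(FilamentCurve(pts, arc_step_px=step))
    return curves


def auto_canvas(curves: Sequence[FilamentCurve], margin: int = 10) -> tuple[int, int]:
    """Canvas (rows, cols) covering every curve with a margin."""
    allp = np.vstack([c.points for c in curves])
    max_x, max_y = allp.max(axis=0)
    min_x, min_y = allp.min(axis=0)
    if min_x - margin < 0 or min_y - margin < 0:
        # curves are generated in absolute pixel coordinates; the clamp
        # position must leave room for the full excursion
        raise ValueError(
            "curve exits the canvas on the low side; move base_xy inward")
    return int(np.ceil(max_y)) + margin + 1, int(np.ceil(max_x)) + margin + 1


def rasterize_skeleton(curve: FilamentCurve, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a curve to an 8-connected single-pixel-wide skeleton.

    Dense arc-length samples are rounded to the pixel grid and the
    result thinned to one-pixel width.  Every lit pixel lies within
    ~0.71 px (half a pixel diagonal) of the continuous curve.
    """
    pts = curve.points
    rows = np.rint(pts[:, 1]).astype(int)
    cols = np.rint(pts[:, 0]).astype(int)
    if (rows < 0).any() or (cols < 0).any() or \
            (rows >= shape[0]).any() or (cols >= shape[1]).any():
        raise ValueError("curve has points outside the raster shape")
    raster = np.zeros(shape, dtype=bool)
    raster[rows, cols] = True
    if raster.sum() > 1:
        raster = thin(raster)
    return raster


# --------------------------------------------------------------------------
# image formation
# --------------------------------------------------------------------------

def _gaussian_kernel(size: int = 3, sigma: float = 2.0) -> np.ndarray:
    """Normalized square Gaussian kernel."""
    half = (size - 1) / 2.0
    ax = np.arange(size) - half
    xx, yy = np.meshgrid(ax, ax)
    k = np.exp(-(xx ** 2 + yy ** 2) / (2.0 * sigma ** 2))
    return k / k.sum()


def render_image(skeleton: np.ndarray) -> np.ndarray:
    """Render a skeleton into a microscopy-like grayscale image.

    Dilation with a radius-2 diamond structuring element (13-pixel
    footprint, |di| + |dj| <= 2), then convolution with a normalized
    3x3 Gaussian point-spread function of sigma 2, rescaled to [0, 1].
    """
    skeleton = np.asarray(skeleton, dtype=bool)
    if not skeleton.any():
        return np.zeros(skeleton.shape, dtype=float)
    dilated = ndimage.binary_dilation(skeleton, structure=diamond(2))
    img = ndimage.convolve(dilated.astype(float), _gaussian_kernel(3, 2.0),
                           mode="constant")
    return img / img.max()


def snr_db_to_linear(snr_db: float) -> float:
    """Convert SNR in decibels to a linear power ratio: 10^(dB/10)."""
    if not np.isfinite(snr_db):
        raise ValueError("snr_db must be finite")
    return float(10.0 ** (snr_db / 10.0))


def add_gaussian_noise(image: np.ndarray, snr_db: float,
                       seed: int | np.random.Generator = 0) -> np.ndarray:
    """Add zero-mean Gaussian noise at a requested SNR (dB).

    The signal power is the variance of the input intensities; the
    noise power is P_signal / SNR_linear and the noise is drawn as
    sigma_noise * N(0, 1) with sigma_noise = sqrt(P_noise).
    """
    image = np.asarray(image, dtype=float)
    if not np.isfinite(image).all():
        raise ValueError("image must be finite")
    p_signal = float(image.var())
    if p_signal == 0.0 or image.min() == image.max():
        return image.copy()
    p_noise = p_signal / snr_db_to_linear(snr_db)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return image + np.sqrt(p_noise) * rng.standard_normal(image.shape)


def add_salt_pepper_noise(image: np.ndarray, density: float,
                          seed: int | np.random.Generator = 0) -> np.ndarray:
    """Set a ``density`` fraction of pixels to 0 or 1 with equal odds."""
    if not 0.0 <= density <= 1.0:
        raise ValueError("density must be in [0, 1]")
    image = np.asarray(image, dtype=float)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    corrupt = rng.random(image.shape) < density
    salt = rng.random(image.shape) < 0.5
    out = image.copy()
    out[corrupt & salt] = 1.0
    out[corrupt & ~salt] = 0.0
    return out


# --------------------------------------------------------------------------
# frame synthesis pipeline
# --------------------------------------------------------------------------

def synthesize_series(params: WaveParams,
                      snr_db: float | None = None,
                      noise: str = "gaussian",
                      sp_density: float = 0.05,
                      shape: tuple[int, int] | None = None) -> list[SyntheticFrame]:
    """Full frame synthesis: curves -> skeletons -> rendered noisy images.

    ``noise`` is ``"gaussian"`` (default; ``snr_db`` sets the level) or
    ``"saltpepper"`` (``sp_density`` sets the corrupted fraction).
    Bit-reproducible for a fixed ``params.seed``.  Gaussian noise is
    left unclipped so the realized noise power matches the requested
    SNR exactly; noisy frames may therefore slightly exceed [0, 1]
    (segmentation re-normalizes intensities anyway).
    """
    curves = generate_beating_filament(params)
    if shape is None:
        shape = auto_canvas(curves)
    rng = np.random.default_rng(params.seed)
    frames = []
    for curve in curves:
        skel = rasterize_skeleton(curve, shape)
        img = render_image(skel)
        if snr_db is not None:
            if noise == "gaussian":
                img = add_gaussian_noise(img, snr_db, seed=rng)
            elif noise == "saltpepper":
                img = add_salt_pepper_noise(img, sp_density, seed=rng)
            else:
                raise ValueError(f"unknown noise model: {noise!r}")
        frames.append(SyntheticFrame(curve, skel, img, snr_db=snr_db))
    return frames


def write_series(frames: Sequence[SyntheticFrame], stack_path: str | Path,
                 truth_csv_path: str | Path | None = None) -> None:
    """Write frames as a multi-page grayscale TIFF plus a truth CSV.

    The CSV has columns frame, point_index, x, y with 0-based pixel
    coordinates (x = column, y = row).
    """
    import tifffile

    stack = np.stack([f.image for f in frames]).astype(np.float32)
    tifffile.imwrite(str(stack_path), stack, photometric="minisblack")
    if truth_csv_path is not None:
        with open(truth_csv_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["frame", "point_index", "x", "y"])
            for i, f in enumerate(frames):
                for j, (x, y) in enumerate(f.truth_curve.points):
                    w.writerow([i, j, f"{x:.4f}", f"{y:.4f}"])
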