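"""Shared fixtures: synthetic rasters, curves, and rendered sequences."""

from __future__ import annotations

import numpy as np
import pytest

from knottrack import WaveParams, generate_loop_closure, auto_canvas
from knottrack.segmentation import Skeleton


def skeleton_from_pixels(pixels, shape=None) -> Skeleton:
    """Build a Skeleton raster from (row, col) tuples."""
    pixels = [tuple(p) for p in pixels]
    if shape is None:
        rmax = max(p[0] for p in pixels)
        cmax = max(p[1] for p in pixels)
        shape = (rmax + 2, cmax + 2)
    mask = np.zeros(shape, dtype=bool)
    for r, c in pixels:
        mask[r, c] = True
    return Skeleton(mask)


def figure_eight_pixels():
    """Hand-built figure-of-eight raster: two tails joined by a loop.

    Start tail enters from the left, the contour loops around a
    diamond of pixels and leaves through the right tail; the single
    crossing pixel (10, 10) has four non-tail neighbors, so it is the
    only Moore-criterion branch pixel.
    """
    tail_in = [(10, c) for c in range(2, 10)]       # left tail
    tail_out = [(10, c) for c in range(11, 19)]     # right tail
    cross = [(10, 10)]
    # loop above the crossing: up-right, across, down-left
    loop = [(9, 11), (8, 12), (7, 12), (6, 11), (5, 10), (6, 9), (7, 8),
            (8, 8), (9, 9)]
    return tail_in, cross, loop, tail_out


@pytest.fixture
def figure_eight():
    tail_in, cross, loop, tail_out = figure_eight_pixels()
    return skeleton_from_pixels(tail_in + cross + loop + tail_out)


@pytest.fixture
def straight_line_skeleton():
    return skeleton_from_pixels([(5, c) for c in range(3, 13)])


@pytest.fixture(scope="session")
def wave_params():
    """Small oscillating filament, low amplitude (never self-intersects)."""
    return WaveParams(length_um=10.0, pixel_size_um=0.1, amplitude_rad=1.0,
                      wavelength_um=15.0, period_s=200.0, n_frames=6,
                      dt_s=10.0, base_xy=(110.0, 110.0), seed=0)


@pytest.fixture(scope="session")
def hook_curves():
    """Canonical knot-formation pair: open hook then crossed loop."""
    return generate_loop_closure()


@pytest.fixture(scope="session")
def hook_shape(hook_curves):
    return auto_canvas(hook_curves)
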