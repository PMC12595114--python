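"""Slice-wise preprocessing that turns raw channels into binary masks.

The acquisition produces stacks whose z step is ~2.4× the xy pixel size, and
the denoising/background parameters (median radius 2 px, rolling-ball radius
750 px) are 2D pixel radii, so both filters operate per z-plane with a flat
disk footprint.

Background subtraction is implemented as greyscale opening with a flat disk:
``output = max(input − opening(input), 0)``. When the disk covers the whole
slice from any centre (radius ≥ slice diagonal — true for the default 750 px
radius on desk-scale slices) the opening degenerates to the per-slice global
minimum, which we compute directly; the result is identical to the direct
opening but O(N).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import VoxelGrid
from .io import read_volume

__all__ = [
    "PreprocessParams",
    "disk_footprint",
    "median_filter",
    "rolling_ball_subtract",
    "threshold_mask",
    "import_probability_map",
    "preprocess_channel",
]


@dataclass
class PreprocessParams:
    """Per-channel preprocessing parameters.

    ``median_radius_px`` and ``rolling_ball_radius_px`` are 2D pixel radii
    applied slice-wise; ``threshold`` is the manual intensity cutoff
    (inclusive, applied after filtering); ``prob_cutoff`` binarises imported
    pixel-classifier probability maps.
    """

    median_radius_px: int = 2
    rolling_ball_radius_px: int = 750
    threshold: float = 0.5
    prob_cutoff: float = 0.5
    subtract_background: bool = True

    def __post_init__(self) -> None:
        if self.median_radius_px < 0:
            raise ValueError("median radius must be non-negative")
        if self.rolling_ball_radius_px < 1:
            raise ValueError("rolling-ball radius must be >= 1")
        if not 0.0 < self.prob_cutoff < 1.0:
            raise ValueError("prob_cutoff must lie strictly inside (0, 1)")


def disk_footprint(radius_px: int) -> np.ndarray:
    """Flat 2D disk: pixels whose centre is within ``radius_px`` of the origin."""
    if radius_px < 0:
        raise ValueError("radius must be non-negative")
    r = int(radius_px)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy * yy + xx * xx) <= r * r


def median_filter(grid: VoxelGrid, radius_px: int) -> VoxelGrid:
    """Slice-wise 2D median filter with a disk footprint of the given radius.

    Border pixels use reflected padding (nearest-equivalent behaviour of the
    underlying rank filter).
    """
    if radius_px < 0:
        raise ValueError("median radius must be non-negative")
    if radius_px == 0:
        return grid.with_data(grid.data.copy())
    fp = disk_footprint(radius_px)[np.newaxis, :, :]  # 2D disk, no z extent
    out = ndimage.median_filter(grid.data, footprint=fp, mode="reflect")
    return grid.with_data(out)


def _slice_opening(plane: np.ndarray, radius_px: int) -> np.ndarray:
    h, w = plane.shape
    # Disk of radius r covers the whole slice from any centre iff r >= diagonal.
    if radius_px >= math.hypot(h - 1, w - 1):
        return np.full_like(plane, plane.min())
    fp = disk_footprint(radius_px)
    return ndimage.grey_opening(plane, footprint=fp, mode="reflect")


def rolling_ball_subtract(grid: VoxelGrid, radius_px: int) -> VoxelGrid:
    """Per-slice background subtraction via greyscale opening with a flat disk.

    Returns ``max(input − background, 0)`` where the background of each
    z-plane is its opening with a disk of ``radius_px``. The output is
    everywhere ≤ input and ≥ 0, and a constant slice maps to zero.
    """
    if radius_px < 1:
        raise ValueError("rolling-ball radius must be >= 1")
    data = grid.data
    out = np.empty_like(data)
    for z in range(data.shape[0]):
        background = _slice_opening(data[z], radius_px)
        out[z] = data[z] - background
    np.maximum(out, 0, out=out)
    return grid.with_data(out)


def threshold_mask(grid: VoxelGrid, t: float) -> VoxelGrid:
    """Binary mask: 1 where value ≥ ``t`` (inclusive), else 0."""
    mask = (grid.data >= t).astype(np.uint8)
    return VoxelGrid(mask, grid.spacing, "binary")


def import_probability_map(path, prob_cutoff: float = 0.5, spacing=None) -> VoxelGrid:
    """Load a pixel-classifier probability map and binarise it at ``prob_cutoff``.

    The map must hold values in [0, 1]; anything outside is rejected rather
    than clipped, since it indicates a mis-exported classifier output.
    """
    if not 0.0 < prob_cutoff < 1.0:
        raise ValueError("prob_cutoff must lie strictly inside (0, 1)")
    grid = read_volume(path, spacing=spacing, dtype_role="intensity")
    lo, hi = float(grid.data.min()), float(grid.data.max())
    if lo < 0.0 or hi > 1.0:
        raise ValueError(f"probability map values outside [0, 1]: range [{lo}, {hi}]")
    return threshold_mask(grid, prob_cutoff)


def preprocess_channel(grid: VoxelGrid, params: PreprocessParams) -> VoxelGrid:
    """Median filter → background subtraction → threshold, as one step."""
    g = median_filter(grid, params.median_radius_px)
    if params.subtract_background:
        g = rolling_ball_subtract(g, params.rolling_ball_radius_px)
    return threshold_mask(g, params.threshold)
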