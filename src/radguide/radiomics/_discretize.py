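"""Gray-level discretization of ROI intensities.

Two schemes are supported:

* fixed bin count ``Ng``: uniform bins over [min, max]; the maximum maps to
  level ``Ng`` (a constant ROI collapses to a single level), and
* fixed bin width ``w``: level = floor((x - min) / w) + 1.

Texture matrices operate on the discretized level grid; first-order entropy
and uniformity use the discretized histogram as well.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class DiscretizationScheme:
    mode: str = "fixed_count"  # or "fixed_width"
    n_bins: int = 32
    bin_width: float | None = None

    def __post_init__(self):
        if self.mode not in ("fixed_count", "fixed_width"):
            raise ValueError(f"unknown discretization mode {self.mode!r}")
        if self.mode == "fixed_count" and self.n_bins < 1:
            raise ValueError("bin count must be >= 1")
        if self.mode == "fixed_width" and (self.bin_width is None or self.bin_width <= 0):
            raise ValueError("bin width must be positive")


@dataclass
class DiscretizedROI:
    """An ROI cropped to its padded bounding box with integer gray levels.

    ``grid`` holds levels 1..Ng inside the ROI and 0 outside; ``values`` are
    the original intensities of the ROI voxels (grid order, C-contiguous);
    ``mask`` is the in-box ROI mask.
    """

    grid: np.ndarray          # int levels, 0 = outside ROI
    values: np.ndarray        # original intensities, one per ROI voxel
    ng: int
    scheme: DiscretizationScheme
    spacing: tuple[float, float, float]

    def __post_init__(self):
        if self.values.size < 1:
            raise ValueError("empty ROI")
        levels = self.grid[self.grid > 0]
        if levels.size and (levels.min() < 1 or levels.max() > self.ng):
            raise ValueError("levels outside 1..Ng")

    @property
    def mask(self) -> np.ndarray:
        return self.grid > 0

    @property
    def n_voxels(self) -> int:
        return int((self.grid > 0).sum())

    @property
    def levels(self) -> np.ndarray:
        """Levels of the ROI voxels in grid (C) order."""
        return self.grid[self.grid > 0]

    def histogram(self) -> np.ndarray:
        """Normalized level histogram p_1..p_Ng."""
        counts = np.bincount(self.levels, minlength=self.ng + 1)[1:]
        return counts / counts.sum()


def discretize_values(values: np.ndarray, scheme: DiscretizationScheme) -> tuple[np.ndarray, int]:
    """Map intensities to integer levels 1..Ng; returns (levels, Ng)."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("empty ROI")
    vmin, vmax = float(values.min()), float(values.max())
    if scheme.mode == "fixed_width":
        w = float(scheme.bin_width)
        # small epsilon keeps values sitting exactly on a bin edge (up to
        # float rounding) in the upper bin, e.g. (1.2 - 1.0) / 0.2 -> 1.0
        ratio = (values - vmin) / w
        levels = np.floor(ratio + 1e-9 * np.maximum(1.0, np.abs(ratio))).astype(np.int64) + 1
        return levels, int(levels.max())
    # fixed bin count
    if vmax == vmin:
        return np.ones(values.shape, dtype=np.int64), 1
    ng = int(scheme.n_bins)
    w = (vmax - vmin) / ng
    levels = np.floor((values - vmin) / w).astype(np.int64) + 1
    levels = np.minimum(levels, ng)  # vmax maps to Ng
    return levels, ng


def discretize_roi(volume_data: np.ndarray, mask: np.ndarray,
                   scheme: DiscretizationScheme,
                   spacing: tuple[float, float, float]) -> DiscretizedROI:
    """Crop the ROI to a 1-voxel padded bounding box and discretize it."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty ROI")
    idx = np.nonzero(mask)
    lo = [max(int(i.min()) - 1, 0) for i in idx]
    hi = [min(int(i.max()) + 2, s) for i, s in zip(idx, mask.shape)]
    box = tuple(slice(l, h) for l, h in zip(lo, hi))
    sub_mask = mask[box]
    sub_vals = np.asarray(volume_data, dtype=np.float64)[box]
    values = sub_vals[sub_mask]
    if np.isnan(values).any():
        raise ValueError("ROI contains NaN intensities")
    levels, ng = discretize_values(values, scheme)
    grid = np.zeros(sub_mask.shape, dtype=np.int64)
    grid[sub_mask] = levels
    return DiscretizedROI(grid=grid, values=values, ng=ng, scheme=scheme,
                          spacing=tuple(float(s) for s in spacing))
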