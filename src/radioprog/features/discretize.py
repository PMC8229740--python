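"""Fixed-bin-width gray-level discretization of ROI intensities.

Level of a voxel with intensity I is ``1 + floor((I - min_ROI) / bin_width)``,
anchored at the ROI minimum. The default width is 0.5 HU.
"""

from dataclasses import dataclass

import numpy as np

DEFAULT_BIN_WIDTH = 0.5


@dataclass
class DiscretizedRoi:
    """Integer gray levels over an ROI.

    Attributes
    ----------
    level_grid : ndarray of int
        Same shape as the image; levels 1..n_levels inside the ROI, 0 outside.
    levels : ndarray of int
        Flat 1-D levels of the ROI voxels (mask order).
    n_levels : int
        Highest occupied level N_g.
    bin_width : float
        Bin width in intensity units (HU).
    bin_anchor : float
        ROI minimum intensity, the left edge of bin 1.
    degenerate : bool
        True when the ROI collapses to a single level (texture degenerates).
    """

    level_grid: np.ndarray
    levels: np.ndarray
    n_levels: int
    bin_width: float
    bin_anchor: float
    degenerate: bool


def discretize(image, mask, bin_width=DEFAULT_BIN_WIDTH):
    """Discretize ``image`` intensities inside ``mask`` with a fixed bin width.

    Parameters
    ----------
    image : ndarray
        3D (or any-D) intensity array.
    mask : ndarray of bool
        Same-shape binary ROI mask; must be non-empty.
    bin_width : float
        Intensity width of one gray level.

    Returns
    -------
    DiscretizedRoi
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot discretize an empty ROI")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    vals = np.asarray(image, dtype=np.float64)[mask]
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite intensities inside the ROI")
    anchor = float(vals.min())
    levels = 1 + np.floor((vals - anchor) / bin_width).astype(np.int64)
    n_levels = int(levels.max())
    grid = np.zeros(mask.shape, dtype=np.int64)
    grid[mask] = levels
    return DiscretizedRoi(
        level_grid=grid,
        levels=levels,
        n_levels=n_levels,
        bin_width=float(bin_width),
        bin_anchor=anchor,
        degenerate=n_levels == 1,
    )
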