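"""Feature stability under ROI perturbation: translations + ICC screening.

Features are recomputed with the ROI shifted by 10% of its bounding-box
extent along each axis (the 6 axis-aligned translations plus the original
ROI, 7 measurements per patient) and screened with a one-way random-effects
single-measurement intraclass correlation coefficient, ICC(1,1):

    ICC = (MS_between - MS_within) / (MS_between + (k - 1) MS_within)

Perturbed segmentations are exchangeable repetitions, not fixed raters,
which is what the one-way model assumes. Features with ICC >= 0.75 are kept.
ICC is location/scale-free, so screening raw (pre-normalization) features is
equivalent to screening Z-scored ones.
"""

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_TRANSLATION_FRACTION = 0.10
DEFAULT_ICC_THRESHOLD = 0.75


def translate_mask(mask, axis, sign, fraction=DEFAULT_TRANSLATION_FRACTION,
                   min_shift=None):
    """Shift a binary mask by round(fraction x bounding-box extent) voxels.

    Parameters
    ----------
    mask : 3D bool array
    axis : int, 0..2
    sign : +1 or -1
    fraction : float
        Fraction of the mask bounding-box extent along ``axis``.
    min_shift : int, optional
        Floor for the rounded shift. By default a shift rounding below one
        voxel is an error; the perturbation set floors it at one voxel so
        small ROIs on coarse grids still get a genuine perturbation.

    Raises
    ------
    ValueError if the rounded shift is below one voxel (and no floor is
    given) or the shifted mask would leave the image bounds.
    """
    mask = np.asarray(mask, dtype=bool)
    idx = np.flatnonzero(mask.any(axis=tuple(a for a in range(3) if a != axis)))
    extent = idx[-1] - idx[0] + 1
    shift = int(np.floor(fraction * extent + 0.5))
    if min_shift is not None:
        shift = max(shift, int(min_shift))
    if shift < 1:
        raise ValueError(
            f"translation of {fraction:.2f} x bbox extent {extent} rounds below 1 voxel"
        )
    shift *= int(sign)
    lo, hi = idx[0] + shift, idx[-1] + shift
    if lo < 0 or hi >= mask.shape[axis]:
        raise ValueError(
            f"translating axis {axis} by {shift} voxels exits the image bounds"
        )
    out = np.zeros_like(mask)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    if shift > 0:
        src[axis] = slice(0, mask.shape[axis] - shift)
        dst[axis] = slice(shift, None)
    else:
        src[axis] = slice(-shift, None)
        dst[axis] = slice(0, mask.shape[axis] + shift)
    out[tuple(dst)] = mask[tuple(src)]
    return out


def perturbation_set(mask, fraction=DEFAULT_TRANSLATION_FRACTION):
    """The unperturbed mask plus its 6 axis-aligned translations.

    Shifts are floored at one voxel so a coarse-grid ROI is still genuinely
    perturbed rather than rejected.
    """
    masks = [mask]
    for axis in range(3):
        for sign in (+1, -1):
            masks.append(translate_mask(mask, axis, sign, fraction, min_shift=1))
    return masks


def icc(values):
    """One-way random-effects single-measurement ICC(1,1).

    Parameters
    ----------
    values : (n_subjects, k_measurements) array, n >= 2, k >= 2.

    Returns
    -------
    float; may be negative. A zero-total-variance matrix returns 1.0
    (degenerate: perfectly reproducible and featureless).
    """
    x = np.asarray(values, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("ICC needs at least 2 subjects x 2 measurements")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    ss_between = k * ((row_means - grand) ** 2).sum()
    ss_within = ((x - row_means[:, None]) ** 2).sum()
    if ss_between + ss_within <= 0:
        return 1.0
    ms_between = ss_between / (n - 1)
    ms_within = ss_within / (n * (k - 1))
    return float((ms_between - ms_within) / (ms_between + (k - 1) * ms_within))


def icc_table(feature_tables):
    """Vectorized ICC(1,1) per feature across perturbation measurements.

    Parameters
    ----------
    feature_tables : list of DataFrame
        One table per perturbation, identically indexed (patients) with
        identical feature columns.

    Returns
    -------
    Series feature -> ICC.
    """
    first = feature_tables[0]
    for t in feature_tables[1:]:
        if list(t.columns) != list(first.columns) or not t.index.equals(first.index):
            raise ValueError("perturbation tables must share index and columns")
    x = np.stack([t.to_numpy(dtype=np.float64) for t in feature_tables], axis=2)
    n, n_feat, k = x.shape
    grand = x.mean(axis=(0, 2))
    row_means = x.mean(axis=2)
    ss_between = k * ((row_means - grand) ** 2).sum(axis=0)
    ss_within = ((x - row_means[:, :, None]) ** 2).sum(axis=(0, 2))
    ms_between = ss_between / (n - 1)
    ms_within = ss_within / (n * (k - 1))
    denom = ms_between + (k - 1) * ms_within
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = (ms_between - ms_within) / denom
    vals = np.where(ss_between + ss_within <= 0, 1.0, vals)
    return pd.Series(vals, index=first.columns, name="icc")


@dataclass
class StabilityReport:
    """Per-feature ICC values and pass flags at a given threshold."""

    icc: pd.Series
    threshold: float = DEFAULT_ICC_THRESHOLD

    @property
    def passed(self):
        return self.icc[self.icc >= self.threshold].index.tolist()

    def to_frame(self):
        return pd.DataFrame(
            {"icc": self.icc, "pass": self.icc >= self.threshold}
        ).rename_axis("feature")

    def to_csv(self, path):
        self.to_frame().to_csv(path)


def select_stable(feature_tables, threshold=DEFAULT_ICC_THRESHOLD):
    """Keep features whose ICC across perturbations meets the threshold.

    ``feature_tables`` must come from training patients only.
    """
    report = StabilityReport(icc_table(feature_tables), threshold)
    kept = report.passed
    if not kept:
        raise ValueError(
            "no feature reached ICC >= %.2f; inspect the stability threshold"
            % threshold
        )
    logger.info("stability: kept %d / %d features", len(kept), report.icc.size)
    return kept, report
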