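"""Full radiomic feature extraction: 536 named features per (image, mask).

Roster: 14 shape + 18 first-order + 24 GLCM + 16 GLRLM on the original
image, plus the 58 intensity/texture features on each of the 8 undecimated
wavelet sub-bands (464). Names follow the ``<image>_<family>_<feature>``
schema with image in {original, wavelet-LLL .. wavelet-HHH}.

Shape features depend on the mask only and are computed once, on the
original-resolution mask. Intensities are rediscretized per wavelet band
(each band has its own dynamic range) with the same fixed bin width.
"""

import logging

import numpy as np

from ._kernels import texture_features
from .discretize import DEFAULT_BIN_WIDTH, discretize
from .firstorder import FIRSTORDER_FEATURE_NAMES, first_order_features
from .glcm import GLCM_FEATURE_NAMES
from .glrlm import GLRLM_FEATURE_NAMES
from .shape import SHAPE_FEATURE_NAMES, shape_features
from .wavelet import DEFAULT_WAVELET, WAVELET_BAND_NAMES, wavelet_bands

logger = logging.getLogger(__name__)

IMAGE_TYPES = ["original"] + [f"wavelet-{b}" for b in WAVELET_BAND_NAMES]


def feature_names():
    """The canonical ordered list of all 536 feature names."""
    names = [f"original_shape_{f}" for f in SHAPE_FEATURE_NAMES]
    for img in IMAGE_TYPES:
        names += [f"{img}_firstorder_{f}" for f in FIRSTORDER_FEATURE_NAMES]
        names += [f"{img}_glcm_{f}" for f in GLCM_FEATURE_NAMES]
        names += [f"{img}_glrlm_{f}" for f in GLRLM_FEATURE_NAMES]
    return names

FEATURE_NAMES = feature_names()
N_FEATURES = len(FEATURE_NAMES)          # 536
N_WAVELET_FEATURES = 8 * (len(FIRSTORDER_FEATURE_NAMES)
                          + len(GLCM_FEATURE_NAMES)
                          + len(GLRLM_FEATURE_NAMES))  # 464


def _bbox_slices(mask):
    idx = np.argwhere(mask)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


def _band_stats(band, mask, voxel_volume, bin_width, prefix, bb=None):
    """First-order + GLCM + GLRLM features of one filtered image under one mask."""
    if bb is None:
        bb = _bbox_slices(mask)
    sub_img = band[bb]
    sub_mask = mask[bb]
    droi = discretize(sub_img, sub_mask, bin_width=bin_width)
    if droi.degenerate:
        logger.info("%s: single-level ROI, texture features degenerate", prefix)
    out = {}
    fo = first_order_features(sub_img[sub_mask], droi.levels, voxel_volume)
    for k, v in fo.items():
        out[f"{prefix}_firstorder_{k}"] = v
    glcm_vals, glrlm_vals = texture_features(
        np.ascontiguousarray(droi.level_grid), droi.n_levels
    )
    for k, v in zip(GLCM_FEATURE_NAMES, glcm_vals):
        out[f"{prefix}_glcm_{k}"] = float(v)
    for k, v in zip(GLRLM_FEATURE_NAMES, glrlm_vals):
        out[f"{prefix}_glrlm_{k}"] = float(v)
    return out


class FeatureExtractor:
    """Radiomic feature extractor with configurable discretization and wavelet.

    Parameters
    ----------
    bin_width : float
        Fixed bin width (HU) for gray-level discretization, default 0.5.
    wavelet : str
        PyWavelets family name for the sub-band decomposition.
    """

    def __init__(self, bin_width=DEFAULT_BIN_WIDTH, wavelet=DEFAULT_WAVELET):
        self.bin_width = float(bin_width)
        self.wavelet = wavelet

    def extract(self, image, mask, spacing):
        """Extract all 536 features for one image/mask pair."""
        return self.extract_set(image, [mask], spacing)[0]

    def extract_set(self, image, masks, spacing, masks_are_translates=False):
        """Extract features for several masks over one image.

        The wavelet transform is shared across masks. With
        ``masks_are_translates=True`` the (translation-invariant) shape
        features are computed once on the first mask and copied.
        """
        image = np.asarray(image, dtype=np.float64)
        spacing = np.asarray(spacing, dtype=np.float64)
        voxel_volume = float(np.prod(spacing))
        bands = wavelet_bands(image, self.wavelet)
        results = []
        shared_shape = None
        for m_idx, mask in enumerate(masks):
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != image.shape:
                raise ValueError("mask and image shapes differ")
            if not mask.any():
                raise ValueError("empty mask")
            feats = {}
            if masks_are_translates and shared_shape is not None:
                shp = shared_shape
            else:
                shp = shape_features(mask, spacing)
                shared_shape = shp
            for k, v in shp.items():
                feats[f"original_shape_{k}"] = v
            bb = _bbox_slices(mask)
            feats.update(
                _band_stats(image, mask, voxel_volume, self.bin_width, "original", bb)
            )
            for bname in WAVELET_BAND_NAMES:
                feats.update(
                    _band_stats(
                        bands[bname], mask, voxel_volume, self.bin_width,
                        f"wavelet-{bname}", bb,
                    )
                )
            ordered = {name: feats[name] for name in FEATURE_NAMES}
            values = np.fromiter(ordered.values(), dtype=np.float64, count=len(ordered))
            if not np.isfinite(values).all():
                bad = [k for k, v in zip(ordered, values) if not np.isfinite(v)]
                logger.warning(
                    "mask %d: %d non-finite features (e.g. %s); patient should be flagged",
                    m_idx, len(bad), bad[0],
                )
            results.append(ordered)
        return results


def extract_all(image, mask, spacing, bin_width=DEFAULT_BIN_WIDTH,
                wavelet=DEFAULT_WAVELET):
    """One-shot extraction of the full 536-feature vector."""
    return FeatureExtractor(bin_width=bin_width, wavelet=wavelet).extract(
        image, mask, spacing
    )
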