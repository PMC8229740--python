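"""In-memory containers for image volumes and ROI masks, plus NIfTI I/O.

Arrays are indexed (x, y, z) with a matching mm spacing triple; NIfTI files
round-trip voxel arrays and spacing exactly (spacing is stored in the affine
diagonal).
"""

from dataclasses import dataclass

import nibabel as nib
import numpy as np


@dataclass
class ImageVolume:
    """3D scalar image in HU-like intensities with anisotropic spacing."""

    voxels: np.ndarray
    spacing: tuple
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("ImageVolume must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def voxel_volume(self):
        return float(np.prod(self.spacing))


@dataclass
class RoiMask:
    """Binary 3D mask aligned with an ImageVolume."""

    voxels: np.ndarray
    spacing: tuple
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValueError("RoiMask must be 3D")
        if not self.voxels.any():
            raise ValueError("RoiMask must contain at least one foreground voxel")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def n_voxels(self):
        return int(self.voxels.sum())

    @property
    def physical_volume(self):
        return self.n_voxels * float(np.prod(self.spacing))


def _affine(spacing, origin):
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def save_nifti(path, voxels, spacing, origin=(0.0, 0.0, 0.0)):
    img = nib.Nifti1Image(np.asarray(voxels), _affine(spacing, origin))
    nib.save(img, str(path))


def load_image(path):
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(o) for o in img.affine[:3, 3])
    return ImageVolume(np.asarray(img.dataobj), spacing, origin)


def load_mask(path):
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(o) for o in img.affine[:3, 3])
    data = np.asarray(img.dataobj)
    vals = np.unique(data)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"mask file {path} has values outside {{0,1}}")
    return RoiMask(data > 0, spacing, origin)
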