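"""Gaussian denoising and isotropic resampling contracts."""

import numpy as np
import pytest

from radioprog.preprocess import (
    crop_to_mask,
    gaussian_denoise,
    gaussian_kernel_3d,
    resample_isotropic,
)
from radioprog.volume import ImageVolume, RoiMask


def ball_mask(n, r, spacing=(1.0, 1.0, 1.0)):
    x, y, z = np.mgrid[:n, :n, :n]
    c = (n - 1) / 2
    return ((x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2) <= r * r


def test_kernel_matches_closed_form_weights():
    sigma = 0.5
    w = gaussian_kernel_3d(sigma, (3, 3, 3))
    offs = np.arange(-1, 2)
    gx, gy, gz = np.meshgrid(offs, offs, offs, indexing="ij")
    expected = np.exp(-(gx**2 + gy**2 + gz**2) / (2 * sigma**2))
    expected /= expected.sum()
    assert np.allclose(w, expected, atol=1e-15)
    assert w.sum() == pytest.approx(1.0, abs=1e-12)


def test_unit_impulse_response_is_normalized_kernel():
    vox = np.zeros((9, 9, 9))
    vox[4, 4, 4] = 1.0
    out = gaussian_denoise(ImageVolume(vox, (1, 1, 1)))
    w = gaussian_kernel_3d()
    assert out.voxels[4, 4, 4] == pytest.approx(w[1, 1, 1])
    assert out.voxels.sum() == pytest.approx(1.0, abs=1e-12)
    assert np.allclose(out.voxels[3:6, 3:6, 3:6], w)


def test_constant_image_unchanged():
    vox = np.full((8, 8, 8), 37.5)
    out = gaussian_denoise(ImageVolume(vox, (1, 1, 3)))
    assert np.allclose(out.voxels, 37.5)
    assert out.spacing == (1.0, 1.0, 3.0)


def test_denoise_never_widens_intensity_range():
    rng = np.random.default_rng(0)
    vox = rng.normal(0, 20, (16, 16, 16))
    out = gaussian_denoise(ImageVolume(vox, (1, 1, 1)))
    assert out.voxels.min() >= vox.min() - 1e-9
    assert out.voxels.max() <= vox.max() + 1e-9


def test_denoise_rejects_non_finite():
    vox = np.zeros((5, 5, 5))
    vox[0, 0, 0] = np.nan
    with pytest.raises(ValueError, match="non-finite"):
        gaussian_denoise(ImageVolume(vox, (1, 1, 1)))


def test_kernel_requires_odd_size():
    with pytest.raises(ValueError, match="odd"):
        gaussian_kernel_3d(0.5, (2, 3, 3))


def test_resample_shape_arithmetic_1mm_40_to_20():
    mask = ball_mask(40, 10)
    img = ImageVolume(np.random.default_rng(1).normal(size=(40, 40, 40)), (1, 1, 1))
    roi = RoiMask(mask, (1, 1, 1))
    out_img, out_mask = resample_isotropic(img, roi, target=2.0)
    assert all(19 <= s <= 21 for s in out_img.voxels.shape)
    assert out_img.spacing == (2.0, 2.0, 2.0)
    assert out_mask.voxels.shape == out_img.voxels.shape


def test_resample_preserves_mask_physical_volume():
    mask = ball_mask(48, 12)
    img = ImageVolume(np.zeros((48, 48, 48)), (1, 1, 1))
    roi = RoiMask(mask, (1, 1, 1))
    _, out_mask = resample_isotropic(img, roi, target=2.0)
    assert out_mask.physical_volume == pytest.approx(roi.physical_volume, rel=0.10)


def test_resample_anisotropic_extent_preserved():
    vox = np.zeros((32, 32, 16))
    mask = np.zeros_like(vox, dtype=bool)
    mask[10:22, 10:22, 4:12] = True
    img = ImageVolume(vox, (1, 1, 3))
    out_img, _ = resample_isotropic(img, RoiMask(mask, (1, 1, 3)), 2.0)
    in_extent = np.array(vox.shape) * (1, 1, 3)
    out_extent = np.array(out_img.voxels.shape) * 2.0
    assert np.all(np.abs(in_extent - out_extent) <= 2.0 + 1e-9)


def test_already_isotropic_identity_on_grid():
    rng = np.random.default_rng(2)
    vox = rng.normal(size=(12, 12, 12))
    mask = ball_mask(12, 4)
    img = ImageVolume(vox, (2, 2, 2))
    out_img, out_mask = resample_isotropic(img, RoiMask(mask, (2, 2, 2)), 2.0)
    assert out_img.voxels.shape == vox.shape
    assert np.allclose(out_img.voxels, vox, atol=1e-9)
    assert np.array_equal(out_mask.voxels, mask)


def test_mask_emptied_by_resampling_is_an_error():
    vox = np.zeros((40, 40, 40))
    mask = np.zeros_like(vox, dtype=bool)
    mask[5, 5, 5] = True  # single voxel vanishes at 4x coarser grid
    with pytest.raises(ValueError, match="emptied"):
        resample_isotropic(
            ImageVolume(vox, (0.5, 0.5, 0.5)), RoiMask(mask, (0.5, 0.5, 0.5)), 4.0
        )


def test_crop_to_mask_preserves_roi_content():
    rng = np.random.default_rng(3)
    vox = rng.normal(size=(40, 40, 40))
    mask = np.zeros((40, 40, 40), dtype=bool)
    mask[18:25, 17:24, 19:23] = True
    img, roi = crop_to_mask(ImageVolume(vox, (1, 1, 1)), RoiMask(mask, (1, 1, 1)), 5.0)
    assert roi.n_voxels == mask.sum()
    assert np.allclose(np.sort(img.voxels[roi.voxels]), np.sort(vox[mask]))
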