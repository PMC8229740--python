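"""Synthetic CT cohort generator with a planted survival signal.

Each patient carries one segmented lesion: an ellipsoid-plus-lobulation mask
whose interior is a base HU level plus a spatially correlated Gaussian random
field (smoothed white noise), embedded in a noisy background. Two knobs plant
a class signal for short survivors (label 1, overall survival <= 10 months):

* ``volume_effect`` — ratio of mean lesion diameter between classes;
* ``heterogeneity_effect`` — ratio of intra-lesional texture contrast.

With both knobs at 1 the class-conditional image distributions are identical
in law, which calibrates the downstream pipeline's null behavior. Clinical
covariates (lesion count, affected organs, performance status, metastatic
status) are sampled from categorical marginals typical of a recurrent/
metastatic head-and-neck immunotherapy cohort and are independent of the
label — the planted signal is imaging-only.

Cohorts are split chronologically: the first ``train_fraction`` of patients
form the training set. The full cohort is a pure function of the config.
"""

import csv
import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import ImageVolume, RoiMask, load_image, load_mask, save_nifti

logger = logging.getLogger(__name__)

CLINICAL_COLUMNS = [
    "patient_id",
    "split",
    "label",
    "n_lesions",
    "n_organs",
    "performance_status",
    "non_metastatic",
    "total_volume_mm3",
]


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the reference cohort: 85 patients, 80/20 chronological
    split, ~30% short survivors, 64^3 anisotropic volumes.
    """

    n_patients: int = 85
    train_fraction: float = 0.8
    event_rate: float = 0.3
    volume_effect: float = 1.2
    heterogeneity_effect: float = 1.5
    voxel_spacing: tuple = (1.0, 1.0, 3.0)
    noise_sd: float = 8.0
    seed: int = 0
    image_shape: tuple = (64, 64, 64)
    base_diameter_mm: float = 15.0
    diameter_sigma: float = 0.12
    background_hu: float = 35.0
    tumor_hu: float = 55.0
    texture_sd: float = 6.0
    texture_smoothing_mm: float = 2.5

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if not 0 < self.event_rate < 1:
            raise ValueError("event_rate must be in (0, 1)")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacings must be positive")
        if self.n_patients < 10:
            raise ValueError("cohorts need at least 10 patients")


@dataclass
class SyntheticPatient:
    patient_id: str
    image: ImageVolume
    mask: RoiMask
    label: int
    n_lesions: int
    n_organs: int
    performance_status: int
    non_metastatic: int
    total_volume: float
    split: str = "train"

    def __post_init__(self):
        if self.n_organs > self.n_lesions:
            raise ValueError("n_organs cannot exceed n_lesions")


def _correlated_field(shape, spacing, smoothing_mm, rng):
    """Unit-variance Gaussian random field via Gaussian-smoothed white noise."""
    sigma_vox = np.asarray(smoothing_mm) / np.asarray(spacing)
    field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_vox)
    sd = field.std()
    return field / sd if sd > 0 else field


def generate_tumor(patient_class, config, rng):
    """One lesion: ellipsoid-plus-lobulation mask and its CT-like image.

    Interior = tumor HU level + correlated texture whose sd scales with
    ``heterogeneity_effect`` for class 1; exterior = background + white
    noise. Lesions too large for the volume are shrunk (and logged).
    """
    shape = tuple(config.image_shape)
    spacing = np.asarray(config.voxel_spacing, dtype=np.float64)
    extent = np.asarray(shape) * spacing

    diameter = config.base_diameter_mm * float(
        np.exp(rng.normal(0.0, config.diameter_sigma))
    )
    if patient_class == 1:
        diameter *= config.volume_effect
    # per-axis semi-axes with mild anisotropy jitter; floor keeps the lesion
    # large enough for 10%-of-bounding-box translations after 2 mm resampling
    semi = diameter / 2.0 * np.exp(rng.normal(0.0, 0.08, size=3))
    semi = np.maximum(semi, 6.0)
    # leave room for boundary margins and stability translations
    max_semi = extent / 2.0 - 2.0 * spacing - 0.15 * extent
    if np.any(semi > max_semi):
        scale = float(np.min(max_semi / semi))
        logger.info("lesion of %.1f mm shrunk by %.2f to fit the volume", diameter, scale)
        semi = semi * scale

    center = extent / 2.0 + rng.normal(0.0, 1.0, size=3)
    # open (broadcast) coordinate grids keep the geometry cheap
    gx = (np.arange(shape[0]) * spacing[0])[:, None, None]
    gy = (np.arange(shape[1]) * spacing[1])[None, :, None]
    gz = (np.arange(shape[2]) * spacing[2])[None, None, :]
    # draw lobulation parameters once so regrow attempts stay deterministic
    bumps = []
    for _ in range(int(rng.integers(2, 5))):
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        bumps.append((direction, float(rng.uniform(0.6, 1.0))))

    def rasterize(semi_axes):
        m = (
            ((gx - center[0]) / semi_axes[0]) ** 2
            + ((gy - center[1]) / semi_axes[1]) ** 2
            + ((gz - center[2]) / semi_axes[2]) ** 2
        ) <= 1.0
        for direction, r_frac in bumps:
            bc = center + direction * semi_axes * 0.9
            br = 0.35 * semi_axes.min() * r_frac
            lo = np.maximum(np.floor((bc - br) / spacing).astype(int), 0)
            hi = np.minimum(np.ceil((bc + br) / spacing).astype(int) + 1, shape)
            if np.any(lo >= hi):
                continue
            sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
            bump = (
                (gx[sl[0], :, :] - bc[0]) ** 2
                + (gy[:, sl[1], :] - bc[1]) ** 2
                + (gz[:, :, sl[2]] - bc[2]) ** 2
            ) <= br * br
            m[sl] |= bump
        return m

    mask = rasterize(semi)
    # a too-thin lesion (rasterized extent under ~12 mm on some axis) cannot
    # survive resampling + bounding-box translations; regrow and log, the
    # mirror image of the oversize shrink above
    for _ in range(6):
        idx = np.argwhere(mask)
        phys_extent = (idx.max(axis=0) - idx.min(axis=0) + 1) * spacing
        if phys_extent.min() >= 12.0 or np.all(semi >= max_semi):
            break
        semi = np.minimum(semi * 1.15, max_semi)
        logger.info("lesion regrown to keep a workable bounding box")
        mask = rasterize(semi)

    image = config.background_hu + config.noise_sd * rng.standard_normal(shape)
    tex_sd = config.texture_sd * (
        config.heterogeneity_effect if patient_class == 1 else 1.0
    )
    # the correlated field is only sampled inside the lesion, so generate it
    # on the bounding box plus the smoothing support (identical in law)
    idx = np.argwhere(mask)
    pad = np.ceil(4.0 * config.texture_smoothing_mm / spacing).astype(int)
    lo = np.maximum(idx.min(axis=0) - pad, 0)
    hi = np.minimum(idx.max(axis=0) + 1 + pad, shape)
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    texture = _correlated_field(
        tuple(int(b - a) for a, b in zip(lo, hi)),
        spacing,
        config.texture_smoothing_mm,
        rng,
    )
    sub_mask = mask[sl]
    image[sl][sub_mask] = config.tumor_hu + tex_sd * texture[sub_mask]

    vol = ImageVolume(image, tuple(spacing))
    roi = RoiMask(mask, tuple(spacing))
    return vol, roi


def _clinical_covariates(rng):
    """Covariates with marginals typical of the emulated cohort; independent
    of the survival label by construction."""
    n_lesions = 1 + int(rng.poisson(2.0))
    n_organs = 1 + int(rng.binomial(n_lesions - 1, 0.45)) if n_lesions > 1 else 1
    performance_status = int(rng.choice([0, 1, 2], p=[0.32, 0.65, 0.03]))
    non_metastatic = int(rng.random() < 0.44)
    return n_lesions, n_organs, performance_status, non_metastatic


def iter_cohort(config):
    """Yield the cohort patient by patient (enrollment order).

    Streaming keeps only one full-resolution volume in memory at a time,
    which matters for large simulated cohorts; ``generate_cohort`` is the
    list-returning wrapper. Both are pure functions of the config.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n = config.n_patients
    n_train = int(np.floor(config.train_fraction * n))
    labels = (rng.random(n) < config.event_rate).astype(int)
    if len(set(labels[:n_train])) < 2:
        raise ValueError(
            "training split contains a single survival class; "
            "use another seed or adjust event_rate"
        )
    for idx in range(n):
        label = int(labels[idx])
        image, mask = generate_tumor(label, config, rng)
        n_lesions, n_organs, ps, non_met = _clinical_covariates(rng)
        largest = mask.physical_volume
        # additional (unsegmented) lesions contribute to total burden
        extra = largest * 0.35 * rng.random(max(n_lesions - 1, 0)).sum()
        yield SyntheticPatient(
            patient_id=f"P{idx + 1:03d}",
            image=image,
            mask=mask,
            label=label,
            n_lesions=n_lesions,
            n_organs=n_organs,
            performance_status=ps,
            non_metastatic=non_met,
            total_volume=largest + extra,
            split="train" if idx < n_train else "test",
        )


def generate_cohort(config):
    """Generate the full cohort with its chronological train/test split.

    Returns
    -------
    list of SyntheticPatient, ordered by enrollment; the first
    ``floor(train_fraction * n)`` carry ``split == 'train'``.
    """
    return list(iter_cohort(config))


def write_cohort(patients, directory):
    """Write NIfTI volumes/masks and the clinical CSV for a cohort."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in patients:
        save_nifti(
            directory / f"{p.patient_id}_img.nii.gz",
            np.asarray(p.image.voxels, dtype=np.float32),
            p.image.spacing,
            p.image.origin,
        )
        save_nifti(
            directory / f"{p.patient_id}_mask.nii.gz",
            p.mask.voxels.astype(np.uint8),
            p.mask.spacing,
            p.mask.origin,
        )
        rows.append(
            [
                p.patient_id,
                p.split,
                p.label,
                p.n_lesions,
                p.n_organs,
                p.performance_status,
                p.non_metastatic,
                f"{p.total_volume:.6f}",
            ]
        )
    with open(directory / "clinical.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CLINICAL_COLUMNS)
        writer.writerows(rows)
    return directory


def read_cohort(directory):
    """Round-trip: rebuild SyntheticPatient objects from a written cohort."""
    from pathlib import Path

    directory = Path(directory)
    patients = []
    with open(directory / "clinical.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            pid = row["patient_id"]
            image = load_image(directory / f"{pid}_img.nii.gz")
            mask = load_mask(directory / f"{pid}_mask.nii.gz")
            patients.append(
                SyntheticPatient(
                    patient_id=pid,
                    image=image,
                    mask=mask,
                    label=int(row["label"]),
                    n_lesions=int(row["n_lesions"]),
                    n_organs=int(row["n_organs"]),
                    performance_status=int(row["performance_status"]),
                    non_metastatic=int(row["non_metastatic"]),
                    total_volume=float(row["total_volume_mm3"]),
                    split=row["split"],
                )
            )
    return patients
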