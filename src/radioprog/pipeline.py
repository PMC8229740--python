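"""End-to-end orchestration: simulate -> preprocess -> extract -> select ->
fit -> evaluate, as one configurable, deterministic study.

``run_study`` works fully in memory and returns a ``StudyResult``;
``run_pipeline`` is the file-producing variant used by the command line. The
whole study is a pure function of its ``RunConfig``.
"""

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluate import (
    clinical_baselines,
    evaluate_calls,
    reports_to_frame,
    save_reports,
    spearman_test,
)
from .features import FeatureExtractor
from .preprocess import (
    DEFAULT_KERNEL,
    DEFAULT_SIGMA,
    DEFAULT_TARGET_SPACING,
    crop_to_mask,
    gaussian_denoise,
    resample_isotropic,
)
from .signature import SignatureConfig, SignatureModel
from .stability import (
    DEFAULT_ICC_THRESHOLD,
    DEFAULT_TRANSLATION_FRACTION,
    perturbation_set,
    select_stable,
)
from .synth import CLINICAL_COLUMNS, CohortConfig, generate_cohort, iter_cohort, write_cohort

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Full configuration of one study run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    # preprocessing
    denoise_sigma: float = DEFAULT_SIGMA
    denoise_kernel: tuple = DEFAULT_KERNEL
    target_spacing: float = DEFAULT_TARGET_SPACING
    crop_margin_mm: float = 20.0
    # extraction
    bin_width: float = 0.5
    wavelet: str = "coif1"
    # stability
    icc_threshold: float = DEFAULT_ICC_THRESHOLD
    translation_fraction: float = DEFAULT_TRANSLATION_FRACTION
    # signature
    signature: SignatureConfig = field(default_factory=SignatureConfig)
    seed: int = 0

    def to_dict(self):
        d = dataclasses.asdict(self)
        d["signature"]["lambda_grid"] = list(d["signature"]["lambda_grid"])
        return d


@dataclass
class StudyResult:
    config: RunConfig
    train_features: pd.DataFrame
    test_features: pd.DataFrame
    clinical: pd.DataFrame
    stability_report: object
    signature: object  # SignatureResults
    predictions: pd.DataFrame  # test scores + calls
    radiomics_report: object
    clinical_reports: list
    spearman_rho: float
    spearman_p: float
    runtime_s: float = 0.0

    @property
    def test_auc(self):
        return self.radiomics_report.auc


def preprocess_patient(patient, config):
    """Crop to the lesion neighborhood, denoise, resample isotropically."""
    image, mask = crop_to_mask(patient.image, patient.mask, config.crop_margin_mm)
    image = gaussian_denoise(image, config.denoise_sigma, config.denoise_kernel)
    try:
        return resample_isotropic(image, mask, config.target_spacing)
    except ValueError as err:
        raise ValueError(f"{patient.patient_id}: {err}") from err


def extract_cohort(patients, config):
    """Extract features for a cohort; training patients get the perturbation
    set (wavelet transform shared across the 7 masks).

    Returns
    -------
    features : DataFrame (all patients x 536)
    perturbed : list of 7 DataFrames (training patients only)
    clinical : DataFrame of survival label, split and clinical covariates
    """
    extractor = FeatureExtractor(bin_width=config.bin_width, wavelet=config.wavelet)
    rows, perturbed_rows, clin_rows = {}, [], {}
    n_perturb = 7
    for patient in patients:
        image, mask = preprocess_patient(patient, config)
        if patient.split == "train":
            masks = perturbation_set(mask.voxels, config.translation_fraction)
            feats = extractor.extract_set(
                image.voxels, masks, image.spacing, masks_are_translates=True
            )
            rows[patient.patient_id] = feats[0]
            perturbed_rows.append((patient.patient_id, feats))
        else:
            rows[patient.patient_id] = extractor.extract(
                image.voxels, mask.voxels, image.spacing
            )
        clin_rows[patient.patient_id] = {
            "split": patient.split,
            "label": patient.label,
            "largest_volume": patient.mask.physical_volume,
            "total_volume": patient.total_volume,
            "n_lesions": patient.n_lesions,
            "n_organs": patient.n_organs,
            "performance_status": patient.performance_status,
            "non_metastatic": patient.non_metastatic,
        }
    features = pd.DataFrame.from_dict(rows, orient="index")
    features.index.name = "patient_id"
    clinical = pd.DataFrame.from_dict(clin_rows, orient="index")
    clinical.index.name = "patient_id"

    train_ids = [pid for pid, _ in perturbed_rows]
    perturbed = [
        pd.DataFrame.from_dict(
            {pid: feats[k] for pid, feats in perturbed_rows}, orient="index"
        ).loc[train_ids]
        for k in range(n_perturb)
    ]

    bad = features.index[~np.isfinite(features.to_numpy()).all(axis=1)]
    if len(bad):
        logger.warning("dropping %d patients with non-finite features: %s",
                       len(bad), list(bad))
        features = features.drop(index=bad)
        clinical = clinical.drop(index=bad)
        perturbed = [t.drop(index=[b for b in bad if b in t.index]) for t in perturbed]
    return features, perturbed, clinical


def run_study(config=RunConfig(), patients=None):
    """Run the full study in memory and evaluate on the held-out test set."""
    t0 = time.time()
    if patients is None:
        patients = iter_cohort(config.cohort)
    features, perturbed, clinical = extract_cohort(patients, config)

    is_train = clinical["split"] == "train"
    train_x = features[is_train]
    test_x = features[~is_train]
    train_y = clinical.loc[is_train, "label"]
    test_y = clinical.loc[~is_train, "label"]

    stable, stab_report = select_stable(perturbed, config.icc_threshold)
    model = SignatureModel(train_x[stable], train_y, config.signature)
    results = model.fit(seed=config.seed)

    predictions = results.predict(test_x)
    radiomics_report = evaluate_calls(
        "radiomics",
        predictions["call"].to_numpy(),
        test_y.to_numpy(),
        scores=predictions["score"].to_numpy(),
        seed=config.seed,
        threshold=results.threshold,
    )
    clin_cols = ["largest_volume", "total_volume", "n_lesions", "n_organs",
                 "performance_status", "non_metastatic"]
    clinical_reports = clinical_baselines(
        clinical.loc[~is_train, clin_cols], test_y.to_numpy(), seed=config.seed
    )
    try:
        rho, p = spearman_test(
            clinical.loc[~is_train, "largest_volume"].to_numpy(),
            predictions["score"].to_numpy(),
        )
    except ValueError as err:
        logger.warning("signature-volume correlation unavailable: %s", err)
        rho, p = float("nan"), float("nan")
    return StudyResult(
        config=config,
        train_features=train_x,
        test_features=test_x,
        clinical=clinical,
        stability_report=stab_report,
        signature=results,
        predictions=predictions,
        radiomics_report=radiomics_report,
        clinical_reports=clinical_reports,
        spearman_rho=rho,
        spearman_p=p,
        runtime_s=time.time() - t0,
    )


def run_pipeline(config, out_dir, write_images=True):
    """File-producing end-to-end run; returns the StudyResult.

    Writes: cohort NIfTI files + clinical.csv (optional), features.csv,
    stability_report.csv, signature_model.json, signature_scores.csv,
    report.json / report.csv, run_config.json and run.log entries.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("radioprog")
    root.addHandler(handler)
    try:
        patients = generate_cohort(config.cohort)
        if write_images:
            write_cohort(patients, out / "cohort")
        result = run_study(config, patients=patients)
        result.train_features.assign(split="train").pipe(
            lambda df: pd.concat([df, result.test_features.assign(split="test")])
        ).to_csv(out / "features.csv")
        result.stability_report.to_csv(out / "stability_report.csv")
        result.signature.save(out / "signature_model.json")
        all_pred = pd.concat(
            [result.signature.predict(result.train_features),
             result.predictions]
        )
        all_pred.rename_axis("patient_id").to_csv(out / "signature_scores.csv")
        save_reports(
            [result.radiomics_report] + result.clinical_reports,
            json_path=out / "report.json",
            csv_path=out / "report.csv",
        )
        extra = {
            "spearman_rho_signature_vs_volume": result.spearman_rho,
            "spearman_p": result.spearman_p,
            "runtime_s": result.runtime_s,
        }
        with open(out / "summary.json", "w") as fh:
            json.dump(extra, fh, indent=1)
        with open(out / "run_config.json", "w") as fh:
            json.dump(config.to_dict(), fh, indent=1)
        return result
    finally:
        root.removeHandler(handler)
        handler.close()
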