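"""Shared fixtures.

The Monte-Carlo study fixtures are session-scoped and lazily computed so the
expensive cohort simulations run once and are shared by the tests that
assert different properties of the same study conditions.
"""

import logging
import warnings

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from radioprog import CohortConfig, RunConfig, run_study

logging.getLogger("radioprog").setLevel(logging.ERROR)
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def texture_fixture():
    """A small textured lesion image + spherical mask (deterministic)."""
    rng = np.random.default_rng(42)
    n = 20
    img = rng.normal(40, 8, (n, n, n))
    x, y, z = np.mgrid[:n, :n, :n]
    mask = ((x - 10) ** 2 + (y - 10) ** 2 + (z - 10) ** 2) <= 4.2**2
    tex = gaussian_filter(rng.normal(size=(n, n, n)), 1.2)
    img[mask] = 55 + 8 * tex[mask] / tex.std()
    return img, mask


def _study_auc(n_patients, heterogeneity, volume, seed):
    cfg = RunConfig(
        cohort=CohortConfig(
            n_patients=n_patients,
            heterogeneity_effect=heterogeneity,
            volume_effect=volume,
            seed=seed,
        ),
        seed=seed,
    )
    try:
        return run_study(cfg).test_auc
    except ValueError:
        # degenerate draw (e.g. single-class split); skip this seed
        return float("nan")


@pytest.fixture(scope="session")
def planted_recovery_aucs():
    """Test AUCs over 20 seeds with a strong planted texture signal
    (heterogeneity 2.5, 200 training / 50 test patients)."""
    return np.array([_study_auc(250, 2.5, 1.2, seed) for seed in range(20)])


@pytest.fixture(scope="session")
def null_aucs():
    """Test AUCs over 20 seeds with no planted signal at the same size."""
    return np.array([_study_auc(250, 1.0, 1.0, 100 + seed) for seed in range(20)])


@pytest.fixture(scope="session")
def heterogeneity_sweep_aucs():
    """Mean test AUC per heterogeneity level {1.0, 1.5, 2.5} at fixed n=55
    (44 train / 11 test), volume effect 1, 20 seeds per level."""
    out = {}
    for het in (1.0, 1.5, 2.5):
        vals = np.array([_study_auc(55, het, 1.0, 200 + seed) for seed in range(20)])
        out[het] = vals
    return out
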