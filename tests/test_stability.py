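"""ROI translation perturbations and ICC-based stability screening."""

import numpy as np
import pandas as pd
import pytest

from radioprog.stability import (
    StabilityReport,
    icc,
    icc_table,
    perturbation_set,
    select_stable,
    translate_mask,
)

from _oracles import icc_oracle


def box_mask(shape=(40, 40, 40), lo=(10, 12, 14), size=(20, 10, 8)):
    m = np.zeros(shape, dtype=bool)
    m[lo[0]:lo[0] + size[0], lo[1]:lo[1] + size[1], lo[2]:lo[2] + size[2]] = True
    return m


def test_translation_shift_arithmetic():
    # bounding box of 20 voxels along x, fraction 0.10 -> 2-voxel shift
    mask = box_mask()
    shifted = translate_mask(mask, axis=0, sign=+1, fraction=0.10)
    assert shifted.sum() == mask.sum()
    assert np.array_equal(shifted, np.roll(mask, 2, axis=0))


def test_translation_round_trip_is_identity():
    mask = box_mask()
    back = translate_mask(translate_mask(mask, 0, +1), 0, -1)
    assert np.array_equal(back, mask)


def test_sub_voxel_shift_rejected():
    mask = box_mask(size=(4, 10, 10))
    with pytest.raises(ValueError, match="below 1 voxel"):
        translate_mask(mask, axis=0, sign=+1, fraction=0.10)


def test_shift_out_of_bounds_rejected():
    mask = box_mask(lo=(0, 10, 10), size=(20, 10, 10))
    with pytest.raises(ValueError, match="bounds"):
        translate_mask(mask, axis=0, sign=-1, fraction=0.10)


def test_perturbation_set_floors_shift_at_one_voxel():
    mask = box_mask(size=(4, 10, 10))  # 10% of 4 rounds to zero
    masks = perturbation_set(mask)
    assert len(masks) == 7
    assert not np.array_equal(masks[1], mask)  # genuinely shifted


def test_perturbation_set_is_seven_equal_count_masks():
    masks = perturbation_set(box_mask())
    assert len(masks) == 7
    counts = {m.sum() for m in masks}
    assert counts == {masks[0].sum()}


def test_icc_known_value_matches_anova_oracle():
    x = [[1, 1.1], [2, 2.1], [3, 2.9]]
    assert icc(x) == pytest.approx(icc_oracle(x), abs=1e-12)
    assert icc(x) == pytest.approx(0.9944802207911683, abs=1e-12)


def test_icc_matches_pingouin_icc1():
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(4)
    x = rng.normal(size=(12, 5)) + 3 * rng.normal(size=(12, 1))
    df = pd.DataFrame({
        "subject": np.repeat(np.arange(12), 5),
        "rater": np.tile(np.arange(5), 12),
        "score": x.ravel(),
    })
    ref = pingouin.intraclass_corr(df, "subject", "rater", "score")
    ref_icc1 = float(ref.set_index("Type").loc["ICC(1,1)", "ICC"])
    assert icc(x) == pytest.approx(ref_icc1, abs=1e-9)


def test_icc_one_when_measurements_identical():
    x = np.tile(np.array([[1.0], [5.0], [9.0]]), (1, 4))
    assert icc(x) == pytest.approx(1.0)


def test_icc_degenerate_zero_variance_returns_one():
    assert icc(np.full((4, 3), 2.5)) == 1.0


def test_icc_noise_only_centered_near_zero():
    # identical subjects, pure measurement noise: ICC concentrates at <= 0
    vals = []
    for seed in range(100):
        x = np.random.default_rng(seed).normal(size=(10, 4))
        vals.append(icc(x))
    assert np.median(vals) <= 0.1


def test_icc_table_matches_scalar_icc():
    rng = np.random.default_rng(0)
    base = rng.normal(size=(15, 3))
    tables = [
        pd.DataFrame(base + 0.05 * rng.normal(size=base.shape),
                     columns=["a", "b", "c"])
        for _ in range(5)
    ]
    series = icc_table(tables)
    for col_idx, name in enumerate(["a", "b", "c"]):
        x = np.stack([t.to_numpy()[:, col_idx] for t in tables], axis=1)
        assert series[name] == pytest.approx(icc(x), abs=1e-12)


def test_select_stable_keeps_reproducible_and_drops_noise():
    rng = np.random.default_rng(1)
    n = 50
    subject_signal = rng.normal(size=n)
    tables = []
    for _ in range(7):
        tables.append(pd.DataFrame({
            "stable": subject_signal,                      # identical each time
            "noisy": rng.normal(size=n),                   # fresh noise
            "mixed": subject_signal + 0.1 * rng.normal(size=n),
        }))
    kept, report = select_stable(tables, threshold=0.75)
    assert "stable" in kept
    assert "mixed" in kept
    assert "noisy" not in kept
    assert report.icc["stable"] == pytest.approx(1.0)


def test_selection_invariant_to_feature_rescaling():
    rng = np.random.default_rng(2)
    base = rng.normal(size=(30, 2))
    tables = [pd.DataFrame(base + 0.2 * rng.normal(size=base.shape),
                           columns=["u", "v"]) for _ in range(4)]
    icc_plain = icc_table(tables)
    scaled = [t * 10.0 for t in tables]
    icc_scaled = icc_table(scaled)
    assert np.allclose(icc_plain.to_numpy(), icc_scaled.to_numpy(), atol=1e-12)


def test_no_stable_feature_is_an_error():
    rng = np.random.default_rng(3)
    tables = [pd.DataFrame({"x": rng.normal(size=20)}) for _ in range(4)]
    with pytest.raises(ValueError, match="ICC"):
        select_stable(tables, threshold=0.99)


def test_report_round_trip(tmp_path):
    report = StabilityReport(pd.Series({"f1": 0.9, "f2": 0.1}), 0.75)
    report.to_csv(tmp_path / "stab.csv")
    back = pd.read_csv(tmp_path / "stab.csv", index_col=0)
    assert back.loc["f1", "pass"]
    assert not back.loc["f2", "pass"]
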