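"""Confusion metrics, Wilson intervals, ROC/AUC and the Spearman test."""

import itertools

import numpy as np
import pytest
from scipy.stats import rankdata
from sklearn.metrics import roc_auc_score

from radioprog.evaluate import (
    clinical_baselines,
    confusion_metrics,
    evaluate_calls,
    roc_auc,
    spearman_pvalue,
    spearman_test,
    wilson_interval,
)

from _oracles import auc_pair_oracle, wilson_oracle


def test_confusion_metrics_seventeen_patient_example():
    labels = np.r_[np.ones(5, int), np.zeros(12, int)]
    calls = np.r_[np.ones(3, int), np.zeros(2, int), np.zeros(11, int), np.ones(1, int)]
    c = confusion_metrics(calls, labels)
    assert (c.tp, c.fn, c.tn, c.fp) == (3, 2, 11, 1)
    assert c.accuracy == pytest.approx(14 / 17)
    assert c.sensitivity == pytest.approx(0.60)
    assert c.specificity == pytest.approx(11 / 12)


def test_confusion_all_correct_and_all_negative():
    y = np.array([1, 0, 1, 0])
    assert confusion_metrics(y, y).accuracy == 1.0
    c = confusion_metrics(np.zeros(4, int), y)
    assert c.sensitivity == 0.0
    assert c.specificity == 1.0


def test_confusion_accepts_hr_lr_strings():
    import pandas as pd

    calls = pd.Series(["HR", "LR", "HR"]).to_numpy()
    c = confusion_metrics(calls, np.array([1, 0, 0]))
    assert (c.tp, c.fn, c.tn, c.fp) == (1, 0, 1, 1)


@pytest.mark.parametrize(
    "successes,n,expected",
    [
        (14, 17, (0.59, 0.94)),
        (3, 5, (0.23, 0.88)),
        (11, 12, (0.65, 0.99)),
        (10, 17, (0.36, 0.78)),
        (12, 17, (0.47, 0.87)),
        (7, 17, (0.22, 0.64)),
    ],
)
def test_wilson_reproduces_published_interval_table(successes, n, expected):
    lo, hi = wilson_interval(successes, n)
    assert (round(lo, 2), round(hi, 2)) == expected


def test_wilson_matches_closed_form_oracle():
    for s, n in [(0, 10), (5, 10), (10, 10), (14, 17), (1, 50)]:
        lo, hi = wilson_interval(s, n)
        olo, ohi = wilson_oracle(s, n)
        assert lo == pytest.approx(olo, abs=1e-9)
        assert hi == pytest.approx(ohi, abs=1e-9)


def test_wilson_upper_is_one_at_full_success():
    _, hi = wilson_interval(12, 12)
    assert hi == pytest.approx(1.0, abs=1e-12)


def test_wilson_invalid_inputs():
    with pytest.raises(ValueError):
        wilson_interval(1, 0)
    with pytest.raises(ValueError):
        wilson_interval(5, 4)


def test_auc_perfectly_ordered_scores():
    auc, (fpr, tpr) = roc_auc([1, 2, 3, 4], [0, 0, 1, 1])
    assert auc == 1.0
    assert fpr[0] == 0.0 and tpr[-1] == 1.0


def test_auc_null_distribution_centered_at_half():
    rng = np.random.default_rng(0)
    scores = rng.normal(size=1000)
    labels = rng.random(1000) < 0.4
    auc, _ = roc_auc(scores, labels.astype(int))
    assert auc == pytest.approx(0.5, abs=0.05)


def test_trapezoidal_auc_equals_pair_counting_with_ties():
    rng = np.random.default_rng(1)
    scores = np.round(rng.normal(size=30), 1)  # induce ties
    labels = (rng.random(30) < 0.5).astype(int)
    auc, _ = roc_auc(scores, labels)
    assert auc == pytest.approx(auc_pair_oracle(scores, labels), abs=1e-12)
    assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


def test_auc_antisymmetry_under_score_negation():
    rng = np.random.default_rng(2)
    scores = rng.normal(size=40)
    labels = (rng.random(40) < 0.5).astype(int)
    a1, _ = roc_auc(scores, labels)
    a2, _ = roc_auc(-scores, labels)
    assert a1 + a2 == pytest.approx(1.0, abs=1e-12)


def test_report_self_consistency_and_interval_coverage():
    labels = np.r_[np.ones(5, int), np.zeros(12, int)]
    calls = np.r_[np.ones(3, int), np.zeros(2, int), np.zeros(11, int), np.ones(1, int)]
    scores = np.linspace(0, 1, 17)[::-1]
    report = evaluate_calls("radiomics", calls, labels, scores=scores, seed=0)
    assert report.check_consistency()
    d = report.to_dict()
    assert d["tp"] + d["fn"] + d["tn"] + d["fp"] == 17


def test_clinical_baseline_identity_variable_perfect():
    import pandas as pd

    labels = np.array([0, 1, 0, 1, 0, 1, 0, 0])
    clin = pd.DataFrame({"ident": labels.astype(float)})
    (report,) = clinical_baselines(clin, labels)
    assert report.accuracy.value == 1.0
    assert not report.inverted


def test_clinical_baseline_inversion_rule():
    import pandas as pd

    labels = np.array([0, 1, 0, 1, 0, 1, 0, 0])
    clin = pd.DataFrame({"anti": -labels.astype(float)})
    (report,) = clinical_baselines(clin, labels)
    assert report.inverted
    assert report.accuracy.value == 1.0
    assert report.auc >= 0.5  # reported after orientation


def test_six_baseline_variables_give_six_rows():
    import pandas as pd

    rng = np.random.default_rng(3)
    labels = (rng.random(30) < 0.4).astype(int)
    clin = pd.DataFrame({
        "largest_volume": rng.lognormal(8, 1, 30),
        "total_volume": rng.lognormal(8.5, 1, 30),
        "n_lesions": rng.integers(1, 6, 30),
        "n_organs": rng.integers(1, 4, 30),
        "performance_status": rng.integers(0, 3, 30),
        "non_metastatic": rng.integers(0, 2, 30),
    })
    reports = clinical_baselines(clin, labels)
    assert len(reports) == 6


def test_spearman_monotone_relation_is_one():
    x = np.array([1.0, 2, 5, 9, 11])
    rho, p = spearman_test(x, np.exp(x))
    assert rho == pytest.approx(1.0)


def test_spearman_published_worked_example():
    # rho = -0.36 at n = 17 gives a two-sided p of about 0.15
    p = spearman_pvalue(-0.36, 17)
    assert 0.15 <= p <= 0.16
    assert p == pytest.approx(0.15, abs=0.01)


def test_spearman_matches_exhaustive_permutation_on_n8():
    rng = np.random.default_rng(4)
    x = rng.normal(size=8)
    y = 0.8 * x + rng.normal(size=8)
    rho, p = spearman_test(x, y)
    rx = rankdata(x)
    count = 0
    total = 0
    for perm in itertools.permutations(rankdata(y)):
        r = np.corrcoef(rx, perm)[0, 1]
        total += 1
        if abs(r) >= abs(rho) - 1e-12:
            count += 1
    assert p == pytest.approx(count / total, abs=0.02)


def test_spearman_rejects_degenerate_input():
    with pytest.raises(ValueError):
        spearman_test([1.0, 1, 1, 1, 1], [1.0, 2, 3, 4, 5])
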