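"""Signature pipeline stages and the Model/Results surface."""

import numpy as np
import pandas as pd
import pytest

from radioprog.signature import (
    SignatureConfig,
    SignatureModel,
    SignatureResults,
    auc_filter,
    choose_threshold,
    feature_auc,
    lasso_select,
    prune_redundant,
    prune_redundant_from_corr,
    smote,
    train_svm,
    zscore_apply,
    zscore_fit_apply,
)


def make_features(n=80, p=12, signal=2.0, seed=0):
    """Gaussian features with one informative column ('f0')."""
    rng = np.random.default_rng(seed)
    y = (rng.random(n) < 0.35).astype(int)
    x = rng.normal(size=(n, p))
    x[:, 0] += signal * y
    cols = [f"f{t}" for t in range(p)]
    return pd.DataFrame(x, columns=cols, index=[f"P{t:03d}" for t in range(n)]), y


# ---------------------------------------------------------------- z-score

def test_zscore_train_columns_standardized_and_frozen_for_test():
    train = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [10.0, 10.0, 16.0]})
    test = pd.DataFrame({"a": [2.0], "b": [13.0]})
    ztrain, ztest, params = zscore_fit_apply(train, test)
    assert np.allclose(ztrain.mean(), 0, atol=1e-12)
    assert np.allclose(ztrain.std(ddof=0), 1, atol=1e-12)
    # test transformed with train parameters, not its own
    assert ztest.loc[0, "a"] == pytest.approx((2 - 2) / train["a"].std(ddof=0))
    # applying the frozen params to train reproduces the normalized train
    assert np.allclose(zscore_apply(params, train), ztrain)


def test_zscore_drops_zero_variance_columns():
    train = pd.DataFrame({"a": [1.0, 2.0, 3.0], "const": [5.0, 5.0, 5.0]})
    ztrain, params = zscore_fit_apply(train)
    assert "const" not in ztrain.columns
    assert list(params["mean"].index) == ["a"]


# ------------------------------------------------------------- redundancy

def test_prune_rule_on_stated_correlation_triangle():
    # rho(A,B)=0.9 offends; A's mean correlation to the rest (0.2) is lower
    # than B's (0.5), so A is kept
    corr = pd.DataFrame(
        [[1.0, 0.9, 0.2], [0.9, 1.0, 0.5], [0.2, 0.5, 1.0]],
        index=list("ABC"), columns=list("ABC"),
    )
    assert prune_redundant_from_corr(corr, 0.85) == ["A", "C"]


def test_duplicated_column_keeps_exactly_one_copy():
    rng = np.random.default_rng(0)
    x = rng.normal(size=50)
    table = pd.DataFrame({"dup1": x, "dup2": x, "other": rng.normal(size=50)})
    kept = prune_redundant(table, 0.85)
    assert "other" in kept
    assert len([k for k in kept if k.startswith("dup")]) == 1


def test_prune_tie_breaks_drop_lexicographically_later():
    corr = pd.DataFrame(
        [[1.0, 0.95, 0.3], [0.95, 1.0, 0.3], [0.3, 0.3, 1.0]],
        index=["beta", "alpha", "zed"], columns=["beta", "alpha", "zed"],
    )
    kept = prune_redundant_from_corr(corr, 0.85)
    assert kept == ["alpha", "zed"]


def test_prune_needs_three_features():
    with pytest.raises(ValueError, match="at least 3"):
        prune_redundant(pd.DataFrame({"a": [1.0, 2], "b": [2.0, 1]}))


# -------------------------------------------------------------- AUC filter

def test_feature_identical_to_label_kept_with_auc_one():
    x, y = make_features(n=60, signal=0.0, seed=1)
    x["oracle"] = y.astype(float)
    kept, aucs = auc_filter(x, y, 0.7)
    assert "oracle" in kept
    assert aucs["oracle"] == pytest.approx(1.0)


def test_anti_ordered_feature_oriented_and_kept():
    x, y = make_features(n=60, signal=0.0, seed=2)
    x["anti"] = -y.astype(float)
    kept, aucs = auc_filter(x, y, 0.7)
    assert "anti" in kept
    assert aucs["anti"] == pytest.approx(1.0)  # orientation-corrected


def test_independent_noise_dropped_at_n200():
    rng = np.random.default_rng(3)
    y = np.r_[np.zeros(100, int), np.ones(100, int)]
    x = pd.DataFrame({"noise": rng.normal(size=200), "sig": y + 0.0})
    kept, aucs = auc_filter(x, y, 0.7)
    assert "noise" not in kept
    assert 0.3 < feature_auc(x["noise"], y) < 0.7


def test_no_passing_feature_falls_back_to_best():
    rng = np.random.default_rng(4)
    y = np.r_[np.zeros(50, int), np.ones(50, int)]
    x = pd.DataFrame(rng.normal(size=(100, 5)), columns=list("abcde"))
    kept, aucs = auc_filter(x, y, 0.7)
    assert kept == [aucs.idxmax()]


# ------------------------------------------------------------------ SMOTE

def test_balanced_input_returned_unchanged():
    x, _ = make_features(n=40, seed=5)
    y = np.r_[np.zeros(20, int), np.ones(20, int)]
    bx, by = smote(x, y, seed=0)
    assert bx.equals(x)
    assert (by.to_numpy() == y).all()


def test_two_identical_minority_points_synthesize_themselves():
    x = pd.DataFrame({"a": [0.0, 0, 0, 0, 1, 1], "b": [1.0, 1, 1, 1, 2, 2]})
    y = np.array([0, 0, 0, 0, 1, 1])
    bx, by = smote(x, y, seed=1)
    assert (by == 1).sum() == (by == 0).sum() == 4
    synth = bx.iloc[6:]
    assert np.allclose(synth["a"], 1.0) and np.allclose(synth["b"], 2.0)


def test_synthetic_points_interpolate_minority_segmentwise():
    rng = np.random.default_rng(6)
    minority = rng.normal(size=(8, 3))
    majority = rng.normal(loc=5.0, size=(40, 3))
    x = pd.DataFrame(np.vstack([majority, minority]), columns=list("abc"))
    y = np.r_[np.zeros(40, int), np.ones(8, int)]
    for seed in range(100):
        bx, by = smote(x, y, k_neighbors=5, seed=seed)
        synth = bx.iloc[48:].to_numpy()
        # each coordinate of every synthetic point lies within the minority
        # class range (convex interpolation along a segment)
        assert (synth >= minority.min(axis=0) - 1e-12).all()
        assert (synth <= minority.max(axis=0) + 1e-12).all()
    assert len(by) == 80


def test_k_reduced_when_minority_small():
    x = pd.DataFrame({"a": np.r_[np.zeros(10), [0.0, 1.0, 2.0]]})
    y = np.r_[np.zeros(10, int), np.ones(3, int)]
    bx, by = smote(x, y, k_neighbors=5, seed=0)
    assert (by == 1).sum() == 10


# ------------------------------------------------------------------ LASSO

def test_large_lambda_limit_gives_empty_support_then_fallback():
    x, y = make_features(n=60, signal=3.0, seed=7)
    selected, lam, path = lasso_select(x, y, lambda_grid=(1e6, 1e5), seed=0)
    # all-zero at both lambdas -> documented fallback keeps all features
    assert [r["n_selected"] for r in path] == [0, 0]
    assert selected == list(x.columns)


def test_support_size_non_increasing_in_lambda_on_fixture():
    x, y = make_features(n=120, p=8, signal=2.0, seed=8)
    grid = tuple(np.logspace(-3, 1.5, 25))
    _, _, path = lasso_select(x, y, lambda_grid=grid, seed=0)
    path_sorted = sorted(path, key=lambda r: r["lambda"])
    sizes = [r["n_selected"] for r in path_sorted]  # increasing lambda
    assert all(a >= b for a, b in zip(sizes, sizes[1:]))


def test_planted_feature_recovered_among_noise():
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        n = 200
        y = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
        x = pd.DataFrame(rng.normal(size=(n, 51)),
                         columns=["planted"] + [f"n{t}" for t in range(50)])
        x["planted"] = y + 0.1 * rng.normal(size=n)
        selected, lam, _ = lasso_select(x, y, seed=seed)
        hits += "planted" in selected
    assert hits >= 19  # >= 95% of seeds


# ------------------------------------------------------------ SVM + threshold

def test_separable_fixture_reaches_training_accuracy_one():
    x, y = make_features(n=50, p=2, signal=6.0, seed=9)
    svm = train_svm(x, y)
    assert svm.degree == 3
    acc = (svm.predict(x.to_numpy()) == y).mean()
    assert acc == 1.0


def test_label_flip_negates_score_ordering():
    x, y = make_features(n=60, p=3, signal=1.5, seed=10)
    s1 = train_svm(x, y).decision_function(x.to_numpy())
    s2 = train_svm(x, 1 - y).decision_function(x.to_numpy())
    auc1 = feature_auc(s1, y)
    auc2 = feature_auc(s2, y)
    # symmetry holds up to the SVM solver's convergence tolerance
    assert auc2 == pytest.approx(1.0 - auc1, abs=0.02)


def test_threshold_perfect_separation_hits_ideal_corner():
    scores = np.array([0.1, 0.2, 0.8, 0.9])
    labels = np.array([0, 0, 1, 1])
    thr = choose_threshold(scores, labels)
    assert thr == pytest.approx(0.5)  # midpoint of the separating gap
    calls = scores > thr
    assert (calls == labels.astype(bool)).all()


def test_threshold_tie_breaks_toward_higher_specificity():
    # distances tie between calling one extra FP or missing one TP; the
    # lower-FPR operating point must win
    scores = np.array([0.0, 1.0, 1.0, 2.0])
    labels = np.array([0, 0, 1, 1])
    thr = choose_threshold(scores, labels)
    fpr = ((scores > thr) & (labels == 0)).mean() * 2
    sens = ((scores > thr) & (labels == 1)).sum() / 2
    assert fpr == 0.0 and sens == 0.5


def test_degenerate_constant_scores_fall_back_to_midpoint():
    thr = choose_threshold(np.full(6, 1.5), np.array([0, 0, 0, 1, 1, 1]))
    assert thr == 1.5


# ------------------------------------------------------- Model / Results

@pytest.fixture(scope="module")
def fitted():
    x, y = make_features(n=90, p=10, signal=2.5, seed=11)
    model = SignatureModel(x, y, SignatureConfig(lambda_grid=tuple(np.logspace(-3, 1, 20))))
    return model, model.fit(seed=0), x, y


def test_feature_lists_nest_monotonically(fitted):
    _, res, _, _ = fitted
    assert set(res.lasso_features) <= set(res.auc_features)
    assert set(res.auc_features) <= set(res.pruned_features)
    assert set(res.pruned_features) <= set(res.stable_features)


def test_applying_to_training_set_is_deterministic(fitted):
    _, res, x, _ = fitted
    a = res.predict(x)
    b = res.predict(x)
    assert a.equals(b)
    assert set(a["call"]) <= {"HR", "LR"}
    assert ((a["score"] > res.threshold) == (a["call"] == "HR")).all()


def test_serialization_round_trip_reproduces_scores(fitted, tmp_path):
    _, res, x, _ = fitted
    res.save(tmp_path / "model.json")
    frozen = SignatureResults.load(tmp_path / "model.json")
    a = res.predict(x)["score"].to_numpy()
    b = frozen.predict(x)["score"].to_numpy()
    assert np.allclose(a, b, atol=1e-12)


def test_fit_is_bitwise_invariant_to_anything_outside_training(fitted):
    model, res, x, y = fitted
    res2 = SignatureModel(x, y, model.config).fit(seed=0)
    assert res.to_json() == res2.to_json()


def test_missing_feature_names_raise(fitted):
    _, res, x, _ = fitted
    with pytest.raises(KeyError, match="missing features"):
        res.predict(x.drop(columns=[res.lasso_features[0]]))


def test_summary_mentions_pipeline_stages(fitted):
    _, res, _, _ = fitted
    text = res.summary()
    assert "LASSO-selected" in text
    assert "threshold" in text
    assert str(len(res.lasso_features)) in text


def test_labels_must_contain_both_classes():
    x, _ = make_features(n=20, seed=12)
    with pytest.raises(ValueError, match="both classes"):
        SignatureModel(x, np.zeros(20, int))
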