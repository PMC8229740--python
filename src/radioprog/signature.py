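"""Radiomic prognostic signature: selection pipeline, SVM model and results.

``SignatureModel`` is built from a training feature table and binary labels
(1 = short survivor / high risk) and ``fit()`` returns a frozen
``SignatureResults``. The training pipeline composes, in order:

1. Z-score normalization (training mean/sd; zero-variance columns dropped);
2. redundancy pruning: of any feature pair with |Spearman rho| > 0.85 only
   one is kept — the one with the lower mean absolute correlation to the
   other retained features;
3. univariate AUC filter: keep features whose orientation-corrected
   rank-sum AUC max(A, 1-A) exceeds 0.7;
4. SMOTE class balancing (synthetic minority interpolation) — synthetic
   points are used only to fit the LASSO and the SVM, never for screening;
5. LASSO feature selection: L1-penalized logistic regression, lambda chosen
   by stratified cross-validated AUC on a log-spaced grid;
6. cubic-kernel SVM on the LASSO-selected features; its continuous decision
   value is the radiomic signature score;
7. ROC threshold: the training operating point closest to the ideal corner
   (sensitivity 100%, false-positive rate 0%). Scores above the threshold
   are called high risk (HR).

Applying the results to new patients uses only frozen parameters: no test
statistic influences any transformation.
"""

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

DEFAULT_RHO_THRESHOLD = 0.85
DEFAULT_AUC_THRESHOLD = 0.7


@dataclass(frozen=True)
class SignatureConfig:
    """Tunable knobs of the signature pipeline (defaults as in the docs)."""

    rho_threshold: float = DEFAULT_RHO_THRESHOLD
    auc_threshold: float = DEFAULT_AUC_THRESHOLD
    smote_k_neighbors: int = 5
    n_folds: int = 5
    lambda_grid: tuple = tuple(np.logspace(-4, 2, 50))
    svm_c: float = 1.0
    svm_degree: int = 3
    svm_coef0: float = 0.0
    svm_gamma: str = "scale"


# --------------------------------------------------------------------------
# pipeline stages (each usable standalone)
# --------------------------------------------------------------------------

def zscore_fit(train):
    """Training per-feature mean/sd; zero-variance columns are dropped."""
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    keep = sd[sd > 0].index
    dropped = [c for c in train.columns if c not in set(keep)]
    if dropped:
        logger.info("z-score: dropped %d zero-variance features", len(dropped))
    return {"mean": mean[keep], "sd": sd[keep]}


def zscore_apply(params, table):
    """Apply frozen normalization parameters to any feature table."""
    cols = params["mean"].index
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise KeyError(f"feature table lacks normalized features: {missing[:5]}")
    return (table[cols] - params["mean"]) / params["sd"]


def zscore_fit_apply(train, other=None):
    params = zscore_fit(train)
    out_train = zscore_apply(params, train)
    if other is None:
        return out_train, params
    return out_train, zscore_apply(params, other), params


def prune_redundant_from_corr(corr, threshold=DEFAULT_RHO_THRESHOLD):
    """Greedy redundancy pruning given an absolute correlation matrix.

    Offending pairs are visited in decreasing |rho|; for each pair still
    retained, the member with the higher mean |rho| to the other retained
    features is dropped (ties: the lexicographically later name).
    """
    corr = corr.abs()
    names = list(corr.columns)
    retained = set(names)
    iu, ju = np.triu_indices(len(names), k=1)
    vals = corr.to_numpy()[iu, ju]
    order = np.argsort(-vals, kind="stable")
    for t in order:
        if vals[t] <= threshold:
            break
        a, b = names[iu[t]], names[ju[t]]
        if a not in retained or b not in retained:
            continue
        others = [c for c in retained if c not in (a, b)]
        if others:
            mean_a = corr.loc[a, others].mean()
            mean_b = corr.loc[b, others].mean()
        else:
            mean_a = mean_b = 0.0
        if mean_a > mean_b:
            drop = a
        elif mean_b > mean_a:
            drop = b
        else:
            drop = max(a, b)
        retained.discard(drop)
    return [c for c in names if c in retained]


def prune_redundant(table, threshold=DEFAULT_RHO_THRESHOLD):
    """Spearman-based redundancy pruning of a feature table."""
    if table.shape[1] < 3:
        raise ValueError("redundancy pruning needs at least 3 features")
    rho, _ = spearmanr(table.to_numpy())
    rho = pd.DataFrame(
        np.atleast_2d(rho), index=table.columns, columns=table.columns
    )
    return prune_redundant_from_corr(rho, threshold)


def feature_auc(values, labels):
    """Rank-sum (Mann-Whitney) AUC of one feature used as a score."""
    labels = np.asarray(labels)
    ranks = rankdata(values)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    return (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def auc_filter(table, labels, threshold=DEFAULT_AUC_THRESHOLD):
    """Keep features with orientation-corrected AUC strictly above threshold.

    If no feature passes, the single best-ranked feature is kept (logged):
    a cohort without univariate signal still yields a well-defined, honest
    (near-random) downstream model.
    """
    labels = np.asarray(labels)
    if labels.sum() == 0:
        raise ValueError(
            "no short survivor in training labels; increase the synthetic effect size"
        )
    ranks = np.apply_along_axis(rankdata, 0, table.to_numpy(dtype=np.float64))
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    auc = (ranks[labels == 1].sum(axis=0) - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    oriented = np.maximum(auc, 1.0 - auc)
    aucs = pd.Series(oriented, index=table.columns)
    kept = aucs[aucs > threshold].index.tolist()
    if not kept:
        best = aucs.idxmax()
        logger.warning(
            "AUC filter: no feature above %.2f; keeping best feature %r (AUC %.3f)",
            threshold, best, aucs.max(),
        )
        kept = [best]
    return kept, aucs


def smote(table, labels, k_neighbors=5, seed=0):
    """Synthetic Minority Oversampling: balance classes by interpolation.

    New minority samples are x_i + u (x_nn - x_i) with u ~ Uniform(0, 1) and
    x_nn one of the k nearest minority neighbors of x_i. Already-balanced
    input is returned unchanged.
    """
    labels = pd.Series(np.asarray(labels), index=table.index, name="label")
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValueError("SMOTE needs both classes")
    minority = counts.idxmin()
    n_needed = int(counts.max() - counts.min())
    if n_needed == 0:
        return table.copy(), labels.copy()
    minority_x = table[labels == minority].to_numpy(dtype=np.float64)
    n_min = minority_x.shape[0]
    if n_min < 2:
        raise ValueError("SMOTE needs at least 2 minority samples")
    k = min(k_neighbors, n_min - 1)
    if k < k_neighbors:
        logger.info("SMOTE: k reduced to %d (minority size %d)", k, n_min)
    d2 = ((minority_x[:, None, :] - minority_x[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    nn_idx = np.argsort(d2, axis=1)[:, :k]
    rng = np.random.default_rng(seed)
    base = rng.integers(0, n_min, size=n_needed)
    pick = nn_idx[base, rng.integers(0, k, size=n_needed)]
    u = rng.random(n_needed)[:, None]
    synthetic = minority_x[base] + u * (minority_x[pick] - minority_x[base])
    synth_index = [f"synthetic_{t}" for t in range(n_needed)]
    out = pd.concat(
        [table, pd.DataFrame(synthetic, columns=table.columns, index=synth_index)]
    )
    out_labels = pd.concat(
        [labels, pd.Series(minority, index=synth_index, name="label")]
    )
    return out, out_labels


def _cv_auc(x, y, c, n_folds, seed):
    folds = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    aucs = []
    for tr, te in folds.split(x, y):
        model = LogisticRegression(
            l1_ratio=1.0, C=c, solver="liblinear", max_iter=2000, random_state=0
        )
        model.fit(x[tr], y[tr])
        score = model.decision_function(x[te])
        if len(set(y[te])) < 2:
            continue
        aucs.append(feature_auc(score, y[te]))
    return float(np.mean(aucs)) if aucs else 0.5


def lasso_select(table, labels, n_folds=5, lambda_grid=None, seed=0):
    """L1-penalized logistic selection with lambda chosen by CV AUC.

    Returns (selected feature names, chosen lambda, per-lambda path info).
    The liblinear parameterization is C = 1/lambda. Ties in CV AUC resolve
    toward the larger lambda (sparser model). If the winning lambda has an
    all-zero solution, the smallest lambda with a nonzero solution is used;
    if none exists, all candidate features are retained (logged fallback).
    """
    if lambda_grid is None:
        lambda_grid = tuple(np.logspace(-4, 2, 50))
    lambdas = np.sort(np.asarray(list(lambda_grid)))[::-1]  # large -> small
    x = table.to_numpy(dtype=np.float64)
    y = np.asarray(labels, dtype=int)
    if x.shape[0] < 2 * n_folds:
        raise ValueError("need at least 2 patients per CV fold")
    path = []
    for lam in lambdas:
        model = LogisticRegression(
            l1_ratio=1.0, C=1.0 / lam, solver="liblinear", max_iter=2000,
            random_state=0,
        )
        model.fit(x, y)
        nz = np.flatnonzero(np.abs(model.coef_[0]) > 0)
        cv = _cv_auc(x, y, 1.0 / lam, n_folds, seed)
        path.append(
            {"lambda": float(lam), "cv_auc": cv, "n_selected": int(nz.size),
             "coef": model.coef_[0].copy()}
        )
    best = max(path, key=lambda r: (r["cv_auc"], r["lambda"]))
    if best["n_selected"] == 0:
        nonzero = [r for r in path if r["n_selected"] > 0]
        if nonzero:
            best = nonzero[-1]  # smallest lambda with support
            logger.warning(
                "LASSO: CV-optimal lambda had empty support; using lambda=%.4g",
                best["lambda"],
            )
        else:
            logger.warning("LASSO: empty support at every lambda; keeping all features")
            return list(table.columns), float(lambdas[-1]), path
    selected = [table.columns[t] for t in np.flatnonzero(np.abs(best["coef"]) > 0)]
    return selected, best["lambda"], path


def train_svm(table, labels, config=SignatureConfig()):
    """Cubic-kernel SVM; the decision value is the signature score."""
    model = SVC(
        kernel="poly",
        degree=config.svm_degree,
        C=config.svm_c,
        coef0=config.svm_coef0,
        gamma=config.svm_gamma,
    )
    model.fit(table.to_numpy(dtype=np.float64), np.asarray(labels, dtype=int))
    return model


def choose_threshold(scores, labels):
    """ROC operating point closest to (sensitivity 1, FPR 0).

    Candidate thresholds are midpoints between adjacent distinct scores plus
    outside sentinels; ties resolve toward higher specificity. Calls are
    'score > threshold'.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    if len(set(labels)) < 2:
        raise ValueError("both classes required to choose a threshold")
    uniq = np.unique(scores)
    if uniq.size == 1:
        logger.warning("degenerate single-valued scores; using midpoint threshold")
        return float(uniq[0])
    mids = (uniq[1:] + uniq[:-1]) / 2.0
    cands = np.concatenate(([uniq[0] - 1.0], mids, [uniq[-1] + 1.0]))
    n_pos = labels.sum()
    n_neg = labels.size - n_pos
    best = None
    for thr in cands:
        calls = scores > thr
        sens = (calls & (labels == 1)).sum() / n_pos
        fpr = (calls & (labels == 0)).sum() / n_neg
        dist = np.hypot(1.0 - sens, fpr)
        key = (dist, fpr)  # ties -> higher specificity (lower FPR)
        if best is None or key < best[0]:
            best = (key, float(thr))
    return best[1]


# --------------------------------------------------------------------------
# Model / Results
# --------------------------------------------------------------------------

class SignatureModel:
    """Radiomic signature model built from training data.

    Parameters
    ----------
    features : DataFrame
        Training patients x feature values (already screened for stability).
    labels : array-like of {0, 1}
        1 = short survivor (overall survival <= 10 months).
    config : SignatureConfig
    """

    def __init__(self, features, labels, config=SignatureConfig()):
        self.features = features.copy()
        self.labels = pd.Series(
            np.asarray(labels, dtype=int), index=features.index, name="label"
        )
        if set(self.labels.unique()) != {0, 1}:
            raise ValueError("labels must contain both classes, coded 0/1")
        self.config = config

    @classmethod
    def from_dataframe(cls, frame, label_col="label", config=SignatureConfig()):
        labels = frame[label_col]
        return cls(frame.drop(columns=[label_col]), labels, config)

    def fit(self, seed=0):
        """Run the full selection + SVM + thresholding pipeline."""
        cfg = self.config
        norm_train, norm = zscore_fit_apply(self.features)
        pruned = prune_redundant(norm_train, cfg.rho_threshold)
        auc_kept, aucs = auc_filter(norm_train[pruned], self.labels, cfg.auc_threshold)
        bal_x, bal_y = smote(
            norm_train[auc_kept], self.labels, cfg.smote_k_neighbors, seed
        )
        lasso_feats, lam, path = lasso_select(
            bal_x, bal_y, cfg.n_folds, cfg.lambda_grid, seed
        )
        final_coef = next(
            r["coef"] for r in path if r["lambda"] == lam
        )
        coef_map = {
            f: float(c)
            for f, c in zip(bal_x.columns, final_coef)
            if f in set(lasso_feats)
        }
        svm = train_svm(bal_x[lasso_feats], bal_y, cfg)
        train_scores = svm.decision_function(
            norm_train[lasso_feats].to_numpy(dtype=np.float64)
        )
        threshold = choose_threshold(train_scores, self.labels.to_numpy())
        return SignatureResults(
            model=self,
            normalization=norm,
            stable_features=list(self.features.columns),
            pruned_features=pruned,
            auc_features=auc_kept,
            lasso_features=lasso_feats,
            lasso_lambda=float(lam),
            lasso_coefficients=coef_map,
            feature_aucs=aucs,
            svm=svm,
            threshold=float(threshold),
            seed=int(seed),
        )


@dataclass
class SignatureResults:
    """Frozen fitted signature: parameters, selected features, threshold."""

    model: SignatureModel
    normalization: dict
    stable_features: list
    pruned_features: list
    auc_features: list
    lasso_features: list
    lasso_lambda: float
    lasso_coefficients: dict
    feature_aucs: pd.Series
    svm: object
    threshold: float
    seed: int

    def predict(self, features):
        """Score and call new patients with frozen parameters only.

        Returns a DataFrame (patient index) with ``score`` and ``call``
        (HR = high risk, score > threshold; else LR).
        """
        missing = [f for f in self.normalization["mean"].index
                   if f not in features.columns]
        if missing:
            raise KeyError(f"missing features: {missing[:10]}")
        norm = zscore_apply(self.normalization, features)
        scores = self.svm.decision_function(
            norm[self.lasso_features].to_numpy(dtype=np.float64)
        )
        calls = np.where(scores > self.threshold, "HR", "LR")
        return pd.DataFrame({"score": scores, "call": calls}, index=features.index)

    def summary(self):
        """Human-readable account of the fitted pipeline."""
        lines = [
            "Radiomic signature - fitted pipeline",
            "=" * 44,
            f"training patients        {self.model.features.shape[0]}",
            f"short survivors (label1) {int(self.model.labels.sum())}",
            f"stable features (input)  {len(self.stable_features)}",
            f"after redundancy pruning {len(self.pruned_features)}",
            f"after AUC filter (>{self.model.config.auc_threshold})   "
            f"{len(self.auc_features)}",
            f"LASSO-selected           {len(self.lasso_features)}"
            f"   (lambda = {self.lasso_lambda:.4g})",
            f"SVM kernel               poly, degree "
            f"{self.model.config.svm_degree}, C = {self.model.config.svm_c}",
            f"score threshold (HR if >) {self.threshold:.6g}",
            "",
            "selected features and LASSO coefficients:",
        ]
        for f in self.lasso_features:
            lines.append(f"  {f:55s} {self.lasso_coefficients.get(f, 0.0):+.4f}")
        return "\n".join(lines)

    # -- serialization ----------------------------------------------------

    def to_json(self):
        svm = self.svm
        payload = {
            "normalization": {
                "features": list(self.normalization["mean"].index),
                "mean": self.normalization["mean"].tolist(),
                "sd": self.normalization["sd"].tolist(),
            },
            "stable_features": self.stable_features,
            "pruned_features": self.pruned_features,
            "auc_features": self.auc_features,
            "lasso_features": self.lasso_features,
            "lasso_lambda": self.lasso_lambda,
            "lasso_coefficients": self.lasso_coefficients,
            "threshold": self.threshold,
            "seed": self.seed,
            "svm": {
                "degree": int(svm.degree),
                "C": float(svm.C),
                "coef0": float(svm.coef0),
                "gamma": float(svm._gamma),
                "support_vectors": svm.support_vectors_.tolist(),
                "dual_coef": svm.dual_coef_.tolist(),
                "intercept": svm.intercept_.tolist(),
            },
        }
        return json.dumps(payload, indent=1)

    def save(self, path):
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @staticmethod
    def load(path):
        """Rebuild a frozen, predict-capable results object from JSON."""
        with open(path) as fh:
            payload = json.load(fh)
        return FrozenSignature(payload)


class FrozenSignature:
    """Predict-only signature reconstructed from its JSON serialization."""

    def __init__(self, payload):
        self.payload = payload
        norm = payload["normalization"]
        self.normalization = {
            "mean": pd.Series(norm["mean"], index=norm["features"]),
            "sd": pd.Series(norm["sd"], index=norm["features"]),
        }
        self.lasso_features = payload["lasso_features"]
        self.threshold = payload["threshold"]
        svm = payload["svm"]
        self._sv = np.asarray(svm["support_vectors"], dtype=np.float64)
        self._dual = np.asarray(svm["dual_coef"], dtype=np.float64)
        self._intercept = np.asarray(svm["intercept"], dtype=np.float64)
        self._gamma = svm["gamma"]
        self._coef0 = svm["coef0"]
        self._degree = svm["degree"]

    def decision_function(self, x):
        k = (self._gamma * (x @ self._sv.T) + self._coef0) ** self._degree
        return k @ self._dual[0] + self._intercept[0]

    def predict(self, features):
        norm = zscore_apply(self.normalization, features)
        scores = self.decision_function(
            norm[self.lasso_features].to_numpy(dtype=np.float64)
        )
        calls = np.where(scores > self.threshold, "HR", "LR")
        return pd.DataFrame({"score": scores, "call": calls}, index=features.index)


def fit_signature(features, labels, config=SignatureConfig(), seed=0):
    """Functional wrapper: build and fit a SignatureModel."""
    return SignatureModel(features, labels, config).fit(seed)


def apply_signature(results, features):
    """Functional wrapper around ``SignatureResults.predict``."""
    return results.predict(features)
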