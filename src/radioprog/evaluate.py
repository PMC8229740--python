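"""Evaluation surface: confusion metrics with Wilson intervals, ROC/AUC,
clinical-baseline classifiers (with direction inversion) and the
signature-volume Spearman check.

Proportion intervals are Wilson score intervals (statsmodels); the AUC
interval is a seeded stratified bootstrap. AUC is the trapezoidal area
under the empirical ROC, which equals the tie-corrected rank-sum statistic.
"""

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata
from statsmodels.stats.proportion import proportion_confint

logger = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self):
        return self.tp + self.fn + self.tn + self.fp

    @property
    def accuracy(self):
        return (self.tp + self.tn) / self.n

    @property
    def sensitivity(self):
        pos = self.tp + self.fn
        return self.tp / pos if pos else float("nan")

    @property
    def specificity(self):
        neg = self.tn + self.fp
        return self.tn / neg if neg else float("nan")


def confusion_metrics(calls, labels):
    """Confusion counts and accuracy/sensitivity/specificity.

    ``calls`` may be boolean/0-1 or 'HR'/'LR' strings.
    """
    calls = np.asarray(calls)
    if calls.dtype.kind in "USO":
        bad = set(calls) - {"HR", "LR"}
        if bad:
            raise ValueError(f"string calls must be 'HR'/'LR', got {sorted(bad)}")
        calls = calls == "HR"
    calls = calls.astype(bool)
    labels = np.asarray(labels, dtype=int)
    if calls.shape != labels.shape:
        raise ValueError("calls and labels must have equal length")
    counts = ConfusionCounts(
        tp=int((calls & (labels == 1)).sum()),
        fn=int((~calls & (labels == 1)).sum()),
        tn=int((~calls & (labels == 0)).sum()),
        fp=int((calls & (labels == 0)).sum()),
    )
    if counts.tp + counts.fn == 0 or counts.tn + counts.fp == 0:
        logger.warning("one class absent: sensitivity or specificity undefined")
    return counts


def wilson_interval(successes, n, level=0.95):
    """Wilson score confidence interval for a binomial proportion."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    lo, hi = proportion_confint(successes, n, alpha=1 - level, method="wilson")
    # the Wilson bounds are algebraically exact at the extremes
    if successes == n:
        hi = 1.0
    if successes == 0:
        lo = 0.0
    return float(max(lo, 0.0)), float(min(hi, 1.0))


def roc_curve_points(scores, labels):
    """Empirical ROC points (FPR, TPR) over unique-score thresholds."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    n_pos = y.sum()
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required for a ROC curve")
    tps = np.cumsum(y)
    fps = np.cumsum(1 - y)
    distinct = np.r_[s[1:] != s[:-1], True]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    return fpr, tpr


def roc_auc(scores, labels):
    """Trapezoidal AUC with its ROC points.

    Constant scores yield AUC 0.5 (flagged degenerate in the log).
    """
    scores = np.asarray(scores, dtype=np.float64)
    if np.unique(scores).size == 1:
        logger.warning("constant scores: AUC degenerate at 0.5")
    fpr, tpr = roc_curve_points(scores, labels)
    auc = float(np.trapezoid(tpr, fpr))
    return auc, (fpr, tpr)


def bootstrap_auc_interval(scores, labels, level=0.95, n_boot=2000, seed=0):
    """Stratified bootstrap percentile interval for the AUC."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    s_pos = scores[labels == 1]
    s_neg = scores[labels == 0]
    if s_pos.size == 0 or s_neg.size == 0:
        raise ValueError("both classes required")
    bp = s_pos[rng.integers(0, s_pos.size, size=(n_boot, s_pos.size))]
    bn = s_neg[rng.integers(0, s_neg.size, size=(n_boot, s_neg.size))]
    # rank-sum AUC for every bootstrap replicate at once
    gt = (bp[:, :, None] > bn[:, None, :]).mean(axis=(1, 2))
    eq = (bp[:, :, None] == bn[:, None, :]).mean(axis=(1, 2))
    vals = gt + 0.5 * eq
    lo, hi = np.percentile(vals, [100 * (1 - level) / 2, 100 * (1 + level) / 2])
    return float(lo), float(hi)


def spearman_test(x, y):
    """Spearman rho (average ranks on ties) with its two-sided t-test p."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 4:
        raise ValueError("need two equal-length samples with n >= 4")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("zero rank variance")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def spearman_pvalue(rho, n):
    """Two-sided p for a given Spearman rho at sample size n (t approx)."""
    if not -1 < rho < 1:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2 * stats.t.sf(abs(t), df=n - 2))


@dataclass
class MetricWithCI:
    value: float
    lower: float
    upper: float

    def as_tuple(self):
        return self.value, self.lower, self.upper

    def __str__(self):
        return f"{self.value:.2f} ({self.lower:.2f}-{self.upper:.2f})"


@dataclass
class EvaluationReport:
    """Classification quality metrics of one variable / one classifier."""

    variable: str
    counts: ConfusionCounts
    accuracy: MetricWithCI
    sensitivity: MetricWithCI
    specificity: MetricWithCI
    auc: float
    auc_interval: tuple = (float("nan"), float("nan"))
    roc: tuple = None
    inverted: bool = False
    threshold: float = float("nan")

    def to_dict(self):
        return {
            "variable": self.variable,
            "n": self.counts.n,
            "tp": self.counts.tp,
            "fn": self.counts.fn,
            "tn": self.counts.tn,
            "fp": self.counts.fp,
            "accuracy": self.accuracy.as_tuple(),
            "sensitivity": self.sensitivity.as_tuple(),
            "specificity": self.specificity.as_tuple(),
            "auc": self.auc,
            "auc_interval": list(self.auc_interval),
            "inverted": self.inverted,
            "threshold": self.threshold,
        }

    def check_consistency(self):
        """Every reported metric must be recomputable from the counts."""
        c = self.counts
        pairs = [
            (self.accuracy, c.accuracy),
            (self.sensitivity, c.sensitivity),
            (self.specificity, c.specificity),
        ]
        for m, ref in pairs:
            if np.isnan(ref):
                assert np.isnan(m.value)
                continue
            assert abs(m.value - ref) < 1e-12
            assert m.lower - 1e-12 <= m.value <= m.upper + 1e-12
        return True


def evaluate_calls(variable, calls, labels, scores=None, level=0.95,
                   seed=0, inverted=False, threshold=float("nan")):
    """Build an EvaluationReport from calls (and optional scores for AUC)."""
    counts = confusion_metrics(calls, labels)

    def metric(successes, n):
        if n == 0:  # class absent: metric undefined, flagged upstream
            return MetricWithCI(float("nan"), float("nan"), float("nan"))
        return MetricWithCI(successes / n, *wilson_interval(successes, n, level))

    acc = metric(counts.tp + counts.tn, counts.n)
    sens = metric(counts.tp, counts.tp + counts.fn)
    spec = metric(counts.tn, counts.tn + counts.fp)
    auc, roc, auc_ci = float("nan"), None, (float("nan"), float("nan"))
    if scores is not None:
        try:
            auc, roc = roc_auc(scores, labels)
            auc_ci = bootstrap_auc_interval(scores, labels, level, seed=seed)
        except ValueError as err:
            logger.warning("AUC unavailable for %r: %s", variable, err)
    report = EvaluationReport(
        variable=variable, counts=counts, accuracy=acc, sensitivity=sens,
        specificity=spec, auc=auc, auc_interval=auc_ci, roc=roc,
        inverted=inverted, threshold=threshold,
    )
    report.check_consistency()
    return report


CLINICAL_BASELINE_VARIABLES = [
    "largest_volume",
    "total_volume",
    "n_lesions",
    "n_organs",
    "performance_status",
    "non_metastatic",
]


def clinical_baselines(clinical, labels, seed=0):
    """Score each clinical variable as a one-dimensional classifier.

    Each variable is used as a risk score; if its AUC is below 0.5 the
    thresholding direction is inverted (low values called high-risk) before
    the closest-to-corner threshold is chosen.
    """
    from .signature import choose_threshold

    labels = np.asarray(labels, dtype=int)
    if len(set(labels)) < 2:
        logger.warning("one survival class absent: clinical baselines skipped")
        return []
    reports = []
    for col in clinical.columns:
        values = clinical[col].to_numpy(dtype=np.float64)
        if np.unique(values).size < 2:
            logger.warning("clinical variable %r constant: uninformative", col)
            continue
        auc, _ = roc_auc(values, labels)
        inverted = auc < 0.5
        scores = -values if inverted else values
        thr = choose_threshold(scores, labels)
        calls = scores > thr
        reports.append(
            evaluate_calls(
                col, calls, labels, scores=scores, seed=seed,
                inverted=inverted, threshold=float(thr),
            )
        )
    return reports


def reports_to_frame(reports):
    """Table mirroring the published layout: variable, metrics (CI), AUC."""
    rows = []
    for r in reports:
        rows.append(
            {
                "variable": r.variable,
                "accuracy": str(r.accuracy),
                "sensitivity": str(r.sensitivity),
                "specificity": str(r.specificity),
                "auc": round(r.auc, 3) if np.isfinite(r.auc) else "",
            }
        )
    return pd.DataFrame(rows)


def plot_roc(reports, ax=None):
    """Plot the ROC curve(s) of one or more EvaluationReports."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    if not isinstance(reports, (list, tuple)):
        reports = [reports]
    for r in reports:
        if r.roc is None:
            continue
        fpr, tpr = r.roc
        ax.plot(fpr, tpr, label=f"{r.variable} (AUC {r.auc:.2f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right", fontsize=8)
    return ax


def save_reports(reports, json_path=None, csv_path=None):
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump([r.to_dict() for r in reports], fh, indent=1)
    if csv_path is not None:
        reports_to_frame(reports).to_csv(csv_path, index=False)
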