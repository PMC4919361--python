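"""Leave-one-out cross-validation and classification metrics.

Each subject in turn is held out; per-voxel z-score normalization is fitted
on the remaining subjects only (no leakage), the multi-kernel SVM is trained
on those subjects, and the held-out subject is predicted.  Pooled LOOCV
decision values give one ROC curve per comparison; the AUC equals the
Mann-Whitney statistic.

Rates are reported as percentages; formatted reports round half-up to two
decimals while full precision is retained internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .features import FeatureMatrix, zscore_apply, zscore_fit
from .mkl import MultiKernelSVC

logger = logging.getLogger(__name__)


@dataclass
class FoldResult:
    held_out_id: str
    y_true: int
    y_pred: int
    decision: float


@dataclass
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass
class MetricsReport:
    """Sensitivity/specificity/accuracy (percent), ROC points and AUC."""

    counts: ConfusionCounts
    sensitivity: float
    specificity: float
    accuracy: float
    roc_points: list
    auc: float

    def formatted(self) -> dict:
        return {
            "SEN": round_half_up(self.sensitivity),
            "SPE": round_half_up(self.specificity),
            "ACC": round_half_up(self.accuracy),
            "AUC": round_half_up(self.auc),
        }


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero toward +inf, like printed report tables."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _as_matrix_dict(feature_matrices) -> dict:
    if isinstance(feature_matrices, dict):
        out = {}
        for name, m in feature_matrices.items():
            out[name] = np.asarray(getattr(m, "values", m), dtype=float)
        return out
    return {f"feature_{i}": np.asarray(getattr(m, "values", m), dtype=float)
            for i, m in enumerate(feature_matrices)}


def loocv(feature_matrices, labels, C: float = 100.0, subject_ids=None,
          normalize_kernels: bool = True, foldwise_zscore: bool = True,
          tol: float = 1e-4, max_outer: int = 100) -> list[FoldResult]:
    """LOOCV of the multi-kernel SVM over per-feature matrices.

    ``feature_matrices`` maps feature name to an (n, D_f) array or
    FeatureMatrix.  With ``foldwise_zscore`` (the default) the z-score is
    re-fitted inside every training fold; otherwise one global normalization
    over all subjects is used.
    """
    mats = _as_matrix_dict(feature_matrices)
    y = np.asarray(labels, dtype=int)
    n = y.size
    if n < 3:
        raise ValueError("LOOCV needs at least 3 subjects")
    if subject_ids is None:
        first = next(iter(feature_matrices.values())) if isinstance(feature_matrices, dict) else None
        subject_ids = getattr(first, "subject_ids", None) or [f"sub-{i+1:03d}" for i in range(n)]
    for name, X in mats.items():
        if X.shape[0] != n:
            raise ValueError(f"feature {name} has {X.shape[0]} rows, expected {n}")

    if not foldwise_zscore:
        all_rows = np.arange(n)
        mats = {
            name: zscore_apply(FeatureMatrix(name, X, list(subject_ids)),
                               zscore_fit(FeatureMatrix(name, X, list(subject_ids)),
                                          all_rows)).values
            for name, X in mats.items()
        }

    results = []
    for i in range(n):
        train = np.delete(np.arange(n), i)
        y_train = y[train]
        if len(np.unique(y_train)) < 2:
            raise ValueError(
                f"training fold holding out {subject_ids[i]} has one class only")
        X_train, X_test = [], []
        for name, X in mats.items():
            fm = FeatureMatrix(name, X, list(subject_ids))
            if foldwise_zscore:
                params = zscore_fit(fm, train)
                Xn = zscore_apply(fm, params).values
            else:
                Xn = X
            X_train.append(Xn[train])
            X_test.append(Xn[[i]])
        clf = MultiKernelSVC(C=C, kernel="linear",
                             normalize_kernels=normalize_kernels,
                             tol=tol, max_outer=max_outer)
        clf.fit(X_train, y_train)
        d = float(clf.decision_function(X_test)[0])
        pred = 1 if d >= 0 else -1
        results.append(FoldResult(held_out_id=subject_ids[i], y_true=int(y[i]),
                                  y_pred=pred, decision=d))
    return results


def confusion_from_folds(fold_results) -> ConfusionCounts:
    tp = sum(1 for r in fold_results if r.y_true == 1 and r.y_pred == 1)
    fn = sum(1 for r in fold_results if r.y_true == 1 and r.y_pred == -1)
    tn = sum(1 for r in fold_results if r.y_true == -1 and r.y_pred == -1)
    fp = sum(1 for r in fold_results if r.y_true == -1 and r.y_pred == 1)
    return ConfusionCounts(tp=tp, fn=fn, tn=tn, fp=fp)


def rates_from_counts(counts: ConfusionCounts):
    """(sensitivity, specificity, accuracy) in percent, full precision."""
    if counts.tp + counts.fn == 0 or counts.tn + counts.fp == 0:
        raise ValueError("both a patient and a control class are required")
    sen = 100.0 * counts.tp / (counts.tp + counts.fn)
    spe = 100.0 * counts.tn / (counts.tn + counts.fp)
    acc = 100.0 * (counts.tp + counts.tn) / counts.n
    return sen, spe, acc


def confusion_metrics(fold_results):
    """Confusion counts and percent rates from LOOCV fold results."""
    if not fold_results:
        raise ValueError("no fold results")
    counts = confusion_from_folds(fold_results)
    sen, spe, acc = rates_from_counts(counts)
    return counts, sen, spe, acc


def roc_auc(decision_values, labels):
    """ROC points (1-specificity, sensitivity) and AUC from pooled decisions.

    The curve sweeps a threshold over the decision values with ties grouped;
    the trapezoidal area under that curve equals the Mann-Whitney statistic
    (patient-beats-control pair probability, ties counted half).
    """
    d = np.asarray(decision_values, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == -1).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-d, kind="stable")
    d_sorted, y_sorted = d[order], y[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < y_sorted.size:
        j = i
        while j < y_sorted.size and d_sorted[j] == d_sorted[i]:
            j += 1
        tp += int((y_sorted[i:j] == 1).sum())
        fp += int((y_sorted[i:j] == -1).sum())
        points.append((fp / n_neg, tp / n_pos))
        i = j
    fpr = np.array([p[0] for p in points])
    tpr = np.array([p[1] for p in points])
    auc = float(np.trapezoid(tpr, fpr))
    return points, auc


def metrics_report(fold_results) -> MetricsReport:
    counts, sen, spe, acc = confusion_metrics(fold_results)
    d = [r.decision for r in fold_results]
    y = [r.y_true for r in fold_results]
    points, auc = roc_auc(d, y)
    return MetricsReport(counts=counts, sensitivity=sen, specificity=spe,
                         accuracy=acc, roc_points=points, auc=auc)


def plot_roc(reports: dict, path) -> None:
    """Write one ROC plot with a curve per report (feature or Combined)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, rep in reports.items():
        arr = np.asarray(rep.roc_points)
        ax.plot(arr[:, 0], arr[:, 1], label=f"{name} (AUC={rep.auc:.2f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def improvement_over_best_single(combined_accuracy: float,
                                 single_accuracies) -> float:
    """Accuracy gain of the combined model over the best single feature,
    in percentage points."""
    singles = list(single_accuracies)
    if not singles:
        raise ValueError("need at least one single-feature accuracy")
    return combined_accuracy - max(singles)
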