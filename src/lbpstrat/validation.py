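"""Cluster-robustness and clinical-utility validation.

A multiclass (multinomial) logistic regression is fit to the consensus
cluster labels under stratified five-fold cross-validation, with features
robust-scaled inside each training fold.  Performance is summarized by
per-fold accuracy (mean +/- SD), a shuffled-label chance baseline,
one-vs-rest ROC and precision-recall curves with 1000-bootstrap 95%
bands, and decision-curve analysis: net benefit

    NB(pt) = TP/N - (FP/N) * pt / (1 - pt)

at threshold probability pt, compared against treat-all and treat-none
references.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from lbpstrat.preprocess import FeatureMatrix


@dataclass
class NetBenefitCurve:
    class_id: int
    thresholds: np.ndarray
    net_benefit: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    treat_all: np.ndarray
    treat_none: np.ndarray
    prevalence: float


@dataclass
class ValidationReport:
    fold_accuracies: np.ndarray
    oof_probabilities: np.ndarray  # n x k
    classes: np.ndarray
    shuffled_accuracies: np.ndarray | None = None
    roc_curves: dict = field(default_factory=dict)
    pr_curves: dict = field(default_factory=dict)
    dca: dict = field(default_factory=dict)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=1))


def _as_matrix(features) -> np.ndarray:
    if isinstance(features, FeatureMatrix):
        return features.values
    if isinstance(features, pd.DataFrame):
        return features.to_numpy(dtype=float)
    return np.asarray(features, dtype=float)


def _robust_scale_train_apply(train, test):
    """Median/IQR scaling with parameters from the training fold only."""
    q1, med, q3 = np.percentile(train, [25, 50, 75], axis=0)
    iqr = q3 - q1
    divisor = np.where(iqr <= 0, 1.0, iqr)
    return (train - med) / divisor, (test - med) / divisor


def fit_cluster_classifier_cv(features, labels, n_folds=5, seed=0):
    """Stratified five-fold CV of a multinomial logistic regression.

    Features are scaled inside each training fold (median/IQR); the model
    is effectively unregularized (ridge 1e-8 for numerical stability).
    Returns ``(fold_accuracies, oof_probabilities, classes)`` where the
    out-of-fold probability matrix is n x k with rows summing to 1.
    """
    X = _as_matrix(features)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    counts = np.array([(y == c).sum() for c in classes])
    if counts.min() < n_folds:
        raise ValueError(f"smallest class has {counts.min()} members; cannot "
                         f"guarantee presence in every one of {n_folds} folds")

    oof = np.zeros((len(y), len(classes)))
    accs = []
    splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for train_idx, val_idx in splitter.split(X, y):
        Xtr, Xva = _robust_scale_train_apply(X[train_idx], X[val_idx])
        model = LogisticRegression(C=1e8, max_iter=2000, random_state=seed)
        model.fit(Xtr, y[train_idx])
        proba = model.predict_proba(Xva)
        # align model class order to the global class order
        order = np.searchsorted(classes, model.classes_)
        oof[np.ix_(val_idx, order)] = proba
        accs.append(float((model.predict(Xva) == y[val_idx]).mean()))
    return np.array(accs), oof, classes


def shuffled_baseline(features, labels, n_folds=5, seed=0, n_repeats=10):
    """Chance-level baseline: permute labels, rerun the identical CV.

    Returns the flat array of per-fold accuracies over all repeats.  For
    class proportions p_i the expected value converges to sum(p_i^2).
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes")
    rng = np.random.default_rng(seed)
    accs = []
    for _ in range(n_repeats):
        permuted = rng.permutation(y)
        fold_accs, _, _ = fit_cluster_classifier_cv(
            features, permuted, n_folds=n_folds,
            seed=int(rng.integers(0, 2**31 - 1)))
        accs.extend(fold_accs)
    return np.array(accs)


def roc_points(truth, score):
    """ROC as (fpr, tpr) over all score thresholds (sklearn convention)."""
    fpr, tpr, _ = roc_curve(truth, score)
    return fpr, tpr


def _pr_at_recall_grid(truth, score, recall_grid):
    """Interpolated precision at fixed recall values.

    Uses the upper envelope p(r) = max{precision at recall >= r}, which
    handles duplicate recall values (ties in the score) and yields the
    standard monotone interpolated PR curve.
    """
    from sklearn.metrics import precision_recall_curve

    prec, rec, _ = precision_recall_curve(truth, score)
    order = np.argsort(rec)
    rec, prec = rec[order], prec[order]
    envelope = np.maximum.accumulate(prec[::-1])[::-1]  # suffix max
    idx = np.searchsorted(rec, recall_grid, side="left").clip(0, len(rec) - 1)
    return envelope[idx]


def bootstrap_curves(oof_probabilities, labels, n_boot=1000, seed=0,
                     grid_size=101, min_class_size=10):
    """One-vs-rest ROC and PR curves per class with bootstrap 95% bands.

    Rows (participants) are resampled with replacement ``n_boot`` times;
    bands are pointwise 2.5/97.5 percentiles of TPR (on a fixed FPR grid)
    and precision (on a fixed recall grid).

    Returns ``(roc, pr)`` dicts keyed by class, each holding the fixed
    grid, the point estimate, the band, and the AUC point estimate with
    its bootstrap percentile interval.
    """
    P = np.asarray(oof_probabilities, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if P.shape != (len(y), len(classes)):
        raise ValueError("probability matrix shape does not match labels/classes")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    rng = np.random.default_rng(seed)
    fpr_grid = np.linspace(0, 1, grid_size)
    recall_grid = np.linspace(0, 1, grid_size)
    roc_out, pr_out = {}, {}
    n = len(y)
    boot_idx = rng.integers(0, n, size=(n_boot, n))
    for j, cl in enumerate(classes):
        truth = (y == cl).astype(int)
        if truth.sum() < min_class_size or (1 - truth).sum() < min_class_size:
            raise ValueError(f"class {cl} has fewer than {min_class_size} members "
                             "on one side; curves would be unstable")
        score = P[:, j]
        fpr, tpr, _ = roc_curve(truth, score)
        tpr_grid = np.interp(fpr_grid, fpr, tpr)
        prec_grid = _pr_at_recall_grid(truth, score, recall_grid)
        auroc = float(np.trapezoid(tpr_grid, fpr_grid))
        auprc = float(np.trapezoid(prec_grid, recall_grid))

        tprs = np.empty((n_boot, grid_size))
        precs = np.empty((n_boot, grid_size))
        aurocs = np.empty(n_boot)
        auprcs = np.empty(n_boot)
        for b in range(n_boot):
            idx = boot_idx[b]
            tb, sb = truth[idx], score[idx]
            if tb.min() == tb.max():  # resample lost one class: reuse estimate
                tprs[b], precs[b] = tpr_grid, prec_grid
                aurocs[b], auprcs[b] = auroc, auprc
                continue
            f, t, _ = roc_curve(tb, sb)
            tprs[b] = np.interp(fpr_grid, f, t)
            precs[b] = _pr_at_recall_grid(tb, sb, recall_grid)
            aurocs[b] = np.trapezoid(tprs[b], fpr_grid)
            auprcs[b] = np.trapezoid(precs[b], recall_grid)

        roc_out[int(cl)] = {
            "fpr": fpr_grid, "tpr": tpr_grid,
            "tpr_low": np.percentile(tprs, 2.5, axis=0),
            "tpr_high": np.percentile(tprs, 97.5, axis=0),
            "auroc": auroc,
            "auroc_ci": (float(np.percentile(aurocs, 2.5)),
                         float(np.percentile(aurocs, 97.5))),
        }
        pr_out[int(cl)] = {
            "recall": recall_grid, "precision": prec_grid,
            "precision_low": np.percentile(precs, 2.5, axis=0),
            "precision_high": np.percentile(precs, 97.5, axis=0),
            "auprc": auprc,
            "auprc_ci": (float(np.percentile(auprcs, 2.5)),
                         float(np.percentile(auprcs, 97.5))),
        }
    return roc_out, pr_out


def net_benefit(binary_truth, probability, pt) -> float:
    """Net benefit of classifying positive at probability >= pt.

    NB = TP/N - (FP/N) * pt/(1-pt).  Zero when nobody is predicted
    positive.
    """
    if not 0 < pt < 1:
        raise ValueError("threshold probability pt must be in (0, 1)")
    truth = np.asarray(binary_truth).astype(bool)
    prob = np.asarray(probability, dtype=float)
    if truth.shape != prob.shape:
        raise ValueError("truth and probability must be aligned")
    n = len(truth)
    pred = prob >= pt
    tp = np.sum(pred & truth)
    fp = np.sum(pred & ~truth)
    return float(tp / n - (fp / n) * pt / (1 - pt))


def treat_all_net_benefit(prevalence, pt):
    """Net benefit of treating everyone: pi - (1-pi) * pt/(1-pt)."""
    pt = np.asarray(pt, dtype=float)
    return prevalence - (1 - prevalence) * pt / (1 - pt)


def dca_curves(oof_probabilities, labels, thresholds=None, n_boot=1000, seed=0):
    """Decision-curve analysis, one-vs-rest per class.

    For each class, the model's net benefit across the threshold grid
    (default 0.01..0.99 step 0.01) with bootstrap percentile 95% CI, plus
    the treat-all curve (from class prevalence) and the treat-none
    reference (identically zero).
    """
    P = np.asarray(oof_probabilities, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if thresholds is None:
        thresholds = np.arange(0.01, 1.0, 0.01)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    rng = np.random.default_rng(seed)
    n = len(y)
    boot_idx = rng.integers(0, n, size=(n_boot, n))
    out = {}
    for j, cl in enumerate(classes):
        truth = (y == cl).astype(int)
        score = P[:, j]
        nb = np.array([net_benefit(truth, score, pt) for pt in thresholds])
        boot_nb = np.empty((n_boot, len(thresholds)))
        for b in range(n_boot):
            idx = boot_idx[b]
            boot_nb[b] = [net_benefit(truth[idx], score[idx], pt) for pt in thresholds]
        prevalence = float(truth.mean())
        out[int(cl)] = NetBenefitCurve(
            class_id=int(cl), thresholds=thresholds, net_benefit=nb,
            ci_low=np.percentile(boot_nb, 2.5, axis=0),
            ci_high=np.percentile(boot_nb, 97.5, axis=0),
            treat_all=treat_all_net_benefit(prevalence, thresholds),
            treat_none=np.zeros_like(thresholds),
            prevalence=prevalence,
        )
    return out


def validate_clusters(features, labels, n_folds=5, seed=0, n_boot=1000,
                      n_shuffle_repeats=10, thresholds=None) -> ValidationReport:
    """Full validation: CV accuracies, shuffled baseline, bootstrap ROC/PR,
    and DCA curves, from one pass of out-of-fold probabilities."""
    accs, oof, classes = fit_cluster_classifier_cv(features, labels,
                                                   n_folds=n_folds, seed=seed)
    shuffled = shuffled_baseline(features, labels, n_folds=n_folds, seed=seed,
                                 n_repeats=n_shuffle_repeats)
    roc, pr = bootstrap_curves(oof, labels, n_boot=n_boot, seed=seed)
    dca = dca_curves(oof, labels, thresholds=thresholds, n_boot=n_boot, seed=seed)
    return ValidationReport(fold_accuracies=accs, oof_probabilities=oof,
                            classes=classes, shuffled_accuracies=shuffled,
                            roc_curves=roc, pr_curves=pr, dca=dca)
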