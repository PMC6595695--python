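"""Clinical validation: impaired-vs-unimpaired classification per gait cluster.

The pipeline mirrors a standard small-cohort methodology: stratified 60/40
train/test split, random undersampling of the training majority class,
z-score standardization and training-median imputation (both fit on the
training set only), Fisher-score top-5 feature selection, an SVM tuned by
inner stratified 5-fold cross-validation over a C x gamma grid (gamma = 0
selects a linear kernel, gamma > 0 an RBF kernel) maximizing AUC, refit on
the full training set, and test-set ROC/AUC from continuous decision scores.

Baseline comparisons are paired: the same seed produces the same split for
every cluster and method.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.svm import SVC

from .core import GaitError, ParameterError, ValidationError

logger = logging.getLogger(__name__)

C_GRID = (0.01, 0.05, 0.1, 0.5, 1, 5, 10, 20, 30, 40, 50, 100)
GAMMA_GRID = (0, 0.01, 0.05, 0.1, 0.5, 1, 5, 10, 20, 40, 50, 100)


@dataclass
class ValidationConfig:
    target: str = "gait"  # or "postural_stability"
    train_fraction: float = 0.6
    top_k: int = 5
    c_grid: tuple = C_GRID
    gamma_grid: tuple = GAMMA_GRID
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ParameterError("train_fraction must be in (0, 1)")
        if not self.c_grid or not self.gamma_grid:
            raise ParameterError("hyperparameter grids must be non-empty")


@dataclass
class ValidationResult:
    cluster: str
    method: str
    target: str
    selected_features: list[str]
    best_c: float
    best_gamma: float
    cv_auc: float
    test_auc: float
    roc_points: np.ndarray  # (n, 2) array of (fpr, tpr)

    def __post_init__(self) -> None:
        if not (0.0 <= self.test_auc <= 1.0):
            raise ValidationError("AUC must be in [0, 1]")


def binarize_labels(scores) -> np.ndarray:
    """Impaired (1) iff the clinical sub-score is nonzero."""
    scores = np.asarray(scores)
    if np.any((scores < 0) | (scores > 4)):
        raise ValidationError("clinical scores must be in 0..4")
    return (scores > 0).astype(int)


def split_train_test(n: int, labels, train_fraction: float, seed: int):
    """Stratified random split; both classes stay represented on both sides."""
    labels = np.asarray(labels)
    if len(labels) != n:
        raise ValidationError("labels length mismatch")
    if len(np.unique(labels)) < 2:
        raise ValidationError("both classes must be present")
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for cls in np.unique(labels):
        members = np.flatnonzero(labels == cls)
        members = rng.permutation(members)
        k = int(round(train_fraction * len(members)))
        k = min(max(k, 1), len(members) - 1)
        train_idx.extend(members[:k])
        test_idx.extend(members[k:])
    return np.sort(np.array(train_idx)), np.sort(np.array(test_idx))


def balance_training(train_idx, labels, seed: int) -> np.ndarray:
    """Random undersampling of the majority class to the minority count."""
    train_idx = np.asarray(train_idx)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels[train_idx], return_counts=True)
    if len(classes) < 2:
        raise ValidationError("both classes must be present in the training set")
    n_min = counts.min()
    rng = np.random.default_rng(seed)
    kept = []
    for cls in classes:
        members = train_idx[labels[train_idx] == cls]
        if len(members) > n_min:
            members = rng.permutation(members)[:n_min]
        kept.extend(members)
    return np.sort(np.array(kept))


def fisher_score(feature_values, labels) -> float:
    """(mu1 - mu0)^2 / (s1^2 + s0^2) with sample variances (ddof=1)."""
    x = np.asarray(feature_values, dtype=float)
    y = np.asarray(labels)
    x0, x1 = x[y == 0], x[y == 1]
    if len(x0) < 2 or len(x1) < 2:
        raise ParameterError("both classes need >= 2 samples for the Fisher score")
    num = (x1.mean() - x0.mean()) ** 2
    den = x1.var(ddof=1) + x0.var(ddof=1)
    if den == 0:
        return float("inf") if num > 0 else 0.0
    return float(num / den)


def select_top_k(features: pd.DataFrame, labels, k: int = 5) -> list[str]:
    """Names of the k features with the highest Fisher scores.

    Missing values are imputed by the column median of the given (training)
    rows before scoring; ties at rank k break toward the earlier column."""
    labels = np.asarray(labels)
    filled = features.fillna(features.median())
    scores = []
    for j, col in enumerate(filled.columns):
        x = filled[col].to_numpy(float)
        if np.isnan(x).any():  # column entirely missing
            scores.append(-np.inf)
        else:
            scores.append(fisher_score(x, labels))
    order = sorted(range(len(scores)), key=lambda j: (-scores[j], j))
    if k > len(order):
        raise ParameterError("fewer features than k")
    return [filled.columns[j] for j in order[:k]]


def _stratified_folds(labels: np.ndarray, n_folds: int, rng: np.random.Generator):
    folds = [[] for _ in range(n_folds)]
    for cls in np.unique(labels):
        members = rng.permutation(np.flatnonzero(labels == cls))
        for i, m in enumerate(members):
            folds[i % n_folds].append(m)
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def _make_svm(c: float, gamma: float) -> SVC:
    if gamma == 0:
        return SVC(kernel="linear", C=c)
    return SVC(kernel="rbf", C=c, gamma=gamma)


def roc_auc(scores, labels) -> float:
    """AUC via the rank statistic with midrank tie handling."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n1 = int(np.sum(labels == 1))
    n0 = int(np.sum(labels == 0))
    if n1 == 0 or n0 == 0:
        raise ValidationError("both classes must be present for the ROC")
    ranks = rankdata(scores)  # midranks
    return float((np.sum(ranks[labels == 1]) - n1 * (n1 + 1) / 2) / (n1 * n0))


def roc_points(scores, labels) -> np.ndarray:
    """ROC curve as (fpr, tpr) points over all score thresholds."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    order = np.argsort(-scores, kind="stable")
    y = labels[order]
    tps = np.cumsum(y == 1)
    fps = np.cumsum(y == 0)
    # collapse tied thresholds
    distinct = np.flatnonzero(np.diff(scores[order]) != 0)
    idx = np.concatenate([distinct, [len(y) - 1]])
    tpr = tps[idx] / max(1, tps[-1])
    fpr = fps[idx] / max(1, fps[-1])
    return np.column_stack([np.concatenate([[0.0], fpr]), np.concatenate([[0.0], tpr])])


def tune_and_fit_svm(train_features: np.ndarray, train_labels, config: ValidationConfig):
    """Grid-search (C, gamma) by inner stratified CV on AUC; refit on all data.

    Returns ``(model, (best_c, best_gamma), cv_auc)``.  Features must already
    be standardized; folds with a single class are skipped with a warning."""
    x = np.asarray(train_features, dtype=float)
    y = np.asarray(train_labels)
    rng = np.random.default_rng(config.seed)
    folds = _stratified_folds(y, config.cv_folds, rng)
    splits = []
    for i in range(config.cv_folds):
        val_idx = folds[i]
        trn_idx = np.concatenate([folds[j] for j in range(config.cv_folds) if j != i])
        if len(val_idx) == 0 or len(np.unique(y[val_idx])) < 2 or len(np.unique(y[trn_idx])) < 2:
            logger.warning("skipping degenerate single-class CV fold %d", i)
            continue
        splits.append((trn_idx, val_idx))
    best = None
    for c in config.c_grid:
        for gamma in config.gamma_grid:
            aucs = []
            for trn_idx, val_idx in splits:
                model = _make_svm(c, gamma)
                model.fit(x[trn_idx], y[trn_idx])
                aucs.append(roc_auc(model.decision_function(x[val_idx]), y[val_idx]))
            mean_auc = float(np.mean(aucs)) if aucs else 0.0
            if best is None or mean_auc > best[0]:
                best = (mean_auc, c, gamma)
    cv_auc, best_c, best_gamma = best
    model = _make_svm(best_c, best_gamma)
    model.fit(x, y)
    return model, (best_c, best_gamma), cv_auc


def run_validation(
    features: pd.DataFrame,
    scores,
    cluster_name: str,
    method_name: str,
    config: ValidationConfig,
) -> ValidationResult:
    """Full chain: split, balance, standardize, select, tune, refit, test AUC.

    ``features`` is one row per subject (columns = cluster feature names);
    ``scores`` the clinical sub-scores.  Aborts when more than 20% of subjects
    have no features at all for the requested cluster."""
    labels = binarize_labels(scores)
    n = len(features)
    all_missing = features.isna().all(axis=1).to_numpy()
    if np.mean(all_missing) > 0.2:
        raise GaitError(
            f"cluster {cluster_name!r}: features missing for "
            f"{np.sum(all_missing)}/{n} subjects (> 20%)"
        )
    train_idx, test_idx = split_train_test(n, labels, config.train_fraction, config.seed)
    train_idx = balance_training(train_idx, labels, config.seed)

    train_df = features.iloc[train_idx]
    medians = train_df.median()
    train_filled = train_df.fillna(medians)
    test_filled = features.iloc[test_idx].fillna(medians)

    selected = select_top_k(train_df, labels[train_idx], config.top_k)
    mu = train_filled[selected].mean()
    sd = train_filled[selected].std(ddof=0).replace(0.0, 1.0)
    x_train = ((train_filled[selected] - mu) / sd).to_numpy(float)
    x_test = ((test_filled[selected] - mu) / sd).to_numpy(float)

    model, (best_c, best_gamma), cv_auc = tune_and_fit_svm(x_train, labels[train_idx], config)
    test_scores = model.decision_function(x_test)
    auc = roc_auc(test_scores, labels[test_idx])
    return ValidationResult(
        cluster=cluster_name,
        method=method_name,
        target=config.target,
        selected_features=selected,
        best_c=float(best_c),
        best_gamma=float(best_gamma),
        cv_auc=float(cv_auc),
        test_auc=float(auc),
        roc_points=roc_points(test_scores, labels[test_idx]),
    )
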