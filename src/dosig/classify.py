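"""RBF-SVM classification gate for candidate gene signatures.

The signature matrix is split 80/20 stratified by class, an RBF-kernel
SVM is tuned over a log10 grid of (gamma, C) by stratified 10-fold
cross-validation on the training set, and the refit model is accepted
only when, on the held-out test set, Cohen's kappa > 0.80, specificity
> 0.80, and an exact one-sided binomial test shows the accuracy beats
the no-information rate at p < 0.05. ROC-AUC and a PCA
variance-coverage check serve as diagnostics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .io import NORMAL, TUMOR


@dataclass
class TuneGrid:
    """Log10 grid over the RBF hyperparameters, one point per decade."""

    gammas: np.ndarray = field(default_factory=lambda: 10.0 ** np.arange(-6, 7))
    Cs: np.ndarray = field(default_factory=lambda: 10.0 ** np.arange(-5, 6))
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        self.gammas = np.asarray(self.gammas, dtype=float)
        self.Cs = np.asarray(self.Cs, dtype=float)
        if (self.gammas <= 0).any() or (self.Cs <= 0).any():
            raise ValueError("grid values must be positive")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class ClassifierReport:
    """Confusion counts (tumor = positive) and the derived acceptance gates."""

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    kappa: float
    nir: float
    p_acc_vs_nir: float
    best_gamma: float
    best_C: float
    accepted: bool

    def to_dict(self) -> dict:
        return {
            "confusion": {"TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn},
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "kappa": self.kappa,
            "nir": self.nir,
            "p_acc_vs_nir": self.p_acc_vs_nir,
            "best_gamma": self.best_gamma,
            "best_C": self.best_C,
            "accepted": self.accepted,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


def stratified_split(labels, train_frac: float = 0.8, seed: int = 0):
    """Per-class randomized split; train size is round(frac * class size).

    ``labels`` is a pandas Series indexed by sample id; returns
    (train_ids, test_ids) as lists, reproducible for a fixed seed.
    """
    labels = pd.Series(labels)
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train: list = []
    test: list = []
    for cls in sorted(labels.unique()):
        ids = list(labels.index[labels == cls])
        if len(ids) < 5:
            raise ValueError(f"class {cls!r} has {len(ids)} samples; need >= 5")
        n_train = int(round(train_frac * len(ids)))
        perm = rng.permutation(len(ids))
        train.extend(ids[i] for i in perm[:n_train])
        test.extend(ids[i] for i in perm[n_train:])
    return train, test


def make_rbf_svm(gamma: float, C: float) -> Pipeline:
    """Standardized RBF-SVM (train-set mean/SD scaling before the kernel)."""
    return Pipeline(
        [("scale", StandardScaler()), ("svm", SVC(kernel="rbf", gamma=gamma, C=C))]
    )


def tune_rbf_svm(X_train, y_train, grid: TuneGrid | None = None):
    """Grid search by mean stratified-CV accuracy.

    Returns (best_gamma, best_C, cv_accuracy); ties break toward the
    smaller C, then the smaller gamma.
    """
    grid = grid or TuneGrid()
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("training data contains a single class")
    if counts.min() < grid.cv_folds:
        raise ValueError(
            f"need >= {grid.cv_folds} samples per class for {grid.cv_folds}-fold CV"
        )
    skf = StratifiedKFold(n_splits=grid.cv_folds, shuffle=True, random_state=grid.seed)
    folds = list(skf.split(X, y))

    best = None  # (acc, C, gamma)
    for C in sorted(grid.Cs):
        for gamma in sorted(grid.gammas):
            correct = 0
            total = 0
            for tr, te in folds:
                model = make_rbf_svm(gamma, C)
                model.fit(X[tr], y[tr])
                correct += int((model.predict(X[te]) == y[te]).sum())
                total += len(te)
            acc = correct / total
            if best is None or acc > best[0] + 1e-12:
                best = (acc, C, gamma)
    cv_acc, best_C, best_gamma = best
    return float(best_gamma), float(best_C), float(cv_acc)


def cohens_kappa(tp: int, fp: int, tn: int, fn: int) -> float:
    """Chance-corrected agreement from raw confusion counts."""
    total = tp + fp + tn + fn
    p_o = (tp + tn) / total
    p_pos = ((tp + fn) / total) * ((tp + fp) / total)
    p_neg = ((tn + fp) / total) * ((tn + fn) / total)
    p_e = p_pos + p_neg
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


def evaluate_classifier(
    model,
    X_test,
    y_test,
    kappa_cut: float = 0.8,
    spec_cut: float = 0.8,
    p_cut: float = 0.05,
    best_gamma: float = float("nan"),
    best_C: float = float("nan"),
) -> ClassifierReport:
    """Held-out confusion matrix, kappa/specificity/NIR gates."""
    X = np.asarray(X_test, dtype=float)
    y = np.asarray(y_test)
    if np.unique(y).size < 2:
        raise ValueError("test set contains a single class")
    pred = model.predict(X)
    tp = int(((pred == TUMOR) & (y == TUMOR)).sum())
    fp = int(((pred == TUMOR) & (y == NORMAL)).sum())
    tn = int(((pred == NORMAL) & (y == NORMAL)).sum())
    fn = int(((pred == NORMAL) & (y == TUMOR)).sum())
    total = tp + fp + tn + fn
    accuracy = (tp + tn) / total
    sensitivity = tp / (tp + fn)
    specificity = tn / (tn + fp)
    kappa = cohens_kappa(tp, fp, tn, fn)
    nir = max((y == TUMOR).mean(), (y == NORMAL).mean())
    correct = tp + tn
    # exact one-sided binomial upper tail P(X >= correct | n, NIR)
    p_acc = float(stats.binom.sf(correct - 1, total, nir))
    accepted = (kappa > kappa_cut) and (specificity > spec_cut) and (p_acc < p_cut)
    return ClassifierReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=accuracy, sensitivity=sensitivity, specificity=specificity,
        kappa=kappa, nir=float(nir), p_acc_vs_nir=p_acc,
        best_gamma=float(best_gamma), best_C=float(best_C), accepted=bool(accepted),
    )


def roc_auc(scores, y) -> float:
    """Rank-based AUC (midranks for ties); tumor is the positive class."""
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("both classes required for ROC analysis")
    return float(roc_auc_score((y == TUMOR).astype(int), np.asarray(scores, dtype=float)))


def pca_variance_check(X, k: int) -> float:
    """Cumulative fraction of total variance in the top-k principal components."""
    X = np.asarray(X, dtype=float)
    centered = X - X.mean(axis=0)
    total = float((centered ** 2).sum())
    if total <= 0:
        raise ValueError("zero total variance")
    max_rank = min(X.shape[0], X.shape[1])
    if not 1 <= k <= max_rank:
        raise ValueError(f"k must lie in [1, {max_rank}]")
    pca = PCA(n_components=min(k, max_rank)).fit(X)
    return float(pca.explained_variance_ratio_[:k].sum())
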