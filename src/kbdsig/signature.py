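"""Gene-signature identification: linear soft-margin SVM classification with a
leave-one-out wrapper that re-runs feature selection inside every fold.

The wrapper reproduces the signature-search protocol of the study design: for
each of the N training samples, hold it out, build the differential feature
pool and the mRMR ranking from the remaining N-1 samples only, then for every
signature size n = 1..n_max train a linear SVM on the top-n genes and predict
the held-out sample. LOOCV accuracy at size n is the fraction of correct
held-out predictions, and exactly N x n_max SVM models are built. The held-out
sample never touches pool construction, discretization thresholds, feature
scaling, or cost selection.

The per-fold feature pool is a Welch-t Bonferroni screen of the fold's
training samples (case vs control per gene), topped up with the next most
significant genes when fewer than n_max pass, so every fold ranks exactly
min(n_max, n_genes) genes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .metrics import ConfusionTable
from .mrmr import discretize, select_mrmr

__all__ = [
    "SvmModel",
    "SignatureCurve",
    "train_svm",
    "grid_search_c",
    "loocv_size_sweep",
    "finalize_signature",
    "evaluate",
    "DEFAULT_C_GRID",
]

logger = logging.getLogger(__name__)

#: C-SVC cost grid, powers of two from 2^-5 to 2^15
DEFAULT_C_GRID: Tuple[float, ...] = tuple(2.0 ** k for k in range(-5, 16, 2))

_SCALE_FLOOR = 1e-8


@dataclass
class SvmModel:
    """A trained linear C-SVC on z-scored features.

    decision(x) = w . (x - center) / scale + b; predictions are the positive
    class for a positive decision value.
    """

    weights: np.ndarray
    bias: float
    cost_c: float
    center: np.ndarray
    scale: np.ndarray
    genes: List[str]
    positive_label: object
    negative_label: object

    def decision_values(self, X) -> np.ndarray:
        X = self._as_matrix(X)
        Xs = (X - self.center) / self.scale
        return Xs @ self.weights + self.bias

    def predict(self, X) -> np.ndarray:
        d = self.decision_values(X)
        return np.where(d > 0, self.positive_label, self.negative_label)

    def _as_matrix(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [g for g in self.genes if g not in X.columns]
            if missing:
                raise KeyError(f"test data missing model gene(s): {missing}")
            X = X[self.genes]
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(self.genes):
            raise ValueError(f"expected {len(self.genes)} features, got {X.shape[1]}")
        return X


@dataclass
class SignatureCurve:
    """LOOCV accuracy as a function of signature size."""

    accuracy_by_n: Dict[int, float]
    per_fold_selections: List[List[str]]
    models_built: int
    pool_sizes: List[int] = field(default_factory=list)

    def selection_frequencies(self, n: Optional[int] = None) -> pd.Series:
        """How often each gene appears among the top-n per-fold selections."""
        counts: Dict[str, int] = {}
        for sel in self.per_fold_selections:
            for g in (sel if n is None else sel[:n]):
                counts[g] = counts.get(g, 0) + 1
        s = pd.Series(counts, dtype=float) / len(self.per_fold_selections)
        return s.sort_values(ascending=False)


def _labels_to_binary(y, positive: Optional[object] = None):
    y = np.asarray(y)
    classes = sorted(pd.unique(y).tolist(), key=str)
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {classes}")
    if positive is None:
        positive = "case" if "case" in classes else classes[-1]
    if positive not in classes:
        raise ValueError(f"positive label {positive!r} not among classes {classes}")
    negative = classes[0] if classes[1] == positive else classes[1]
    return (y == positive).astype(int), positive, negative


def train_svm(X, y, cost_c: float = 0.5, positive: Optional[object] = None) -> SvmModel:
    """Fit a linear soft-margin SVM (C-SVC) on z-scored features.

    Centering and scaling are learned from ``X`` only; scales are floored to
    avoid division by zero on constant features.
    """
    if cost_c <= 0:
        raise ValueError("cost_c must be positive")
    genes = list(X.columns) if isinstance(X, pd.DataFrame) else [f"x{i}" for i in range(np.shape(X)[1])]
    Xv = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(Xv)):
        raise ValueError("X must contain no missing values")
    yb, pos, neg = _labels_to_binary(y, positive)
    center = Xv.mean(axis=0)
    scale = np.maximum(Xv.std(axis=0, ddof=0), _SCALE_FLOOR)
    svc = SVC(kernel="linear", C=cost_c)
    svc.fit((Xv - center) / scale, yb)
    return SvmModel(
        weights=svc.coef_[0].copy(),
        bias=float(svc.intercept_[0]),
        cost_c=cost_c,
        center=center,
        scale=scale,
        genes=genes,
        positive_label=pos,
        negative_label=neg,
    )


def grid_search_c(
    X, y, grid: Sequence[float] = DEFAULT_C_GRID, folds: int = 5, seed: int = 0,
    positive: Optional[object] = None,
) -> float:
    """Pick the cost C maximizing mean stratified-CV accuracy; ties go to the
    smallest C (the simpler model). Fold assignment is seeded."""
    grid = list(grid)
    if not grid:
        raise ValueError("grid must be non-empty")
    if len(grid) == 1:
        return float(grid[0])
    Xv = np.asarray(X, dtype=float)
    yb, pos, neg = _labels_to_binary(y, positive)
    y_arr = np.asarray(y)
    folds = min(folds, int(np.bincount(yb).min()))
    if folds < 2:
        raise ValueError("too few samples per class for cross-validated grid search")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    cols = list(X.columns) if isinstance(X, pd.DataFrame) else None
    mean_acc = []
    for c in grid:
        accs = []
        for tr, te in skf.split(Xv, yb):
            Xtr = pd.DataFrame(Xv[tr], columns=cols) if cols else Xv[tr]
            model = train_svm(Xtr, y_arr[tr], cost_c=c, positive=pos)
            Xte = pd.DataFrame(Xv[te], columns=cols) if cols else Xv[te]
            accs.append(np.mean(model.predict(Xte) == y_arr[te]))
        mean_acc.append(np.mean(accs))
    mean_acc = np.asarray(mean_acc)
    best = mean_acc.max()
    candidates = [c for c, a in zip(grid, mean_acc) if a >= best - 1e-12]
    choice = float(min(candidates))
    logger.info("grid search over %d values: C=%g (mean CV accuracy %.4f)",
                len(grid), choice, best)
    return choice


def _feature_pool(
    X: pd.DataFrame, yb: np.ndarray, n_max: int, alpha: float = 0.05
) -> List[str]:
    """Bonferroni Welch-t screen with significance-ordered top-up to n_max."""
    case = X.to_numpy(dtype=float)[yb == 1]
    ctrl = X.to_numpy(dtype=float)[yb == 0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(case, ctrl, axis=0, equal_var=False)
    p = np.nan_to_num(np.asarray(res.pvalue, dtype=float), nan=1.0)
    order = np.argsort(p, kind="stable")
    n_pass = int(np.sum(p * X.shape[1] < alpha))
    pool_size = min(X.shape[1], max(n_pass, n_max))
    return [X.columns[i] for i in order[:pool_size]]


def loocv_size_sweep(
    matrix: pd.DataFrame,
    labels,
    n_max: int = 50,
    de_first: bool = True,
    alpha: float = 0.05,
    k_sigma: float = 1.0,
    criterion: str = "MID",
    cost_c: float = 0.5,
) -> SignatureCurve:
    """Leave-one-out signature-size sweep with per-fold re-selection.

    Parameters
    ----------
    matrix : samples x genes DataFrame of per-sample log2 expression.
    labels : per-sample class labels ("case"/"control" or any two values).
    de_first : screen the fold's training samples for differential genes and
        rank only within that pool (topped up to ``n_max``); otherwise the
        pool is the whole panel.
    cost_c : fixed SVM cost used inside the sweep.
    """
    n_samples, n_genes = matrix.shape
    if n_samples < 3:
        raise ValueError("need at least 3 samples")
    if not 1 <= n_max <= n_genes:
        raise ValueError(f"n_max must be in 1..{n_genes}")
    y = np.asarray(labels)
    yb_all, pos, neg = _labels_to_binary(y)

    correct = np.zeros(n_max, dtype=int)
    counted = np.zeros(n_max, dtype=int)
    models_built = 0
    per_fold_selections: List[List[str]] = []
    pool_sizes: List[int] = []

    for i in range(n_samples):
        tr_mask = np.ones(n_samples, dtype=bool)
        tr_mask[i] = False
        Xtr = matrix.iloc[tr_mask]
        ytr = y[tr_mask]
        ybtr = yb_all[tr_mask]
        if ybtr.min() == ybtr.max():
            raise ValueError("a fold lost one class entirely; labels too unbalanced for LOOCV")
        pool = _feature_pool(Xtr, ybtr, n_max, alpha) if de_first else list(matrix.columns)
        pool_sizes.append(len(pool))
        depth = min(n_max, len(pool))
        if depth < n_max:
            warnings.warn(
                f"fold {i}: pool has only {len(pool)} genes; sweep truncated at n={depth}",
                stacklevel=2,
            )
        disc = discretize(Xtr[pool], k_sigma=k_sigma)
        ranking = select_mrmr(disc, n=depth, criterion=criterion, labels=ytr)
        ranked_genes = ranking.gene_names
        per_fold_selections.append(ranked_genes)
        x_heldout = matrix.iloc[[i]]
        y_heldout = y[i]
        for n in range(1, depth + 1):
            feats = ranked_genes[:n]
            model = train_svm(Xtr[feats], ytr, cost_c=cost_c, positive=pos)
            pred = model.predict(x_heldout[feats])[0]
            models_built += 1
            counted[n - 1] += 1
            if pred == y_heldout:
                correct[n - 1] += 1

    accuracy_by_n = {
        n: correct[n - 1] / counted[n - 1] for n in range(1, n_max + 1) if counted[n - 1] > 0
    }
    return SignatureCurve(
        accuracy_by_n=accuracy_by_n,
        per_fold_selections=per_fold_selections,
        models_built=models_built,
        pool_sizes=pool_sizes,
    )


def finalize_signature(
    matrix: pd.DataFrame,
    labels,
    n: int = 20,
    de_first: bool = True,
    alpha: float = 0.05,
    k_sigma: float = 1.0,
    criterion: str = "MID",
    c_grid: Optional[Sequence[float]] = DEFAULT_C_GRID,
    cost_c: float = 0.5,
    seed: int = 0,
) -> Tuple[List[str], SvmModel]:
    """Fit the final signature model: mRMR once on the full training set, take
    the top-n genes, grid-search the cost C (5-fold, seeded) and train the SVM.

    Per-fold selection frequencies for transparency come from
    ``SignatureCurve.selection_frequencies`` of a prior sweep.
    """
    y = np.asarray(labels)
    yb, pos, neg = _labels_to_binary(y)
    pool = _feature_pool(matrix, yb, max(n, 1), alpha) if de_first else list(matrix.columns)
    if n > len(pool):
        raise ValueError(f"requested signature size {n} exceeds pool size {len(pool)}")
    disc = discretize(matrix[pool], k_sigma=k_sigma)
    ranking = select_mrmr(disc, n=n, criterion=criterion, labels=y)
    genes = ranking.gene_names
    c = grid_search_c(matrix[genes], y, grid=c_grid, seed=seed, positive=pos) if c_grid else cost_c
    model = train_svm(matrix[genes], y, cost_c=c, positive=pos)
    return genes, model


def evaluate(model: SvmModel, X_test, y_test) -> ConfusionTable:
    """Confusion table of the model on an independent test set; the model's
    positive (case) label is the positive class. Missing model genes in the
    test data raise rather than being imputed."""
    preds = model.predict(X_test)
    return ConfusionTable.from_predictions(np.asarray(y_test), preds, positive=model.positive_label)
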