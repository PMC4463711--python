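"""Bayes (linear) discriminant analysis of disease degree.

Classifies KBD patients into severity degree I vs II from the log2 expression
ratios of the signature genes. Both classes share a pooled within-class
covariance (Gaussian model with equal covariances), so the decision rule is
linear: assign the class maximizing Gaussian density x prior. "Original"
accuracy is resubstitution (fit on all cases, classify all); "cross-validated"
is leave-one-out (each case classified by a model fit on all other cases).

Priors default to equal, matching the balanced 50/50 degree design;
"proportional" uses the observed class frequencies. A ridge term
lambda * trace(S)/p * I is added to the pooled covariance only if its Cholesky
factorization fails, and the lambda used is recorded on the model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import linalg

from .metrics import ConfusionTable

__all__ = ["BdaModel", "fit_bda", "classify_bda", "loocv_bda", "format_table2"]

logger = logging.getLogger(__name__)


@dataclass
class BdaModel:
    classes: List[str]
    class_means: np.ndarray          # k x p
    pooled_covariance: np.ndarray    # p x p
    priors: np.ndarray               # k, sums to 1
    genes: List[str]
    ridge_lambda: float = 0.0
    _chol: Optional[np.ndarray] = None  # lower Cholesky factor, cached

    def log_posteriors(self, x) -> np.ndarray:
        """Unnormalized log posterior per class for one observation or a
        matrix of observations (rows)."""
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        if single:
            x = x[None, :]
        if x.shape[1] != len(self.genes):
            raise ValueError(f"expected {len(self.genes)} features, got {x.shape[1]}")
        out = np.empty((x.shape[0], len(self.classes)))
        for k in range(len(self.classes)):
            diff = x - self.class_means[k]
            z = linalg.solve_triangular(self._chol, diff.T, lower=True)
            maha = np.sum(z ** 2, axis=0)
            out[:, k] = -0.5 * maha + np.log(self.priors[k])
        return out[0] if single else out


def _chol_with_ridge(cov: np.ndarray) -> Tuple[np.ndarray, float]:
    p = cov.shape[0]
    lam = 0.0
    trace_scale = np.trace(cov) / p if np.trace(cov) > 0 else 1.0
    for attempt in range(12):
        try:
            L = linalg.cholesky(cov + lam * trace_scale * np.eye(p), lower=True)
            return L, lam
        except linalg.LinAlgError:
            lam = 1e-8 if lam == 0.0 else lam * 10.0
    raise linalg.LinAlgError("pooled covariance could not be regularized")


def fit_bda(X, degrees, priors: str = "equal") -> BdaModel:
    """Fit the pooled-covariance Gaussian discriminant.

    Parameters
    ----------
    X : cases x genes DataFrame (or array) of log2 expression ratios.
    degrees : per-case class labels; exactly two classes, each with >= 2 cases.
    priors : "equal" or "proportional".
    """
    if priors not in ("equal", "proportional"):
        raise ValueError("priors must be 'equal' or 'proportional'")
    genes = list(X.columns) if isinstance(X, pd.DataFrame) else [f"x{i}" for i in range(np.shape(X)[1])]
    Xv = np.asarray(X, dtype=float)
    y = np.asarray(degrees)
    classes = sorted(pd.unique(y).tolist(), key=str)
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {classes}")
    counts = np.array([np.sum(y == c) for c in classes])
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 cases")
    means = np.vstack([Xv[y == c].mean(axis=0) for c in classes])
    n, p = Xv.shape
    pooled = np.zeros((p, p))
    for c, m in zip(classes, means):
        d = Xv[y == c] - m
        pooled += d.T @ d
    pooled /= n - len(classes)
    pooled = (pooled + pooled.T) / 2.0
    L, lam = _chol_with_ridge(pooled)
    if lam > 0:
        logger.info("pooled covariance regularized with ridge lambda=%g", lam)
        pooled = pooled + lam * (np.trace(pooled) / p) * np.eye(p)
    pr = np.full(2, 0.5) if priors == "equal" else counts / counts.sum()
    return BdaModel(classes=[str(c) for c in classes], class_means=means,
                    pooled_covariance=pooled, priors=pr, genes=genes,
                    ridge_lambda=lam, _chol=L)


def classify_bda(model: BdaModel, x) -> Tuple[str, np.ndarray]:
    """Classify one observation; returns (class, posterior per class).

    Posteriors are normalized Gaussian-density x prior; an exact tie goes to
    the first class (degree I).
    """
    if isinstance(x, pd.Series):
        x = x.reindex(model.genes).to_numpy()
    lp = model.log_posteriors(np.asarray(x, dtype=float))
    if lp.ndim != 1:
        raise ValueError("classify_bda takes a single observation")
    post = np.exp(lp - lp.max())
    post = post / post.sum()
    # argmax breaks exact ties toward the first (degree I) class
    return model.classes[int(np.argmax(post))], post


def _predict_all(model: BdaModel, Xv: np.ndarray) -> np.ndarray:
    lp = model.log_posteriors(Xv)
    return np.asarray(model.classes, dtype=object)[np.argmax(lp, axis=1)]


def loocv_bda(X, degrees, priors: str = "equal") -> Tuple[ConfusionTable, ConfusionTable]:
    """Resubstitution and leave-one-out degree confusion tables.

    Returns (original, cross_validated) with degree I as the positive class,
    i.e. tp = degree-I cases classified I, tn = degree-II cases classified II.
    """
    Xv = np.asarray(X, dtype=float)
    y = np.asarray(degrees)
    model = fit_bda(X, degrees, priors=priors)
    first = model.classes[0]
    original = ConfusionTable.from_predictions(
        y.astype(str), _predict_all(model, Xv), positive=first
    )
    preds = np.empty(len(y), dtype=object)
    for i in range(len(y)):
        mask = np.ones(len(y), dtype=bool)
        mask[i] = False
        m_i = fit_bda(Xv[mask], y[mask], priors=priors)
        preds[i], _ = classify_bda(m_i, Xv[i])
    cross_validated = ConfusionTable.from_predictions(y.astype(str), preds, positive=first)
    return original, cross_validated


def format_table2(original: ConfusionTable, cross_validated: ConfusionTable,
                  classes: Sequence[str] = ("Degree I", "Degree II")) -> str:
    """Render the degree-classification results as a counts + row-percentage
    report with resubstitution and cross-validated blocks."""
    a, b = classes

    def block(name: str, ct: ConfusionTable) -> List[str]:
        rows = [(a, ct.tp, ct.fn), (b, ct.fp, ct.tn)]
        lines = [f"{name}"]
        lines.append(f"  Count\t\t{a}\t{b}\tTotal")
        for label, x, y in rows:
            lines.append(f"  \t{label}\t{x}\t{y}\t{x + y}")
        lines.append(f"  %\t\t{a}\t{b}\tTotal")
        for label, x, y in rows:
            tot = x + y
            lines.append(f"  \t{label}\t{100 * x / tot:.1f}\t{100 * y / tot:.1f}\t100.0")
        return lines

    lines = ["Diagnosed Group\tPredicted Group Membership"]
    lines += block("Original", original)
    lines += block("Cross-validated", cross_validated)
    lines.append(f"{100 * original.accuracy:.1f}% of original grouped cases correctly classified; "
                 f"{100 * cross_validated.accuracy:.1f}% of cross-validated grouped cases "
                 "correctly classified.")
    return "\n".join(lines) + "\n"
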