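"""Minimum-redundancy maximum-relevance (mRMR) gene ranking.

Expression values are first discretized gene-wise into three states around the
gene's own mean (below mu - k*sigma, within, above mu + k*sigma), the scheme of
the original mRMR methodology for microarray data. Relevance and redundancy
are plug-in empirical mutual information in bits. Selection is greedy: the
first gene maximizes relevance I(gene; label); each subsequent step maximizes

    MID:  I(g; label) - mean_{s in S} I(g; s)
    MIQ:  I(g; label) / max(mean_{s in S} I(g; s), eps)

over the not-yet-selected genes, where S is the selected set. Ties break to
the lower gene index, making the ranking fully deterministic.

The plug-in MI estimator carries the usual positive small-sample bias; no
bias correction is applied (none is in the underlying methodology). This is
immaterial for ranking, which only compares estimates on a common sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "DiscretizedMatrix",
    "MrmrRanking",
    "discretize",
    "mutual_information",
    "select_mrmr",
]

_MIQ_EPS = 1e-12


@dataclass
class DiscretizedMatrix:
    """Three-state discretized expression with optional class labels.

    states : samples x genes int8 array with values in {-1, 0, +1}.
    labels : optional per-sample class labels (any hashable values).
    thresholds : genes x 2 array of (low, high) cut points used per gene.
    """

    states: np.ndarray
    genes: List[str]
    thresholds: np.ndarray
    labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if not np.isin(self.states, (-1, 0, 1)).all():
            raise ValueError("states must be in {-1, 0, +1}")
        if self.states.shape[1] != len(self.genes):
            raise ValueError("genes must match the state matrix width")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != self.states.shape[0]:
                raise ValueError("labels must have one entry per sample")


def discretize(
    matrix: pd.DataFrame, k_sigma: float = 1.0, labels: Optional[Sequence] = None
) -> DiscretizedMatrix:
    """Discretize log2 expression gene-wise into {-1, 0, +1} at mu +/- k*sigma.

    ``matrix`` is samples x genes of finite reals (log2 ratios or log2
    intensities). Constant genes map to all-zero states with a warning.
    """
    if k_sigma <= 0:
        raise ValueError("k_sigma must be positive")
    values = matrix.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("matrix must be finite")
    mu = values.mean(axis=0)
    sd = values.std(axis=0, ddof=0)
    constant = sd == 0
    if constant.any():
        names = [g for g, c in zip(matrix.columns, constant) if c]
        warnings.warn(f"constant gene(s) map to all-zero states: {names}", stacklevel=2)
    lo = mu - k_sigma * sd
    hi = mu + k_sigma * sd
    states = np.zeros(values.shape, dtype=np.int8)
    states[values < lo] = -1
    states[values > hi] = 1
    states[:, constant] = 0
    return DiscretizedMatrix(
        states=states,
        genes=list(matrix.columns),
        thresholds=np.column_stack([lo, hi]),
        labels=None if labels is None else np.asarray(labels),
    )


def _mi_from_codes(x: np.ndarray, y: np.ndarray, nx: int, ny: int) -> float:
    """Plug-in MI in bits from small nonnegative integer codes."""
    joint = np.bincount(x * ny + y, minlength=nx * ny).astype(float).reshape(nx, ny)
    n = joint.sum()
    pxy = joint / n
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    return float(np.sum(pxy[nz] * np.log2(pxy[nz] / (px @ py)[nz])))


def mutual_information(x: Sequence, y: Sequence) -> float:
    """Empirical mutual information I(X;Y) in bits between two discrete
    sequences; zero-count cells contribute nothing, so MI >= 0 and is
    symmetric in its arguments."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D sequences of equal length")
    if x.size == 0:
        raise ValueError("sequences must be non-empty")
    xc, xu = pd.factorize(x)
    yc, yu = pd.factorize(y)
    return _mi_from_codes(xc, yc, len(xu), len(yu))


@dataclass
class MrmrRanking:
    ordered_genes: List[int]       # gene indices into the discretized matrix
    gene_names: List[str]
    scores: List[float]            # criterion value at each greedy step
    relevance: np.ndarray          # I(gene; label) for every gene
    criterion: str


def select_mrmr(
    disc: DiscretizedMatrix,
    n: int,
    criterion: str = "MID",
    labels: Optional[Sequence] = None,
) -> MrmrRanking:
    """Greedy mRMR ranking of ``n`` genes against the class label.

    ``labels`` overrides ``disc.labels`` when given; both classes must be
    present. Ties at any step resolve to the lower gene index.
    """
    if criterion not in ("MID", "MIQ"):
        raise ValueError(f"criterion must be 'MID' or 'MIQ', got {criterion!r}")
    y = np.asarray(labels) if labels is not None else disc.labels
    if y is None:
        raise ValueError("class labels are required (labels= or disc.labels)")
    if len(y) != disc.states.shape[0]:
        raise ValueError("labels must have one entry per sample")
    classes = pd.unique(y)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    n_genes = disc.states.shape[1]
    if not 1 <= n <= n_genes:
        raise ValueError(f"n must be in 1..{n_genes}, got {n}")

    codes = (disc.states + 1).astype(np.intp)        # {0,1,2}
    yc = pd.factorize(y)[0].astype(np.intp)
    ny = len(classes)
    relevance = np.array(
        [_mi_from_codes(codes[:, g], yc, 3, ny) for g in range(n_genes)]
    )
    if np.all(relevance == 0):
        warnings.warn("all genes have zero relevance; ranking falls back to index order",
                      stacklevel=2)

    selected: List[int] = []
    scores: List[float] = []
    red_sum = np.zeros(n_genes)
    available = np.ones(n_genes, dtype=bool)
    for step in range(n):
        if step == 0:
            crit = relevance.copy()
        else:
            mean_red = red_sum / len(selected)
            if criterion == "MID":
                crit = relevance - mean_red
            else:
                crit = relevance / np.maximum(mean_red, _MIQ_EPS)
        crit[~available] = -np.inf
        pick = int(np.argmax(crit))  # argmax returns the first (lowest) index on ties
        selected.append(pick)
        scores.append(float(crit[pick]))
        available[pick] = False
        if step < n - 1:
            xp = codes[:, pick]
            for g in np.flatnonzero(available):
                red_sum[g] += _mi_from_codes(xp, codes[:, g], 3, 3)
    return MrmrRanking(
        ordered_genes=selected,
        gene_names=[disc.genes[g] for g in selected],
        scores=scores,
        relevance=relevance,
        criterion=criterion,
    )
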