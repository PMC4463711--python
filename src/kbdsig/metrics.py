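"""Binary-classification confusion counts and derived diagnostic metrics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ConfusionTable"]


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 confusion counts with the case group as the positive class.

    ``tp``/``fn`` partition the true cases, ``tn``/``fp`` the true controls.
    Derived rates follow the usual diagnostic definitions: accuracy is the
    overall correct fraction, sensitivity the true-positive rate among cases,
    specificity the true-negative rate among controls.
    """

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "tn", "fp"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"count {name!r} must be a nonnegative integer, got {v}")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total if self.total else float("nan")

    @property
    def sensitivity(self) -> float:
        pos = self.tp + self.fn
        return self.tp / pos if pos else float("nan")

    @property
    def specificity(self) -> float:
        neg = self.tn + self.fp
        return self.tn / neg if neg else float("nan")

    @classmethod
    def from_predictions(cls, y_true, y_pred, positive) -> "ConfusionTable":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        if y_true.shape != y_pred.shape:
            raise ValueError("y_true and y_pred must have the same length")
        pos_t = y_true == positive
        pos_p = y_pred == positive
        return cls(
            tp=int(np.sum(pos_t & pos_p)),
            fn=int(np.sum(pos_t & ~pos_p)),
            tn=int(np.sum(~pos_t & ~pos_p)),
            fp=int(np.sum(~pos_t & pos_p)),
        )

    @classmethod
    def from_rates(cls, sensitivity: float, specificity: float,
                   n_cases: int, n_controls: int) -> "ConfusionTable":
        """Reconstruct integer counts from sensitivity/specificity and group sizes.

        Raises if the rates are not attainable as exact count fractions.
        """
        tp = sensitivity * n_cases
        tn = specificity * n_controls
        if abs(tp - round(tp)) > 1e-9 or abs(tn - round(tn)) > 1e-9:
            raise ValueError("rates do not correspond to integer counts for these group sizes")
        tp, tn = int(round(tp)), int(round(tn))
        return cls(tp=tp, fn=n_cases - tp, tn=tn, fp=n_controls - tn)
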