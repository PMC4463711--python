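"""Orthogonal validation statistics: 2^-ddCt qPCR quantification, rank-sum
testing, and age-association checks for a candidate gene signature.

The qPCR side implements the comparative-threshold-cycle method: per sample,
dCt = Ct(target) - Ct(housekeeping gene); ddCt is the difference of group-mean
dCt values (case minus control) and the relative fold change is 2^-ddCt. No
amplification-efficiency correction is applied (plain 2^-ddCt).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CtTable",
    "RankSumResult",
    "ddct_fold_change",
    "rank_sum_test",
    "age_association",
]

#: soft plausibility window for qPCR threshold cycles
_CT_SOFT_RANGE = (10.0, 40.0)


@dataclass
class CtTable:
    """Long-format qPCR threshold-cycle table.

    ``data`` columns: sample_id, group ("case" | "control"), gene, ct.
    Technical replicates may appear as repeated (sample, gene) rows; they are
    averaged before any dCt computation.
    """

    data: pd.DataFrame
    housekeeping: str = "ACTB"  # beta-actin

    def __post_init__(self) -> None:
        required = {"sample_id", "group", "gene", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"CtTable missing columns: {sorted(missing)}")
        ct = self.data["ct"].to_numpy(dtype=float)
        if not np.all(np.isfinite(ct)):
            raise ValueError("Ct values must be finite")
        lo, hi = _CT_SOFT_RANGE
        if np.any(ct < lo) or np.any(ct > hi):
            warnings.warn(
                f"Ct values outside the typical {lo}-{hi} cycle range", stacklevel=2
            )
        bad = set(self.data["group"]) - {"case", "control"}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")

    def mean_ct(self) -> pd.DataFrame:
        """Replicate-averaged Ct, one row per (sample_id, group, gene)."""
        return (
            self.data.groupby(["sample_id", "group", "gene"], sort=False)["ct"]
            .mean()
            .reset_index()
        )


@dataclass(frozen=True)
class RankSumResult:
    u_statistic: float
    p_value: float
    method: str  # "exact" or "asymptotic"


def ddct_fold_change(table: CtTable, gene: str) -> float:
    """Relative expression of ``gene`` in cases vs controls, 2^-ddCt.

    dCt = Ct(gene) - Ct(housekeeper) per sample; ddCt = mean dCt over case
    samples minus mean dCt over control samples.
    """
    mean_ct = table.mean_ct()
    wide = mean_ct.pivot_table(index=["sample_id", "group"], columns="gene", values="ct")
    if gene not in wide.columns:
        raise KeyError(f"gene {gene!r} not present in the Ct table")
    if table.housekeeping not in wide.columns:
        raise KeyError(f"housekeeping gene {table.housekeeping!r} not present in the Ct table")
    hk = wide[table.housekeeping]
    missing_hk = hk[hk.isna()].index.get_level_values("sample_id").tolist()
    if missing_hk:
        raise ValueError(
            f"sample(s) missing housekeeping measurement: {missing_hk}"
        )
    dct = (wide[gene] - hk).dropna()
    groups = dct.index.get_level_values("group")
    for g in ("case", "control"):
        if not np.any(groups == g):
            raise ValueError(f"gene {gene!r} has no measurements in group {g!r}")
    ddct = dct[groups == "case"].mean() - dct[groups == "control"].mean()
    return float(2.0 ** (-ddct))


def rank_sum_test(values_case: Sequence[float], values_control: Sequence[float]) -> RankSumResult:
    """Two-sided Mann-Whitney U test of case vs control values.

    Uses full enumeration of arrangements when the combined sample size is at
    most 20 and there are no ties, and the tie-corrected normal approximation
    otherwise.
    """
    a = np.asarray(values_case, dtype=float)
    b = np.asarray(values_control, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    if np.all(combined == combined[0]):
        warnings.warn("all values tied across both groups; p set to 1", stacklevel=2)
        return RankSumResult(u_statistic=a.size * b.size / 2.0, p_value=1.0, method="degenerate")
    has_ties = np.unique(combined).size < combined.size
    if a.size + b.size <= 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return RankSumResult(u_statistic=float(res.statistic), p_value=float(res.pvalue), method=method)


def age_association(
    matrix: pd.DataFrame,
    ages: Sequence[float],
    signature: Sequence[str],
    alpha: float = 0.05,
    n_age_groups: int = 4,
) -> pd.DataFrame:
    """Per-gene association of log2 expression ratio with subject age.

    Two checks per signature gene: Pearson correlation of log2 ratio vs age,
    and one-way ANOVA across ``n_age_groups`` age groups formed by sample
    quantiles of age. A gene is flagged if either test has p < ``alpha``.

    Parameters
    ----------
    matrix : pairs x genes DataFrame of positive expression ratios.
    ages : one age per row of ``matrix`` (the case member of the pair).
    """
    ages = np.asarray(ages, dtype=float)
    if len(ages) != len(matrix):
        raise ValueError("ages must have one entry per matrix row")
    if np.unique(ages).size < 2:
        raise ValueError("need at least 2 distinct ages")
    missing = [g for g in signature if g not in matrix.columns]
    if missing:
        raise KeyError(f"signature genes absent from matrix: {missing}")

    # quantile age groups; duplicate edges collapse for very discrete ages
    groups = pd.qcut(ages, q=n_age_groups, duplicates="drop")
    boundaries = [iv.right for iv in groups.categories[:-1]]

    rows = []
    for gene in signature:
        y = np.log2(matrix[gene].to_numpy(dtype=float))
        ok = np.isfinite(y)
        if np.ptp(y[ok]) == 0:
            warnings.warn(f"gene {gene!r} is constant; correlation undefined", stacklevel=2)
            rows.append({"gene": gene, "pearson_r": np.nan, "p_corr": np.nan,
                         "anova_f": np.nan, "p_anova": np.nan, "flagged": False})
            continue
        r, p_corr = stats.pearsonr(ages[ok], y[ok])
        samples = [y[ok & (groups.codes == c)] for c in range(len(groups.categories))]
        samples = [s for s in samples if s.size >= 2]
        if len(samples) >= 2:
            f, p_anova = stats.f_oneway(*samples)
        else:  # pragma: no cover - degenerate grouping
            f, p_anova = np.nan, np.nan
        flagged = bool((p_corr < alpha) or (np.isfinite(p_anova) and p_anova < alpha))
        rows.append({"gene": gene, "pearson_r": float(r), "p_corr": float(p_corr),
                     "anova_f": float(f), "p_anova": float(p_anova), "flagged": flagged})
    report = pd.DataFrame(rows)
    report.attrs["age_group_boundaries"] = boundaries
    return report
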