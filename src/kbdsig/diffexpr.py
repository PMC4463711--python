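"""Differential-expression screen over the target gene panel.

A gene is called up-regulated when its mean case/control ratio over pairs
exceeds ``fc_up`` (default 2) and its Bonferroni-adjusted one-sample t-test of
the log2 per-pair ratios against zero is significant at ``alpha``; symmetrical
for down-regulation below ``fc_down`` (default 0.5). Both conditions are
required. Fold-change summary statistics (mean and SEM) are reported on the
ratio scale; the test runs on the log2 scale, the natural paired analogue of a
two-sample comparison in a matched two-color design.
"""

from __future__ import annotations

import io
import logging
import re
import warnings
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["screen_de", "format_table1", "parse_table1"]

logger = logging.getLogger(__name__)

_CALL_ORDER = {"down": 0, "up": 1, "ns": 2}


def screen_de(
    matrix: pd.DataFrame,
    fc_up: float = 2.0,
    fc_down: float = 0.5,
    alpha: float = 0.05,
    annotations: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Screen a pairs x genes ratio matrix for differential expression.

    Parameters
    ----------
    matrix : pairs x genes DataFrame of positive ratios; NaN marks missing
        cells, which are excluded pairwise.
    annotations : optional per-gene table (indexed by gene symbol) providing
        ``gene_name`` / ``public_id`` columns for reporting.

    Returns
    -------
    One row per gene with columns gene_symbol, public_id, n_used, mean_fc,
    sem_fc, p_raw, p_adj, call, flag -- sorted by call (down, up, ns) then
    symbol. ``p_adj`` is the Bonferroni adjustment min(1, p_raw * G) with G
    the number of genes actually tested. Genes with fewer than 3 usable pairs
    are reported with call "ns" and flag "insufficient_pairs" rather than
    silently dropped.
    """
    if fc_down >= fc_up:
        raise ValueError("fc_down must be below fc_up")
    values = matrix.to_numpy(dtype=float)
    if np.nanmin(values) <= 0:
        raise ValueError("ratio matrix must be strictly positive")
    n_used = np.sum(np.isfinite(values), axis=0)
    testable = n_used >= 3
    n_tested = int(testable.sum())
    if n_tested == 0:
        raise ValueError("no gene has >= 3 usable pairs")
    logger.info("Bonferroni G = %d genes tested (of %d on panel)", n_tested, matrix.shape[1])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_fc = np.nanmean(values, axis=0)
        sem_fc = np.nanstd(values, axis=0, ddof=1) / np.sqrt(n_used)
        log2v = np.log2(values)
        t_res = stats.ttest_1samp(log2v, popmean=0.0, axis=0, nan_policy="omit")
    p_raw = np.asarray(t_res.pvalue, dtype=float)
    p_raw[~testable] = np.nan
    p_adj = np.minimum(1.0, p_raw * n_tested)

    call = np.full(matrix.shape[1], "ns", dtype=object)
    sig = testable & (p_adj < alpha)
    call[sig & (mean_fc > fc_up)] = "up"
    call[sig & (mean_fc < fc_down)] = "down"

    if annotations is not None:
        names = annotations.reindex(matrix.columns)
        gene_name = names.get("gene_name", pd.Series(index=matrix.columns, dtype=object))
        public_id = names.get("public_id", pd.Series(index=matrix.columns, dtype=object))
    else:
        gene_name = pd.Series(index=matrix.columns, dtype=object)
        public_id = pd.Series(index=matrix.columns, dtype=object)

    out = pd.DataFrame({
        "gene_symbol": matrix.columns,
        "gene_name": gene_name.fillna("").to_numpy(),
        "public_id": public_id.fillna("").to_numpy(),
        "n_used": n_used,
        "mean_fc": mean_fc,
        "sem_fc": sem_fc,
        "p_raw": p_raw,
        "p_adj": p_adj,
        "call": call,
        "flag": np.where(testable, "", "insufficient_pairs"),
    })
    out = out.sort_values(
        by=["call", "gene_symbol"], key=lambda s: s.map(_CALL_ORDER) if s.name == "call" else s
    ).reset_index(drop=True)
    out.attrs["n_tested"] = n_tested
    return out


def format_table1(results: pd.DataFrame) -> str:
    """Render the differential genes as a published-style report: the
    down-regulated block then the up-regulated block, fold change as
    "mean +/- SEM" with two decimals."""
    if results.empty:
        raise ValueError("results table is empty")
    lines = ["Gene Name\tSymbol\tPublic ID\tFold Change"]
    for block, title in (("down", "down-regulated genes"), ("up", "up-regulated genes")):
        sub = results[results["call"] == block]
        if sub.empty:
            continue
        lines.append(f"*** {title} ***")
        for row in sub.itertuples():
            lines.append(
                f"{row.gene_name}\t{row.gene_symbol}\t{row.public_id}\t"
                f"{row.mean_fc:.2f} ± {row.sem_fc:.2f}"
            )
    return "\n".join(lines) + "\n"


def parse_table1(text: str) -> pd.DataFrame:
    """Parse a ``format_table1`` report back into (symbol, mean_fc, sem_fc, call)."""
    rows = []
    call = None
    for line in text.splitlines():
        if line.startswith("Gene Name") or not line.strip():
            continue
        m = re.match(r"\*\*\* (down|up)-regulated genes \*\*\*", line)
        if m:
            call = m.group(1)
            continue
        name, symbol, public_id, fc = line.split("\t")
        mean_s, sem_s = fc.split("±")
        rows.append({"gene_symbol": symbol, "public_id": public_id,
                     "mean_fc": float(mean_s), "sem_fc": float(sem_s), "call": call})
    return pd.DataFrame(rows)
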