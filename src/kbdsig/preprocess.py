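"""Two-color microarray preprocessing: QC filtering, background correction,
global normalization, and per-pair expression-ratio computation.

Each array carries one matched pair: the control sample in the Cy3 channel and
the case (KBD) sample in Cy5. Per-spot records hold foreground and background
intensity per channel plus a scanner QC flag (negative = failed QC, the GenePix
convention). The stage chain is strictly ordered -- QC filter, then background
correction, then global normalization, then ratios -- and out-of-order calls
raise ``PipelineOrderError``.

Normalization rescales the Cy5 channel by a single constant. The default
("sum") equalizes total corrected intensity across channels over all retained
spots; "median" sets the median per-spot Cy3/Cy5 ratio to 1. Both rest on the
usual assumption that most genes on the panel are not differential.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ArrayScan",
    "PipelineOrderError",
    "qc_filter",
    "background_correct",
    "global_normalize",
    "compute_ratio_matrix",
    "sample_expression_matrix",
]

logger = logging.getLogger(__name__)

_STAGES = ("raw", "qc", "background", "normalized")
_CHANNELS = ("f_cy5", "b_cy5", "f_cy3", "b_cy3")


class PipelineOrderError(RuntimeError):
    """Raised when a preprocessing stage is applied out of order."""


@dataclass
class ArrayScan:
    """One two-channel scan (one matched pair).

    ``spots`` columns: probe_id, gene, f_cy5, b_cy5, f_cy3, b_cy3, flag.
    ``stage`` records how far through the chain this scan has progressed;
    ``provenance`` accumulates stage bookkeeping (removal counts, the
    normalization constant).
    """

    pair_id: str
    spots: pd.DataFrame
    stage: str = "raw"
    provenance: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"probe_id", "gene", "flag", *_CHANNELS}
        missing = required - set(self.spots.columns)
        if missing:
            raise ValueError(f"scan {self.pair_id}: missing spot columns {sorted(missing)}")
        if self.stage not in _STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        vals = self.spots[list(_CHANNELS)].to_numpy(dtype=float)
        if np.any(vals < 0) or not np.all(np.isfinite(vals)):
            raise ValueError(f"scan {self.pair_id}: intensities must be finite and >= 0")
        if self.spots["probe_id"].duplicated().any():
            raise ValueError(f"scan {self.pair_id}: duplicate probe_ids")


def _require_stage(scan: ArrayScan, expected: str, op: str) -> None:
    if scan.stage != expected:
        raise PipelineOrderError(
            f"{op} expects a {expected!r}-stage scan, got {scan.stage!r} "
            f"(pipeline order is QC -> background -> normalize -> ratio)"
        )


def qc_filter(scan: ArrayScan) -> ArrayScan:
    """Drop spots whose scanner QC flag is negative.

    Genes losing all their spots stay absent from the output and are reported
    as missing downstream (a warning is emitted here).
    """
    _require_stage(scan, "raw", "qc_filter")
    bad = scan.spots["flag"].to_numpy() < 0
    kept = scan.spots.loc[~bad].reset_index(drop=True)
    n_removed = int(bad.sum())
    logger.info("scan %s: QC removed %d of %d spots", scan.pair_id, n_removed, len(scan.spots))
    lost = set(scan.spots["gene"]) - set(kept["gene"])
    if lost:
        warnings.warn(
            f"scan {scan.pair_id}: all spots failed QC for gene(s) {sorted(lost)}; "
            "cells will be marked missing",
            stacklevel=2,
        )
    prov = dict(scan.provenance)
    prov["qc_removed"] = n_removed
    return ArrayScan(pair_id=scan.pair_id, spots=kept, stage="qc", provenance=prov)


def background_correct(scan: ArrayScan, floor: float = 1.0) -> ArrayScan:
    """Per-spot, per-channel background subtraction, floored at a positive
    constant so downstream ratios stay finite and positive."""
    _require_stage(scan, "qc", "background_correct")
    if floor <= 0:
        raise ValueError("floor must be positive")
    spots = scan.spots.copy()
    for f, b in (("f_cy5", "b_cy5"), ("f_cy3", "b_cy3")):
        spots[f] = np.maximum(spots[f].to_numpy(dtype=float) - spots[b].to_numpy(dtype=float), floor)
        spots[b] = 0.0
    prov = dict(scan.provenance)
    prov["background_floor"] = floor
    return ArrayScan(pair_id=scan.pair_id, spots=spots, stage="background", provenance=prov)


def global_normalize(scan: ArrayScan, method: str = "sum") -> ArrayScan:
    """Rescale the Cy5 channel by one constant computed from all retained spots.

    method="sum": constant = sum(Cy3) / sum(Cy5) so channel totals agree;
    method="median": constant = median per-spot Cy3/Cy5 ratio.
    """
    _require_stage(scan, "background", "global_normalize")
    if method not in ("sum", "median"):
        raise ValueError(f"unknown normalization method {method!r}")
    if len(scan.spots) == 0:
        raise ValueError(f"scan {scan.pair_id}: no spots left to normalize")
    cy5 = scan.spots["f_cy5"].to_numpy(dtype=float)
    cy3 = scan.spots["f_cy3"].to_numpy(dtype=float)
    if cy5.sum() <= 0 or cy3.sum() <= 0:
        raise ValueError(f"scan {scan.pair_id}: zero total intensity in a channel")
    if method == "sum":
        constant = cy3.sum() / cy5.sum()
    else:
        constant = float(np.median(cy3 / cy5))
    spots = scan.spots.copy()
    spots["f_cy5"] = cy5 * constant
    prov = dict(scan.provenance)
    prov["normalization_method"] = method
    prov["normalization_constant"] = float(constant)
    logger.info("scan %s: %s normalization constant %.6g", scan.pair_id, method, constant)
    return ArrayScan(pair_id=scan.pair_id, spots=spots, stage="normalized", provenance=prov)


def compute_ratio_matrix(
    scans: Sequence[ArrayScan],
    panel: Sequence[str],
    max_missing_fraction: float = 0.2,
) -> pd.DataFrame:
    """Assemble the pairs x genes case/control ratio matrix.

    Duplicate spots per gene are averaged per channel on the corrected
    intensity scale before the ratio. Genes absent from a scan give an
    explicit NaN cell (with a warning); genes missing in more than
    ``max_missing_fraction`` of pairs are dropped from the panel.
    """
    panel = list(panel)
    rows = {}
    for scan in scans:
        if scan.stage != "normalized":
            raise PipelineOrderError(
                f"compute_ratio_matrix expects normalized scans; scan {scan.pair_id} is at "
                f"stage {scan.stage!r}"
            )
        per_gene = scan.spots.groupby("gene", sort=False)[["f_cy5", "f_cy3"]].mean()
        ratio = per_gene["f_cy5"] / per_gene["f_cy3"]
        missing = [g for g in panel if g not in ratio.index]
        if missing:
            warnings.warn(
                f"scan {scan.pair_id}: gene(s) {missing} absent; cells marked missing",
                stacklevel=2,
            )
        rows[scan.pair_id] = ratio.reindex(panel)
    matrix = pd.DataFrame(rows).T
    matrix.index.name = "pair_id"
    missing_frac = matrix.isna().mean(axis=0)
    dropped = list(missing_frac.index[missing_frac > max_missing_fraction])
    if dropped:
        warnings.warn(
            f"dropping gene(s) missing in >{max_missing_fraction:.0%} of pairs: {dropped}",
            stacklevel=2,
        )
        matrix = matrix.drop(columns=dropped)
    return matrix


def sample_expression_matrix(scans: Sequence[ArrayScan]) -> pd.DataFrame:
    """Per-sample log2 single-channel intensities from normalized scans.

    Each scan yields two rows: "<pair>_KBD" from the Cy5 channel and
    "<pair>_CTL" from Cy3 (duplicate spots averaged per channel first). This
    is the per-sample profile consumed by the sample-level classifier stages.
    """
    rows = {}
    for scan in scans:
        if scan.stage != "normalized":
            raise PipelineOrderError(
                f"sample_expression_matrix expects normalized scans; scan {scan.pair_id} is at "
                f"stage {scan.stage!r}"
            )
        per_gene = scan.spots.groupby("gene", sort=False)[["f_cy5", "f_cy3"]].mean()
        rows[f"{scan.pair_id}_KBD"] = np.log2(per_gene["f_cy5"])
        rows[f"{scan.pair_id}_CTL"] = np.log2(per_gene["f_cy3"])
    return pd.DataFrame(rows).T
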