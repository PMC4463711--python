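"""Readers and writers for the pipeline's plain-text interchange formats.

Ratio matrices travel as genes x pairs CSV (first column the gene symbol,
header row the pair IDs) even though the in-memory convention is pairs x
genes; scans travel as GenePix-style TSV (Block/Column/Row/Name/ID plus
median foreground/background per channel and Flags); metadata, Ct tables and
per-gene reports as CSV; ground truth, signatures and metrics as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Sequence, Union

import numpy as np
import pandas as pd

from .preprocess import ArrayScan
from .signature import SvmModel
from .validation_stats import CtTable

__all__ = [
    "write_ratio_matrix", "read_ratio_matrix",
    "write_metadata", "read_metadata",
    "write_scan", "read_scan",
    "write_truth", "read_truth",
    "write_signature", "read_signature",
    "write_ct_table", "read_ct_table",
    "fetch_geo_series",
]

PathLike = Union[str, Path]

_GPR_COLUMNS = ["Block", "Column", "Row", "Name", "ID",
                "F635 Median", "B635 Median", "F532 Median", "B532 Median", "Flags"]


def write_ratio_matrix(matrix: pd.DataFrame, path: PathLike) -> None:
    """Write a pairs x genes matrix as genes x pairs CSV with a gene column."""
    matrix.T.rename_axis(index="gene", columns=None).to_csv(path)


def read_ratio_matrix(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    matrix = df.T
    matrix.index.name = "pair_id"
    matrix.columns.name = None
    return matrix


def write_metadata(metadata: pd.DataFrame, path: PathLike) -> None:
    metadata.to_csv(path, index=False)


def read_metadata(path: PathLike) -> pd.DataFrame:
    meta = pd.read_csv(path, keep_default_na=False)
    return meta.set_index("sample_id", drop=False).rename_axis(None)


def write_scan(scan: ArrayScan, path: PathLike) -> None:
    spots = scan.spots
    n = len(spots)
    out = pd.DataFrame({
        "Block": np.ones(n, dtype=int),
        "Column": np.arange(n) % 32 + 1,
        "Row": np.arange(n) // 32 + 1,
        "Name": spots["gene"].to_numpy(),
        "ID": spots["probe_id"].to_numpy(),
        "F635 Median": spots["f_cy5"].to_numpy(),
        "B635 Median": spots["b_cy5"].to_numpy(),
        "F532 Median": spots["f_cy3"].to_numpy(),
        "B532 Median": spots["b_cy3"].to_numpy(),
        "Flags": spots["flag"].to_numpy(),
    })
    out.to_csv(path, sep="\t", index=False)


def read_scan(path: PathLike, pair_id: str | None = None) -> ArrayScan:
    """Read a GenePix-like TSV; unknown columns are ignored."""
    raw = pd.read_csv(path, sep="\t")
    missing = [c for c in _GPR_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    spots = pd.DataFrame({
        "probe_id": raw["ID"],
        "gene": raw["Name"],
        "f_cy5": raw["F635 Median"].astype(float),
        "b_cy5": raw["B635 Median"].astype(float),
        "f_cy3": raw["F532 Median"].astype(float),
        "b_cy3": raw["B532 Median"].astype(float),
        "flag": raw["Flags"].astype(int),
    })
    if pair_id is None:
        pair_id = Path(path).stem
    return ArrayScan(pair_id=pair_id, spots=spots)


def write_truth(truth: pd.DataFrame, path: PathLike) -> None:
    payload = truth.reset_index().to_dict(orient="records")
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path: PathLike) -> pd.DataFrame:
    payload = json.loads(Path(path).read_text())
    return pd.DataFrame(payload).set_index("gene")


def write_signature(genes: Sequence[str], model: SvmModel, path: PathLike) -> None:
    payload = {
        "genes": list(genes),
        "weights": model.weights.tolist(),
        "bias": model.bias,
        "cost_c": model.cost_c,
        "center": model.center.tolist(),
        "scale": model.scale.tolist(),
        "positive_label": model.positive_label,
        "negative_label": model.negative_label,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_signature(path: PathLike) -> SvmModel:
    payload = json.loads(Path(path).read_text())
    return SvmModel(
        weights=np.asarray(payload["weights"], dtype=float),
        bias=float(payload["bias"]),
        cost_c=float(payload["cost_c"]),
        center=np.asarray(payload["center"], dtype=float),
        scale=np.asarray(payload["scale"], dtype=float),
        genes=list(payload["genes"]),
        positive_label=payload["positive_label"],
        negative_label=payload["negative_label"],
    )


def write_ct_table(table: CtTable, path: PathLike) -> None:
    out = table.data.copy()
    out.attrs = {}
    out.to_csv(path, index=False)


def read_ct_table(path: PathLike, housekeeping: str = "ACTB") -> CtTable:
    return CtTable(data=pd.read_csv(path), housekeeping=housekeeping)


def fetch_geo_series(accession: str = "GSE59446", dest: PathLike | None = None):
    """Documented stub for loading the deposited microarray series.

    The original cohort is deposited in NCBI GEO under this accession. This
    package deliberately ships no downloader; analyses run on synthetic
    cohorts or on user-supplied ratio/metadata CSV files in the formats this
    module reads. Calling this raises NotImplementedError with instructions.
    """
    raise NotImplementedError(
        f"No GEO client is bundled. Download {accession} manually, export the "
        "per-pair ratio matrix to the genes x pairs CSV layout of "
        "read_ratio_matrix, and the sample annotations to the metadata CSV "
        "layout of read_metadata."
    )
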