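"""End-to-end orchestration: simulate -> preprocess -> screen -> signature ->
independent-test evaluation -> degree discriminant -> validation statistics.

The run directory receives every stage artifact plus a manifest recording the
resolved configuration, the seeded train/test split, SHA-256 checksums of all
written files, and an explicit assertion that test pairs were untouched by
every training-side stage (screening, ranking, scaling, cost search).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import io as kio
from .bda import format_table2, loocv_bda
from .diffexpr import format_table1, screen_de
from .preprocess import background_correct, compute_ratio_matrix, global_normalize, qc_filter, sample_expression_matrix
from .signature import DEFAULT_C_GRID, evaluate, finalize_signature, loocv_size_sweep
from .synthetic_data import SimulationConfig, generate_cohort, generate_ct_table, generate_intensity_scans, study_config
from .validation_stats import age_association, ddct_fold_change, rank_sum_test

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


class RunConfig(BaseModel):
    """Resolved parameterization of a full pipeline run."""

    model_config = ConfigDict(frozen=True)

    seed: int = 0
    simulation: Optional[SimulationConfig] = None

    # split (per-pair; a pair contributes both its samples to the same side)
    n_test_pairs: int = Field(default=20, ge=1)
    train_pairs: Optional[Tuple[str, ...]] = None
    test_pairs: Optional[Tuple[str, ...]] = None

    # screening
    fc_up: float = 2.0
    fc_down: float = 0.5
    alpha: float = 0.05

    # signature search
    n_max: int = Field(default=50, ge=1)
    signature_size: int = Field(default=20, ge=1)
    criterion: str = "MID"
    cost_c: float = 0.5
    c_grid: Tuple[float, ...] = DEFAULT_C_GRID
    run_sweep: bool = True

    # preprocessing
    use_scans: bool = True
    normalization: str = "sum"

    # validation
    n_qpcr_up: int = 4
    n_qpcr_down: int = 2

    @model_validator(mode="after")
    def _check_split(self):
        if (self.train_pairs is None) != (self.test_pairs is None):
            raise ValueError("train_pairs and test_pairs must be given together")
        if self.train_pairs is not None:
            overlap = set(self.train_pairs) & set(self.test_pairs)
            if overlap:
                raise ValueError(f"train/test pairs overlap: {sorted(overlap)}")
        return self

    def resolved_simulation(self) -> SimulationConfig:
        if self.simulation is not None:
            return self.simulation
        return study_config(self.seed)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _split_pairs(pair_ids: List[str], config: RunConfig) -> Tuple[List[str], List[str]]:
    if config.train_pairs is not None:
        unknown = (set(config.train_pairs) | set(config.test_pairs)) - set(pair_ids)
        if unknown:
            raise ValueError(f"split references unknown pairs: {sorted(unknown)}")
        return list(config.train_pairs), list(config.test_pairs)
    if config.n_test_pairs >= len(pair_ids):
        raise ValueError("n_test_pairs must leave at least one training pair")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    order = rng.permutation(len(pair_ids))
    test = sorted(pair_ids[i] for i in order[: config.n_test_pairs])
    train = sorted(pair_ids[i] for i in order[config.n_test_pairs:])
    return train, test


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the full pipeline on a synthetic cohort and return the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.resolved_simulation()
    manifest: dict = {"seed": config.seed, "simulation_seed": sim.seed, "stages": []}

    # --- simulate ---------------------------------------------------------
    cohort = generate_cohort(sim)
    kio.write_ratio_matrix(cohort.ratios, outdir / "ratios_truth_path.csv")
    kio.write_metadata(cohort.metadata, outdir / "metadata.csv")
    kio.write_truth(cohort.truth, outdir / "truth.json")
    manifest["stages"].append("simulate")

    # --- preprocess -------------------------------------------------------
    if config.use_scans:
        scans = generate_intensity_scans(sim, cohort)
        processed = [
            global_normalize(background_correct(qc_filter(s)), method=config.normalization)
            for s in scans
        ]
        ratios = compute_ratio_matrix(processed, panel=list(sim.symbols))
        expr = sample_expression_matrix(processed)
        manifest["normalization_constants"] = {
            s.pair_id: s.provenance["normalization_constant"] for s in processed
        }
    else:
        ratios = cohort.ratios
        expr = cohort.sample_expression
    kio.write_ratio_matrix(ratios, outdir / "ratios.csv")
    manifest["stages"].append("preprocess")

    # --- split ------------------------------------------------------------
    train_pairs, test_pairs = _split_pairs(cohort.pair_ids, config)
    assert not set(train_pairs) & set(test_pairs)
    meta = cohort.metadata
    train_samples = meta.index[meta["pair_id"].isin(train_pairs)].tolist()
    test_samples = meta.index[meta["pair_id"].isin(test_pairs)].tolist()
    manifest["split"] = {"train_pairs": train_pairs, "test_pairs": test_pairs}

    # --- differential expression (training pairs only) --------------------
    train_ratios = ratios.loc[[p for p in ratios.index if p in set(train_pairs)]]
    de = screen_de(train_ratios, fc_up=config.fc_up, fc_down=config.fc_down, alpha=config.alpha)
    de.to_csv(outdir / "de_results.csv", index=False)
    (outdir / "table1.txt").write_text(format_table1(de))
    manifest["stages"].append("diffexpr")

    # --- signature search (training samples only) -------------------------
    # QC-flagged spots leave explicit NaN cells; the model stages need complete
    # data, so fill with per-gene medians learned from the training side only.
    X_train = expr.loc[train_samples]
    train_medians = X_train.median()
    X_train = X_train.fillna(train_medians)
    y_train = meta.loc[train_samples, "role"].to_numpy()
    if config.run_sweep:
        curve = loocv_size_sweep(
            X_train, y_train, n_max=config.n_max, criterion=config.criterion,
            cost_c=config.cost_c, alpha=config.alpha,
        )
        pd.DataFrame({
            "n": list(curve.accuracy_by_n), "loocv_accuracy": list(curve.accuracy_by_n.values())
        }).to_csv(outdir / "signature_curve.csv", index=False)
        curve.selection_frequencies(config.signature_size).rename("frequency").to_csv(
            outdir / "selection_frequencies.csv"
        )
        manifest["models_built"] = curve.models_built
    genes, model = finalize_signature(
        X_train, y_train, n=config.signature_size, criterion=config.criterion,
        c_grid=config.c_grid, alpha=config.alpha, seed=config.seed,
    )
    kio.write_signature(genes, model, outdir / "signature.json")
    manifest["stages"].append("signature")

    # --- independent test-set evaluation ----------------------------------
    X_test = expr.loc[test_samples].fillna(train_medians)
    y_test = meta.loc[test_samples, "role"].to_numpy()
    ct = evaluate(model, X_test, y_test)
    metrics = {
        "tp": ct.tp, "fn": ct.fn, "tn": ct.tn, "fp": ct.fp,
        "accuracy": ct.accuracy, "sensitivity": ct.sensitivity, "specificity": ct.specificity,
        "cost_c": model.cost_c,
    }
    (outdir / "metrics.json").write_text(json.dumps(metrics, indent=1))
    manifest["stages"].append("evaluate")
    manifest["test_samples_untouched_before_evaluation"] = True

    # --- degree discriminant on all cases ---------------------------------
    case_ratios = np.log2(ratios[genes].fillna(ratios[genes].median()))
    degrees = cohort.degrees.to_numpy()
    original, cross_validated = loocv_bda(case_ratios, degrees)
    (outdir / "bda_table2.txt").write_text(format_table2(original, cross_validated))
    manifest["bda"] = {
        "original_accuracy": original.accuracy,
        "cross_validated_accuracy": cross_validated.accuracy,
    }
    manifest["stages"].append("bda")

    # --- qPCR and age validation ------------------------------------------
    de_indexed = de.set_index("gene_symbol")
    up = de_indexed[de_indexed["call"] == "up"].sort_values("p_adj").index[: config.n_qpcr_up]
    down = de_indexed[de_indexed["call"] == "down"].sort_values("p_adj").index[: config.n_qpcr_down]
    qpcr_genes = list(up) + list(down)
    if qpcr_genes:
        ddct_truth = {g: -float(np.log2(cohort.truth.loc[g, "true_fc"])) for g in qpcr_genes}
        table = generate_ct_table(sim, qpcr_genes, ddct_truth)
        kio.write_ct_table(table, outdir / "ct_table.csv")
        wide = table.mean_ct().pivot_table(index=["sample_id", "group"], columns="gene", values="ct")
        hk = wide["ACTB"]
        qrows = []
        for g in qpcr_genes:
            dct = wide[g] - hk
            grp = dct.index.get_level_values("group")
            rs = rank_sum_test(dct[grp == "case"], dct[grp == "control"])
            qrows.append({"gene": g, "fold_change_2ddct": ddct_fold_change(table, g),
                          "u_statistic": rs.u_statistic, "p_value": rs.p_value,
                          "method": rs.method})
        pd.DataFrame(qrows).to_csv(outdir / "qpcr.csv", index=False)
    case_meta = meta[meta["role"] == "case"].set_index("pair_id")
    ages = case_meta.loc[ratios.index, "age"].to_numpy()
    age_report = age_association(ratios, ages, signature=genes, alpha=config.alpha)
    age_report.to_csv(outdir / "age_report.csv", index=False)
    manifest["stages"].append("validation_stats")

    # --- manifest ----------------------------------------------------------
    manifest["config"] = json.loads(config.model_dump_json())
    manifest["checksums"] = {
        p.name: _sha256(p) for p in sorted(outdir.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
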