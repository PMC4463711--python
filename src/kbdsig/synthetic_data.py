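"""Synthetic paired case-control cohorts for the KBD blood-signature pipeline.

Emulates the statistical structure of a 100-pair, 169-gene custom two-color
microarray study of Kashin-Beck disease (KBD): each pair is one patient and one
age/sex-matched control hybridized on one array (control labeled Cy3, patient
Cy5), read out as per-gene case/control intensity ratios. Differential genes
are planted with known fold changes so every downstream stage (QC/normalization,
differential-expression screen, mRMR/SVM signature search, degree discriminant,
qPCR validation) can be tested against ground truth.

Generative model
----------------
Per pair p and gene g the expression ratio is lognormal,

    r_pg = 2 ** (loc_g + s_p * e * 1[g in degree genes] + eps_pg),
    eps_pg ~ Normal(0, log_ratio_sd**2),

where ``s_p`` indicates a degree-II patient and ``e`` is the degree shift.
Null genes have loc_g = 0. For planted genes the location depends on the
fold-change convention:

* ``"mean"`` (default): the planted value is the *expected arithmetic mean*
  of the per-pair ratios (the convention in which published per-gene
  "mean +/- SEM" fold changes are stated), i.e.
  loc_g = log2(FC) - sd^2 ln2 / 2 - log2(mixture factor of the degree shift).
* ``"log"``: the planted value sits on the log scale directly,
  loc_g = log2(FC); the arithmetic mean then carries the lognormal bias
  factor exp((sd ln2)^2 / 2).

Per-sample (single-channel) log2 intensities share a per-pair baseline so the
pair ratio is exactly the lognormal above while case and control samples remain
separable per gene by loc_g, which is what the sample-level SVM stage consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .preprocess import ArrayScan
from .validation_stats import CtTable

__all__ = [
    "SimulationConfig",
    "PairedCohort",
    "generate_cohort",
    "generate_intensity_scans",
    "generate_ct_table",
    "study_planted_effects",
    "study_config",
    "calibrate_sd_to_sem",
    "TABLE1_SIGNATURE",
]

_LN2 = float(np.log(2.0))

#: The 20 published signature genes: (symbol, public_id, mean fold change, SEM),
#: 15 down-regulated then 5 up-regulated.
TABLE1_SIGNATURE: Tuple[Tuple[str, str, float, float], ...] = (
    ("ABCC13", "NR_003087", 0.42, 0.03),
    ("ABI3BP", "NM_015429", 0.33, 0.03),
    ("BCAT1", "NM_001178091", 0.43, 0.04),
    ("CACNG6", "NM_145814", 0.39, 0.02),
    ("CSGALNACT1", "NM_001130518", 0.21, 0.03),
    ("CTSC", "NM_001114173", 0.39, 0.02),
    ("CYB5R3", "NM_000398", 0.48, 0.04),
    ("DMD", "NM_007868", 0.37, 0.02),
    ("ERH", "NM_004450", 0.38, 0.02),
    ("F11R", "NM_016946", 0.46, 0.02),
    ("FKBP9", "NM_007270", 0.49, 0.06),
    ("FZD1", "NM_003505", 0.47, 0.03),
    ("GDF5", "NM_000557", 0.44, 0.03),
    ("HBA2", "NM_000517", 0.49, 0.03),
    ("ZIC5", "NM_033132", 0.38, 0.02),
    ("BIRC3", "NM_001165", 4.26, 0.35),
    ("FGFR1OP2", "NM_001171887", 2.39, 0.15),
    ("SIGLEC8", "NM_014442", 2.50, 0.29),
    ("SSBP1", "NM_001256510", 3.12, 0.25),
    ("TTC25", "NM_031421", 3.19, 0.25),
)

#: fixed placement seed so planted gene positions are stable across cohort seeds
_PLACEMENT_SEED = 20150519


class SimulationConfig(BaseModel):
    """Full parameterization of a synthetic paired cohort."""

    model_config = ConfigDict(frozen=True)

    n_pairs: int = Field(default=100, ge=2)
    n_genes: int = Field(default=169, ge=1)
    planted_effects: Tuple[Tuple[int, float], ...] = ()
    log_ratio_sd: float = Field(default=0.3, gt=0)
    fc_convention: Literal["mean", "log"] = "mean"
    degree_effect: float = 0.5
    degree_split: float = Field(default=0.5, ge=0.0, le=1.0)
    degree_genes: Optional[Tuple[int, ...]] = None
    seed: int = 0

    # per-sample (single-channel) structure
    baseline_mean: float = 10.0
    baseline_sd: float = Field(default=1.5, ge=0)
    sample_sd: float = Field(default=0.5, ge=0)

    # optional age confounding (negative-control knob; off by default)
    age_trend_gene: Optional[int] = None
    age_trend_slope: float = 0.0
    case_age_range: Tuple[int, int] = (43, 79)
    control_age_range: Tuple[int, int] = (40, 77)
    male_fraction: float = Field(default=0.44, ge=0.0, le=1.0)

    # intensity-scan generation
    dye_bias_cy5: float = Field(default=1.5, gt=0)
    background_level: float = Field(default=50.0, ge=0)
    bad_spot_fraction: float = Field(default=0.02, ge=0.0, lt=1.0)
    spots_per_gene: int = Field(default=1, ge=1)

    # qPCR generation
    ct_noise_sd: float = Field(default=0.2, ge=0)
    housekeeping_ct: float = 18.0
    target_ct_baseline: float = 26.0
    n_qpcr_per_group: int = Field(default=5, ge=1)

    gene_symbols: Optional[Tuple[str, ...]] = None

    @field_validator("planted_effects")
    @classmethod
    def _positive_fold_changes(cls, v):
        for gene_id, fc in v:
            if fc <= 0:
                raise ValueError(f"planted_effects: true_fold_change must be > 0 (gene {gene_id})")
        seen = [g for g, _ in v]
        if len(seen) != len(set(seen)):
            raise ValueError("planted_effects: duplicate gene_id")
        return v

    @model_validator(mode="after")
    def _cross_checks(self):
        for gene_id, _ in self.planted_effects:
            if not 0 <= gene_id < self.n_genes:
                raise ValueError(f"planted_effects: gene_id {gene_id} out of range for n_genes={self.n_genes}")
        if self.degree_genes is not None:
            for g in self.degree_genes:
                if not 0 <= g < self.n_genes:
                    raise ValueError(f"degree_genes: gene_id {g} out of range for n_genes={self.n_genes}")
        if self.gene_symbols is not None and len(self.gene_symbols) != self.n_genes:
            raise ValueError("gene_symbols must have length n_genes")
        if self.age_trend_gene is not None and not 0 <= self.age_trend_gene < self.n_genes:
            raise ValueError("age_trend_gene out of range")
        return self

    @property
    def symbols(self) -> Tuple[str, ...]:
        if self.gene_symbols is not None:
            return self.gene_symbols
        return tuple(f"G{i:03d}" for i in range(self.n_genes))


@dataclass
class PairedCohort:
    """A generated cohort plus its ground truth.

    ratios : pairs x genes DataFrame of strictly positive case/control ratios.
    sample_expression : (2 * n_pairs) x genes DataFrame of per-sample log2
        single-channel intensities (rows "<pair>_KBD" and "<pair>_CTL").
    metadata : per-sample table (sample_id index; role, pair_id, degree, age, sex).
    truth : per-gene table (gene index; true_fc, log2_location, de_status).
    """

    ratios: pd.DataFrame
    sample_expression: pd.DataFrame
    metadata: pd.DataFrame
    truth: pd.DataFrame
    config: SimulationConfig
    seed_used: int

    @property
    def pair_ids(self) -> list:
        return list(self.ratios.index)

    @property
    def labels(self) -> pd.Series:
        """Per-sample case/control labels aligned with sample_expression."""
        return self.metadata.loc[self.sample_expression.index, "role"]

    @property
    def degrees(self) -> pd.Series:
        """Per-case degree labels ("I"/"II") indexed by pair id."""
        cases = self.metadata[self.metadata["role"] == "case"]
        return cases.set_index("pair_id")["degree"].loc[self.pair_ids]


def calibrate_sd_to_sem(mean_fc: float, sem_fc: float, n_pairs: int) -> float:
    """Log2-ratio noise SD whose lognormal ratio distribution reproduces a
    published ratio-scale mean +/- SEM at the given number of pairs.

    Moment matching: with ratio = FC * exp(N(-tau^2/2, tau^2)) the ratio SD is
    FC * sqrt(exp(tau^2) - 1), so tau^2 = ln(1 + (SEM * sqrt(n) / FC)^2).
    """
    if mean_fc <= 0 or sem_fc <= 0 or n_pairs < 2:
        raise ValueError("mean_fc and sem_fc must be positive and n_pairs >= 2")
    tau2 = np.log1p((sem_fc * np.sqrt(n_pairs) / mean_fc) ** 2)
    return float(np.sqrt(tau2) / _LN2)


def study_planted_effects(n_genes: int = 169) -> Tuple[pd.DataFrame, Tuple[str, ...]]:
    """Default planted-truth table for the full study cohort: 50 differential
    genes (18 up, 32 down). The 20 published signature genes keep their printed
    symbols and fold changes; the remaining 13 up / 17 down genes are filled
    with fold changes spread over the printed ranges.

    Returns (table, gene_symbols): the table has columns gene_id, symbol,
    public_id, fold_change; gene_symbols covers all ``n_genes`` positions.
    """
    if n_genes < 50:
        raise ValueError("study planted structure needs at least 50 genes")
    extra_up = [(f"KBDUP{i + 1:02d}", "synthetic", fc, np.nan)
                for i, fc in enumerate(np.round(np.linspace(2.4, 4.2, 13), 2))]
    extra_down = [(f"KBDDN{i + 1:02d}", "synthetic", fc, np.nan)
                  for i, fc in enumerate(np.round(np.linspace(0.22, 0.45, 17), 2))]
    down = [t for t in TABLE1_SIGNATURE if t[2] < 1] + extra_down
    up = [t for t in TABLE1_SIGNATURE if t[2] > 1] + extra_up
    planted = down + up  # 32 down, 18 up
    rng = np.random.default_rng(_PLACEMENT_SEED)
    positions = np.sort(rng.choice(n_genes, size=len(planted), replace=False))
    symbols = [f"G{i:03d}" for i in range(n_genes)]
    rows = []
    for pos, (sym, pid, fc, sem) in zip(positions, planted):
        symbols[pos] = sym
        rows.append({"gene_id": int(pos), "symbol": sym, "public_id": pid,
                     "fold_change": float(fc), "published_sem": sem})
    return pd.DataFrame(rows), tuple(symbols)


def study_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The default full-scale study cohort: 100 pairs, 169 genes, 50 planted
    differential genes (18 up, 32 down) at the published effect sizes."""
    table, symbols = study_planted_effects(169)
    planted = tuple((int(r.gene_id), float(r.fold_change)) for r in table.itertuples())
    params = dict(
        n_pairs=100,
        n_genes=169,
        planted_effects=planted,
        gene_symbols=symbols,
        seed=seed,
    )
    params.update(overrides)
    return SimulationConfig(**params)


def _child_rngs(seed: int, n: int) -> list:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _locations(config: SimulationConfig, frac_degree_ii: float) -> np.ndarray:
    """Per-gene log2 location implementing the fold-change convention."""
    loc = np.zeros(config.n_genes)
    degree_set = set(config.degree_genes) if config.degree_genes is not None else {
        g for g, _ in config.planted_effects
    }
    tau2 = (config.log_ratio_sd * _LN2) ** 2
    for gene_id, fc in config.planted_effects:
        loc[gene_id] = np.log2(fc)
        if config.fc_convention == "mean":
            loc[gene_id] -= tau2 / (2.0 * _LN2)
            if gene_id in degree_set and config.degree_effect != 0.0:
                mixture = (1 - frac_degree_ii) + frac_degree_ii * 2.0 ** config.degree_effect
                loc[gene_id] -= np.log2(mixture)
    return loc


def generate_cohort(config: SimulationConfig) -> PairedCohort:
    """Generate a paired cohort under the lognormal ratio model.

    Deterministic given ``config.seed``; all sub-streams (baselines, noise,
    degree assignment, ages, sexes) derive from a single seed sequence.
    """
    rng_base, rng_eps, rng_deg, rng_age, rng_sex, rng_pair = _child_rngs(config.seed, 6)
    n_p, n_g = config.n_pairs, config.n_genes
    symbols = list(config.symbols)
    pair_ids = [f"P{i + 1:03d}" for i in range(n_p)]

    # degree assignment for cases
    n_ii = int(round(config.degree_split * n_p))
    order = rng_deg.permutation(n_p)
    is_ii = np.zeros(n_p, dtype=bool)
    is_ii[order[:n_ii]] = True
    frac_ii = n_ii / n_p

    loc = _locations(config, frac_ii)
    degree_set = set(config.degree_genes) if config.degree_genes is not None else {
        g for g, _ in config.planted_effects
    }
    degree_mask = np.zeros(n_g, dtype=bool)
    for g in degree_set:
        degree_mask[g] = True

    baseline = rng_base.normal(config.baseline_mean, config.baseline_sd, size=n_g)
    pair_effect = rng_pair.normal(0.0, config.sample_sd, size=(n_p, n_g))
    eps = rng_eps.normal(0.0, config.log_ratio_sd, size=(n_p, n_g))

    log2_ratio = loc[None, :] + eps
    if config.degree_effect != 0.0 and degree_mask.any():
        log2_ratio[np.ix_(is_ii, degree_mask)] += config.degree_effect

    # ages and sexes (pair-matched sex; ages independent of expression unless
    # the age-trend knob is set)
    case_age = rng_age.integers(config.case_age_range[0], config.case_age_range[1] + 1, size=n_p)
    ctrl_age = rng_age.integers(config.control_age_range[0], config.control_age_range[1] + 1, size=n_p)
    sex = np.where(rng_sex.random(n_p) < config.male_fraction, "M", "F")

    if config.age_trend_gene is not None and config.age_trend_slope != 0.0:
        centered = case_age - case_age.mean()
        log2_ratio[:, config.age_trend_gene] += config.age_trend_slope * centered

    control_expr = baseline[None, :] + pair_effect
    case_expr = control_expr + log2_ratio
    ratios = 2.0 ** log2_ratio

    ratio_df = pd.DataFrame(ratios, index=pair_ids, columns=symbols)
    ratio_df.index.name = "pair_id"

    sample_rows, sample_ids = [], []
    meta_rows = []
    for i, pid in enumerate(pair_ids):
        for role, expr, age in (("case", case_expr[i], case_age[i]),
                                ("control", control_expr[i], ctrl_age[i])):
            sid = f"{pid}_{'KBD' if role == 'case' else 'CTL'}"
            sample_ids.append(sid)
            sample_rows.append(expr)
            meta_rows.append({
                "sample_id": sid, "role": role, "pair_id": pid,
                "degree": ("II" if is_ii[i] else "I") if role == "case" else "",
                "age": int(age), "sex": sex[i],
            })
    expr_df = pd.DataFrame(np.vstack(sample_rows), index=sample_ids, columns=symbols)
    meta_df = pd.DataFrame(meta_rows).set_index("sample_id", drop=False)
    meta_df.index.name = None

    planted_map = dict(config.planted_effects)
    truth_rows = []
    for g in range(n_g):
        fc = planted_map.get(g, 1.0)
        status = "ns" if g not in planted_map else ("up" if fc > 1 else "down")
        truth_rows.append({"gene": symbols[g], "gene_id": g, "true_fc": float(fc),
                           "log2_location": float(loc[g]), "de_status": status,
                           "degree_gene": bool(degree_mask[g])})
    truth = pd.DataFrame(truth_rows).set_index("gene")

    return PairedCohort(ratios=ratio_df, sample_expression=expr_df, metadata=meta_df,
                        truth=truth, config=config, seed_used=config.seed)


def generate_intensity_scans(
    config: SimulationConfig, cohort: Optional[PairedCohort] = None
) -> list:
    """Per-pair two-channel spot tables consistent with the cohort's ratios.

    Foreground = dye_bias * 2**log2_expression + background (Cy5 carries the
    configured dye bias), background = the configured constant, and a seeded
    fraction of spots is flagged bad. Running the preprocess chain
    (QC -> background correction -> global normalization -> ratios) recovers
    the cohort's ratio matrix up to the normalization constant.
    """
    if cohort is None:
        cohort = generate_cohort(config)
    (rng_flag,) = _child_rngs(config.seed + 1_000_003, 1)
    scans = []
    symbols = list(config.symbols)
    case = 2.0 ** cohort.sample_expression.loc[[f"{p}_KBD" for p in cohort.pair_ids]].to_numpy()
    ctrl = 2.0 ** cohort.sample_expression.loc[[f"{p}_CTL" for p in cohort.pair_ids]].to_numpy()
    k = config.spots_per_gene
    for i, pid in enumerate(cohort.pair_ids):
        rows = []
        for g, sym in enumerate(symbols):
            for rep in range(k):
                flag = -100 if rng_flag.random() < config.bad_spot_fraction else 0
                rows.append({
                    "probe_id": f"{sym}_r{rep + 1}",
                    "gene": sym,
                    "f_cy5": config.dye_bias_cy5 * case[i, g] + config.background_level,
                    "b_cy5": config.background_level,
                    "f_cy3": ctrl[i, g] + config.background_level,
                    "b_cy3": config.background_level,
                    "flag": flag,
                })
        scans.append(ArrayScan(pair_id=pid, spots=pd.DataFrame(rows)))
    return scans


def generate_ct_table(
    config: SimulationConfig,
    genes: Sequence[str],
    ddct_truth: Mapping[str, float],
    n_per_group: Optional[int] = None,
) -> CtTable:
    """qPCR threshold-cycle table with a planted ddCt per gene.

    Control samples get Ct = per-gene baseline + noise; case samples get the
    baseline shifted by ddct_truth[gene] (so the cohort mean ddCt converges to
    the planted value and the fold change to 2**-ddct). The housekeeping gene
    is constant up to noise in every sample.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("gene list must be non-empty")
    for g in genes:
        d = ddct_truth[g]
        if not np.isfinite(d):
            raise ValueError(f"ddct_truth for {g!r} must be finite")
    n = n_per_group if n_per_group is not None else config.n_qpcr_per_group
    rng_bl, rng_ct = _child_rngs(config.seed + 2_000_003, 2)
    baselines = {g: config.target_ct_baseline + rng_bl.normal(0.0, 1.0) for g in genes}
    records = []
    for group, shift_on in (("case", True), ("control", False)):
        for s in range(n):
            sid = f"Q{'K' if group == 'case' else 'C'}{s + 1:02d}"
            records.append({"sample_id": sid, "group": group, "gene": "ACTB",
                            "ct": config.housekeeping_ct + rng_ct.normal(0.0, config.ct_noise_sd)})
            for g in genes:
                ct = baselines[g] + (ddct_truth[g] if shift_on else 0.0)
                records.append({"sample_id": sid, "group": group, "gene": g,
                                "ct": ct + rng_ct.normal(0.0, config.ct_noise_sd)})
    return CtTable(data=pd.DataFrame(records), housekeeping="ACTB")
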