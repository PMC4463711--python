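# Methods

This note documents the statistical model behind `kbdsig`, the defaults and
why they were chosen, the numerical decisions, and what the synthetic cohorts
do and do not establish about real data.

## Generative model of the synthetic cohort

Each of `n_pairs` matched pairs carries one KBD patient and one control
hybridized on one two-color array. For pair *p* and gene *g* the case/control
expression ratio is lognormal:

```
r_pg = 2 ** (loc_g + s_p * e * 1[g ∈ degree genes] + eps_pg),
eps_pg ~ N(0, sigma^2),    sigma = log_ratio_sd (default 0.3)
```

where `s_p` indicates a degree-II patient and `e` is the additive log2 degree
shift (default 0.5). Null genes have `loc_g = 0`, so their log2 ratios are
exactly centered and the null calibration of the t-based screen holds by
construction.

**Fold-change convention.** Published per-gene summaries of this kind of
design are arithmetic means (± SEM) of the per-pair ratios. A lognormal with
log2-location `log2(FC)` has arithmetic mean `FC * exp((sigma ln2)^2 / 2)` —
a bias of ~2% at sigma = 0.3 but ~40% at sigma ≈ 1. The generator therefore
interprets a planted fold change as the *expected arithmetic mean ratio* and
sets

```
loc_g = log2(FC) − sigma^2 ln2 / 2 − log2((1−f) + f * 2^e)      ("mean", default)
```

where the last term removes the degree-mixture contribution (`f` = realized
fraction of degree-II patients) for degree-shifted genes, so that the screen's
estimator is unbiased for the planted value under any noise level. The literal
location `loc_g = log2(FC)` remains available as `fc_convention="log"`; the
two coincide as noise → 0.

**Noise scale.** A single log2-ratio SD for all genes (default 0.3) is the
simplest model matching the order of published per-gene SEMs at n = 100. When
an experiment must reproduce a specific published mean ± SEM,
`calibrate_sd_to_sem(mean, sem, n)` solves the lognormal moment match
`sigma = sqrt(ln(1 + (sem·sqrt(n)/mean)^2)) / ln 2`. For the 4.26 ± 0.35
up-regulated benchmark gene this gives sigma ≈ 1.04. Note that at such noise
the per-pair ratio distribution is strongly right-skewed: a plain
mean ± 2·(sample SEM) interval covers the truth in ~93% rather than 95% of
cohorts, which is why replicate-averaged recovery checks are used at that
scale.

**Per-sample profiles.** Control samples get log2 intensity
`b_g + u_pg` (gene baseline `b_g ~ N(10, 1.5^2)`, per-pair effect
`u_pg ~ N(0, 0.5^2)`), cases get the same baseline plus the pair's log2 ratio,
so pair ratios and sample profiles are exactly consistent and the per-gene
class separation equals `loc_g`. The shared per-pair baseline mimics the
within-array pairing of the two channels.

**Planted structure of the full-scale cohort** (`study_config`): 169 genes,
50 planted differential genes (18 up, 32 down). The 20 published signature
genes keep their printed symbols and fold changes (down 0.21–0.49, up
2.39–4.26); the remaining 13 up / 17 down are filled evenly over 2.4–4.2 and
0.22–0.45. Gene positions on the panel are fixed by an internal placement
seed so truth tables are comparable across cohort seeds.

**Degree substructure** is a synthetic-only assumption: no severity
expression model is published, so a configurable additive log2 shift on a
configurable gene subset (default: the planted genes) gives the discriminant
stage signal to find. The differential-expression recovery experiments set
`degree_effect = 0` to isolate the case–control contrast; severity
substructure is exercised separately in the discriminant experiments.

**Ages** are uniform over the published ranges (cases 43–79, controls 40–77)
and independent of expression by default, matching the published finding of
no age effect; `age_trend_gene`/`age_trend_slope` plant a linear log2-ratio
trend for negative-control tests. Sexes are pair-matched at the published
44% male fraction.

**Scans.** Spot foreground = dye_bias × linear intensity + background;
background is a known constant; a seeded fraction of spots carries a negative
QC flag. Not modeled: spatial artifacts, print-tip effects, probe sequence
effects, dye swaps, intensity-dependent (curved) dye bias — consequently the
preprocessing tests establish arithmetic correctness of the chain, not
robustness to those artifacts.

**Ct tables.** Per sample, Ct(target) = per-gene baseline (+ planted ΔΔCt in
cases) + N(0, 0.2²); Ct(β-actin) constant up to the same noise. Technical
replicates are averaged per sample-gene before ΔCt. qPCR cohort default is
5 + 5 (the published validation cohort table), configurable.

## Preprocessing decisions

- Background: per-spot median background subtracted from foreground, floored
  at 1.0 (keeps ratios finite/positive); the standard reading of
  GenePix-style columns.
- Global normalization: one constant rescaling Cy5 so channel totals match
  over all retained spots ("using all detected genes"); median-ratio scaling
  is a config alternative. Which variant the original study used is not
  recoverable; sum is the default. Both rest on the assumption that most
  panel genes are non-differential, so on panels with strong asymmetric
  signal the constant absorbs part of the global shift (visible in round-trip
  tests as a per-scan additive log2 offset).
- Duplicate probes: arithmetic mean of corrected intensities per channel
  before the ratio.
- Missing cells: genes missing in > 20% of pairs are dropped with a warning;
  remaining NaN cells are excluded pairwise in per-gene statistics, and
  filled with training-side per-gene medians before the classifier stages.

## Differential screen

One-sample two-sided t-test of log2 per-pair ratios against 0 — the natural
paired analogue for a matched ratio design ("which t-test" is otherwise
unspecified in such designs). Bonferroni G = genes actually tested (≥ 3
usable pairs), not the nominal panel size. A call requires fold change AND
significance. Genes with < 3 usable pairs are reported flagged, never
silently dropped. No FDR variant is offered by design.

## mRMR

Discretization is the 3-state μ ± k·σ scheme (k = 1) of the original mRMR
methodology; no published choice exists for this stage, so the scheme and k
are configurable. MI is the plug-in estimator in bits with zero-count cells
contributing zero; its positive small-sample bias is irrelevant for ranking
(all candidates share the sample). MID (relevance − mean redundancy) is the
default criterion: it is numerically stable when redundancy → 0, whereas MIQ
divides by max(mean redundancy, 1e−12). Ties break to the lower gene index,
making rankings fully deterministic.

## LOOCV wrapper and SVM

- Per-fold feature pool: Welch-t Bonferroni screen on the fold's training
  samples, topped up with the next most significant genes to `n_max`, so
  every fold ranks exactly `n_max` genes, the model count is structurally
  `n_samples × n_max`, and no-signal data still defines a pool. The paired
  fold-change thresholds are not re-applied at per-sample level (they are
  defined on the paired-ratio scale).
- The held-out sample never touches pool construction, discretization
  thresholds, feature scaling, or cost selection (leakage-guard tested).
- Features are z-scored with training statistics (scales floored at 1e−8);
  required for a meaningful C scale.
- The sweep uses the fixed default cost C = 0.5; the final model grid-searches
  C over {2⁻⁵, 2⁻³, …, 2¹⁵} with seeded stratified 5-fold CV, ties to the
  smallest C. A kernel-width parameter is deliberately dropped: it is inert
  for the linear kernel. The SVM itself is LIBSVM's C-SVC via scikit-learn.
- Final signature: mRMR on the full training set, top-n (default 20), with
  per-fold selection frequencies reported alongside for transparency — the
  reduction from N differing per-fold selections to one signature is
  otherwise underdetermined. The accuracy-vs-size curve is always emitted;
  choosing compactness over marginal accuracy is user policy.

## Degree discriminant

Linear (pooled-covariance) Gaussian discriminant, priors equal by default
(balanced 50/50 degree design; proportional optional and logged). Features
are log2 ratios (Gaussian assumption more plausible than raw ratios). The
pooled covariance uses denominator n − k; if Cholesky fails, a ridge
λ·trace/p·I is added with λ escalating from 1e−8 and recorded on the model.
Exact posterior ties go to degree I. "Original" = resubstitution,
"cross-validated" = leave-one-out refits.

## Rank-sum and age tests

Mann-Whitney U is exact by full enumeration when combined n ≤ 20 without
ties, otherwise the tie-corrected normal approximation; the method used is
recorded. Age groups for the ANOVA are sample quartiles (boundaries
reported); a gene is flagged if either the Pearson or the ANOVA p falls
below α.

## Orchestration

The train/test split is per-pair (both samples of a pair stay on one side),
seeded and recorded; an explicit split with overlapping pairs is rejected at
config validation. The run manifest records the resolved config, the split,
normalization constants, SHA-256 checksums of all artifacts, and the
assertion that test pairs were untouched before evaluation. Identical
configs reproduce artifacts bit-for-bit.

## Problem sizes used in the checks

The end-to-end checks run at the study's own scale where that scale is the
claim: the differential-recovery and effect-size experiments use 100 pairs ×
169 genes, and the signature-sweep count uses 160 samples × sizes 1–50
(8000 models, ~30 s). Property suites (null calibration over 200 cohorts,
optimism over 50 replicates, greedy-vs-brute-force agreement) use small
cohorts where the property is scale-free.

## What passing tests do and do not show

The synthetic cohort assumes independent genes, a single noise scale,
Gaussian log-ratios, and planted effects far from the decision thresholds
(except the published 0.48–0.49 down-regulated genes, which sit ~1 SEM from
the 0.5 cutoff — exact count recovery of the down set is therefore not
guaranteed on every seed, and the near-perfect LOOCV accuracies reflect the
essentially separable planted signal, not expected real-data performance).
Real cohorts add gene–gene correlation, batch structure, and intensity-
dependent artifacts that this generator deliberately does not model; results
on it validate the *procedures* (arithmetic, counts, leakage-freedom,
calibration), not clinical performance.
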