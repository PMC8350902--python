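# Methods

`taucompare` implements a complete comparison pipeline for the three
modalities used to measure tau pathology in Alzheimer's disease — tau PET
(aggregated, insoluble tau), CSF phosphorylated tau and plasma
phosphorylated tau (soluble tau) — exercised end-to-end on synthetic
memory-clinic cohorts with known ground truth. This note documents the
models, the defaults and their rationale, the numerical choices, and what
the synthetic experiments do and do not show about real cohort data.

## The synthetic cohort model

Real multimodal tau datasets are access-restricted, so the package ships a
generator whose statistical structure mirrors what the analysis stages are
designed to detect. Each participant carries a scalar latent disease stage
`D ∈ [0, 1]`; cognitively unimpaired (CU) participants draw `D ~ Beta(2, 5)`
and impaired participants `D ~ Beta(5, 2)`. Two logistic functions of `D`
create the cascade:

- **Amyloid burden** `A = σ(s·(D − 0.35) + 1.5·APOEε4)` rises *early*
  (midpoint 0.35, slope `s = 10`). The APOE ε4 logit shift of 1.5
  corresponds to roughly a four-fold odds increase of amyloid positivity in
  carriers, in line with epidemiological estimates. Ground-truth amyloid
  status thresholds this noise-free burden at 0.5, so status is unambiguous;
  the *observed* CSF Aβ42/40 ratio and amyloid PET SUVR add their own
  measurement noise on top of `A`.
- **Aggregated tau** `T = σ(s·(D − 0.65))` rises *late* (lag 0.30 after the
  amyloid midpoint); the entorhinal signal leads the temporal meta-ROI
  signal by 0.08 stage units, reflecting earlier involvement of entorhinal
  cortex.

Soluble tau is a *state* variable responding to upstream pathology:
`S = 0.80·(2A−1) + 0.25·age_z + ε`, `ε ~ N(0, 0.18)`. Age acts directly on
`S` (production increases with age) and nowhere else; APOE acts only through
amyloid (its canonical path — a direct APOE→soluble term exists in the
configuration but defaults to 0 so that switching off the amyloid→soluble
path really removes every fluid–amyloid association). Downstream
consequences — the four cognitive domain z-scores, MMSE, AD-signature
cortical thickness, hippocampal volume/TIV — are decreasing functions of `T`
only, with domain-specific loadings (memory 1.00, executive 0.90, language
0.85, visuospatial 0.70 of the base slope 0.70) and noise (0.60–0.80). The
visuospatial composite is deliberately the weakest and noisiest domain, as
in real cohorts; its verdict is the least stable one at demo scale, and the
headline checks therefore assert the pattern on the other cognitive
measures and report visuospatial alongside.

Observed markers are noisy transforms of the latents: PET SUVRs are affine
(`meta = 1.47 + 0.27·(2T−1) + noise`), fluid concentrations log-affine
(always positive, right-skewed, e.g. `CSF p-tau181 = 55·exp(0.85·(S + noise))`
pg/ml). The affine constants were chosen once so that the amyloid-negative
CU reference subgroup yields mean + 2 SD cut-offs near the familiar
published values (≈1.36 SUVR for the temporal meta-ROI, ≈1.48 for
entorhinal) and so that raw-scale correlations sit in the published range
(PET–fluid r ≈ 0.56 at large n; fluid–Aβ42/40 r ≈ −0.66). Plasma p-tau217
has an assay detection limit (default 1.4 pg/ml); values below it are set to
the lowest measurable value, and with the default disease mix ≈90% of
censored samples come from amyloid-negative participants.

Missingness has two components: MCAR deletion at rate 0.05 across the
imputable columns, and a *structural* rule — amyloid PET is never acquired
in dementia, so the scan is missing for the dementia sub-flag (by default
the most advanced 40% of impaired participants) and is never imputed.
Identifiers, group, amyloid status, age and sex are never deleted.

**What passing tests show and what they do not.** The generator produces the
qualitative differential structure (fluid markers tied to early features,
PET to late ones) by construction; recovery tests therefore validate that
the *inference machinery* detects a known structure at realistic effect
sizes, sample sizes and missingness — not that the structure holds in any
real population. Real data differ in ways the generator does not emulate:
assay batch effects, non-monotone trajectories, comorbid pathologies,
informative (MAR/MNAR) missingness beyond the structural amyloid rule, and
longitudinal dynamics.

## Cut-offs, concordance, correlations

Cut-offs are `mean + 2·SD` (sample SD, n−1) over a reference population —
the amyloid-negative CU subgroup — or externally supplied. A value is
positive strictly above the cut-off; a tie is negative, reading the cut-off
as the upper envelope of the reference distribution. Concordance of two
dichotomized markers is the percentage of agreeing complete pairs in the
2×2 quadrant table; both discordance percentages are always reported, and
pairs with a missing call are excluded and counted. Correlation matrices
use pairwise-complete Pearson coefficients (≥3 complete pairs required; a
constant variable yields a flagged cell, never a silent NaN). Amyloid PET
SUVR converts to Centiloids by the tracer-specific lines
`196.9·SUVR − 196.03` (florbetapir) and `159.08·SUVR − 151.65`
(florbetaben).

## Multiple imputation

Chained equations with predictive mean matching (PMM): columns are visited
in order of ascending missingness; each incomplete column is regressed on
all other imputable columns, coefficients receive a Bayesian posterior draw
(`σ²* = SSE/χ²_{n−p}`, `β* ~ N(β̂, σ²*(XᵀX)⁻¹)`), and each missing cell
takes the observed value of one of the 5 donors whose predictions (under
`β̂`) are nearest the cell's prediction (under `β*`). Five sweeps per chain,
25 independent chains by default (m is configurable; the demo configuration
uses m = 5). The initial fill draws randomly from each column's observed
values. Binary columns ride the same PMM machinery on a 0/1 coding — donors
guarantee the fill stays in {0, 1}. The inner solve adds a tiny ridge term
(10⁻⁶ of the mean Gram diagonal) so collinear predictor sets remain
solvable. Structurally missing columns are excluded entirely. No Rubin
pooling is performed: the downstream bootstrap consumes the m tables
directly.

## The ridge comparison engine

For each AD-related feature three standardized ridge models are fitted:
feature ~ fluid marker, feature ~ PET marker, and feature ~ both, always
adjusting for age and sex, plus education for cognitive outcomes (age drops
out of the covariates when it is the outcome). All variables are
standardized to mean 0, SD 1 (sample SD) per fitted dataset, so coefficients
are standardized β and the intercept vanishes; the solver is the penalized
normal equations `(XᵀX + λI)β = Xᵀy`.

**Penalty selection.** λ is chosen once per (outcome, model) by 10-fold
cross-validation on the row-stacked imputed tables over the grid
{0, 0.1, 1, 10, 100, 1000}, using the 1-SE rule (the largest λ whose CV
error is within one standard error of the minimum — the `lambda.1se`
convention of penalized-regression practice). The 1-SE choice matters for
inference: with the CV-minimum λ (≈2% shrinkage), the split of the combined
model's coefficients between two highly correlated tau markers is dominated
by cohort-level sampling noise, and the verdict rule below then reports a
spurious asymmetry for markers with identical true effects in ~20% of null
cohorts; the 1-SE penalty stabilizes the split (≤ a few percent false
asymmetry) without affecting recovery of true differential effects. Because
λ is selected on m stacked tables but applied to single-table fits, it is
rescaled by `n_table / n_stacked` (penalty per observation). The covariates
are penalized like the tau predictors (uniform λ). The ridge-vs-OLS
prediction check uses the plain CV minimum instead — there the target is
predictive accuracy, not coefficient stability.

**Bootstrap.** B = 1000 replicates by default; replicate b resamples rows
(with replacement) of imputed table `b mod m`, so imputation and sampling
uncertainty both enter the percentile 95% CIs. The same row indices drive
all three models within a replicate; standardization and λ stay fixed at
their full-data values so β draws are comparable across replicates. A
resample that leaves any predictor constant is redrawn and counted. When
the outcome is amyloid PET, standardization and resampling are restricted
to rows with an observed scan (the structurally missing cells are never
imputed). If both simple-model CIs cross zero, the feature is associated
with neither marker and the combined model is not fitted.

**Verdict rule**, evaluated in order (first firing criterion recorded):
(i) disjoint simple-model CIs → the modality with larger |median β| is
stronger; (ii) exactly one modality's CI excludes zero in its simple *or*
combined model (the "either" reading; configurable to simple-only or
combined-only) → that modality; (iii) exactly one modality shows a
significant simple→combined drop (disjoint simple vs combined CIs) → the
*other* modality; otherwise the modalities are comparable. The percent
change of each median β from simple to combined
(`100·(combined − simple)/|simple|`) is reported with every verdict.
Binary outcomes (APOE carriership, amyloid status) run through the same
machinery as 0/1 outcomes.

## Bagged regression trees and variable importance

Trees grow by greedy binary recursive partitioning: exhaustive search over
all (variable, midpoint-between-consecutive-distinct-values) splits
minimizing the summed child SSE, with ties going to the lower variable
index and lower threshold; leaves predict their training mean. Growth stops
below 2·`min_node` rows (default 20) or when the best decrease falls under
1% of the root SSE. Pruning is cost-complexity (weakest-link) with the
penalty chosen by 10-fold cross-validation at the candidate values given by
geometric means of consecutive critical α's; the 1-SE rule again
operationalizes "ties go to the smaller tree". Bagging aggregates 25
grown-and-pruned trees on bootstrap resamples; out-of-bag indices are kept
per tree. Missing values are never handled inside trees (no surrogate
splits) — trees consume imputed tables.

The variable importance measure (VIM) of a predictor is its summed SSE
decrease over all splits, averaged over the bagged trees and divided by the
full-sample root SSE. This is a documented, reproducible convention chosen
because published VIM axes depend on library-specific rescaling; only ranks
and relative magnitudes are treated as comparable across conventions.
Across m imputed tables the per-table VIMs form the reported distribution
(median, 2.5/97.5 percentiles, median-based ranks with alphabetical
tie-break).

## Pipeline, seeds, problem sizes

`run_full` sequences generate → censor → missingness → cut-offs/concordance
→ correlations → impute → ridge verdicts → tree VIMs under one global seed;
every stage derives its own substream (`default_rng([seed, stage])`), so
identical configurations give byte-identical artifacts and report digests.
The demo configuration (n = 400 participants, B = 200 bootstrap replicates,
m = 5 imputations, 25 trees) runs in well under a minute on one core; the
full-scale configuration (B = 1000, m = 25) in about one minute. The test
suite's Monte-Carlo experiments use 100 cohorts of n = 400 for verdict
recovery and calibration, 500 replications for bootstrap CI coverage, and
25 pipeline runs for VIM rank stability — sizes chosen to keep the whole
suite comfortably reproducible on a laptop while leaving the binomial
uncertainty of each estimated rate well inside the asserted margins.

## Known limitations

- The generator's single-stage cascade cannot represent discordant
  biologies (e.g. primary age-related tauopathy, non-AD neurodegeneration).
- MCAR + one structural rule is a simplification of real missingness.
- Censoring applies only to plasma p-tau217, per the assay that motivated
  it.
- The verdict rule inherits the discreteness of interval-overlap logic:
  near-boundary configurations can flip between adjacent categories under
  resampling; the percent-change values provide the continuous companion
  measure.
- Trees use exhaustive midpoint splits on numeric predictors only;
  categorical predictors must be pre-coded.
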