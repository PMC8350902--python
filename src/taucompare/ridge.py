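"""Ridge regression comparison of tau-biomarker modalities.

For each Alzheimer-related feature, three standardized ridge models are
fitted: the feature predicted by the fluid marker alone (simple), by the PET
marker alone (simple), and by both (combined), always adjusted for age and
sex (plus education for cognitive outcomes). Percentile 95% confidence
intervals of the standardized coefficients are obtained by bootstrapping rows
with replacement across the multiply-imputed tables, and a three-criterion
rule turns the interval geometry into a verdict on which modality is more
strongly associated with the feature:

(i)   disjoint simple-model CIs -> the modality with the larger |median|;
(ii)  CI excluding zero (simple or combined) for exactly one modality ->
      that modality;
(iii) a significant simple-to-combined drop (disjoint simple vs combined CI)
      for exactly one modality -> the *other* modality;
otherwise the modalities are called comparable. If both simple CIs cross
zero the feature is associated with neither and no combined model is fitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .impute import ImputedSet

logger = logging.getLogger(__name__)

FLUID = "FLUID"
PET = "PET"

NEITHER = "NEITHER"
COMPARABLE = "COMPARABLE"
FLUID_STRONGER = "FLUID_STRONGER"
PET_STRONGER = "PET_STRONGER"

COGNITIVE_OUTCOMES = {"mmse", "mem_z", "lang_z", "exec_z", "visuo_z"}

#: default penalty grid for cross-validated selection (Gram-matrix units)
LAMBDA_GRID = (0.0, 0.1, 1.0, 10.0, 100.0, 1000.0)


@dataclass(frozen=True)
class ModelSpec:
    """One regression model: outcome ~ tau predictor(s) + covariates."""

    outcome: str
    tau_predictors: tuple[str, ...]
    covariates: tuple[str, ...]
    restrict_to_amyloid_pet_available: bool = False

    def __post_init__(self) -> None:
        if not self.tau_predictors:
            raise ValueError("tau_predictors must be non-empty")
        if self.outcome in self.covariates:
            raise ValueError(f"outcome {self.outcome!r} cannot be a covariate")

    @property
    def predictors(self) -> tuple[str, ...]:
        return self.tau_predictors + self.covariates


def default_covariates(outcome: str) -> tuple[str, ...]:
    """Age and sex, plus education for cognitive outcomes; never the outcome itself."""
    covs = ["age", "sex"]
    if outcome in COGNITIVE_OUTCOMES:
        covs.append("education")
    return tuple(c for c in covs if c != outcome)


def make_specs(outcome: str, fluid: str, pet: str,
               restrict: bool | None = None) -> dict[str, ModelSpec]:
    """Build the simple-fluid / simple-PET / combined spec triple for one outcome.

    ``restrict`` forces bootstrap resampling to rows with observed amyloid
    PET; it defaults to True when the outcome is amyloid PET itself.
    """
    if restrict is None:
        restrict = outcome == "amyloid_pet"
    covs = default_covariates(outcome)
    return {
        "simple_fluid": ModelSpec(outcome, (fluid,), covs, restrict),
        "simple_pet": ModelSpec(outcome, (pet,), covs, restrict),
        "combined": ModelSpec(outcome, (fluid, pet), covs, restrict),
    }


@dataclass
class RidgeFit:
    """A standardized ridge fit; intercept is zero by construction."""

    lambda_: float
    beta_std: dict[str, float]
    r_squared: float
    n: int
    intercept: float = 0.0


def _standardize(M: np.ndarray, names: Sequence[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = M.mean(axis=0)
    sd = M.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(f"zero-variance predictor(s): {[names[i] for i in zero]}")
    return (M - mean) / sd, mean, sd


def _encode(table: pd.DataFrame, columns: Sequence[str]) -> np.ndarray:
    """Numeric design matrix; sex is coded F=0, M=1."""
    out = np.empty((len(table), len(columns)))
    for j, c in enumerate(columns):
        col = table[c]
        if col.dtype == object:
            values = set(col.dropna().unique())
            if values <= {"F", "M"}:
                out[:, j] = (col == "M").astype(float)
            elif values <= {"POS", "NEG"}:
                out[:, j] = (col == "POS").astype(float)
            else:
                raise ValueError(f"cannot encode non-numeric column {c!r}")
        else:
            out[:, j] = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)
    return out


def ridge_solve(X: np.ndarray, y: np.ndarray, lambda_: float) -> np.ndarray:
    """Solve the penalized normal equations (X'X + lambda I) b = X'y as given.

    No standardization is applied; on an orthonormal design each coefficient
    is the OLS coefficient divided by (1 + lambda).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    p = X.shape[1]
    return np.linalg.solve(X.T @ X + lambda_ * np.eye(p), X.T @ y)


def fit_ridge(X: np.ndarray, y: np.ndarray, lambda_: float,
              names: Sequence[str] | None = None) -> RidgeFit:
    """Solve the standardized penalized normal equations (X'X + lambda I) b = X'y.

    Predictors and outcome are standardized to mean 0, SD 1 (sample SD), so
    the intercept vanishes and coefficients are standardized betas. At
    ``lambda_ = 0`` this is ordinary least squares.
    """
    if lambda_ < 0:
        raise ValueError("lambda must be non-negative")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    Xs, _, _ = _standardize(X, list(names))
    ys, _, _ = _standardize(y[:, None], ["outcome"])
    ys = ys[:, 0]
    beta = ridge_solve(Xs, ys, lambda_)
    resid = ys - Xs @ beta
    tss = float(ys @ ys)
    r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else 0.0
    return RidgeFit(lambda_=lambda_, beta_std=dict(zip(names, beta)), r_squared=r2,
                    n=len(y))


def select_lambda(X: np.ndarray, y: np.ndarray, grid: Sequence[float] = LAMBDA_GRID,
                  k_folds: int = 10, seed: int = 0, one_se: bool = True) -> float:
    """Pick the penalty by k-fold out-of-fold squared error.

    With ``one_se`` (default) the largest penalty whose cross-validated error
    lies within one standard error of the minimum wins (the ``lambda.1se``
    convention of penalized-regression practice, which stabilizes coefficient
    splits between correlated predictors); otherwise the exact minimizer,
    with ties going to the larger penalty. The fold split is seeded and
    fixed.
    """
    grid = sorted(set(float(g) for g in grid))
    if len(grid) < 1 or any(g < 0 for g in grid):
        raise ValueError("grid must contain non-negative values")
    if len(grid) == 1:
        return grid[0]
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < k_folds:
        raise ValueError(f"n={n} smaller than k_folds={k_folds}")
    rng = np.random.default_rng([seed, 3])
    order = rng.permutation(n)
    folds = np.array_split(order, k_folds)
    fold_mse = np.zeros((len(folds), len(grid)))
    for fi, fold in enumerate(folds):
        test = np.zeros(n, dtype=bool)
        test[fold] = True
        Xtr, ytr = X[~test], y[~test]
        mx, sx = Xtr.mean(0), Xtr.std(0, ddof=1)
        my, sy = ytr.mean(), ytr.std(ddof=1)
        sx = np.where(sx == 0, 1.0, sx)
        sy = sy if sy > 0 else 1.0
        Xs, ys = (Xtr - mx) / sx, (ytr - my) / sy
        Xt, yt = (X[test] - mx) / sx, (y[test] - my) / sy
        G = Xs.T @ Xs
        for gi, lam in enumerate(grid):
            beta = np.linalg.solve(G + lam * np.eye(p), Xs.T @ ys)
            fold_mse[fi, gi] = float(np.mean((yt - Xt @ beta) ** 2))
    mean = fold_mse.mean(axis=0)
    best = int(np.argmin(mean))
    if one_se:
        se = float(fold_mse[:, best].std(ddof=1) / np.sqrt(len(folds)))
        threshold = mean[best] + se
    else:
        threshold = mean[best] * (1 + 1e-12)
    return max(lam for gi, lam in enumerate(grid) if mean[gi] <= threshold)


@dataclass
class ModelDraws:
    """Bootstrap draws for one model of the triple."""

    spec: ModelSpec
    lambda_: float
    draws: dict[str, np.ndarray]  # per tau predictor -> B standardized betas
    r2_draws: np.ndarray

    def median(self, predictor: str) -> float:
        return float(np.median(self.draws[predictor]))

    def ci(self, predictor: str, level: float = 95.0) -> tuple[float, float]:
        half = (100.0 - level) / 2.0
        lo, hi = np.percentile(self.draws[predictor], [half, 100.0 - half])
        return float(lo), float(hi)


@dataclass
class BootstrapSummary:
    """Per-outcome bootstrap summaries for the model triple."""

    outcome: str
    fluid: str
    pet: str
    B: int
    models: dict[str, ModelDraws]
    n_redrawn: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for mname, md in self.models.items():
            for pred in md.spec.tau_predictors:
                lo, hi = md.ci(pred)
                rows.append({
                    "outcome": self.outcome, "model": mname, "predictor": pred,
                    "median": md.median(pred), "ci_lo": lo, "ci_hi": hi,
                    "lambda": md.lambda_, "B": self.B,
                    "r2_median": float(np.median(md.r2_draws)),
                })
        return pd.DataFrame(rows)


def _batched_ridge(Xs: np.ndarray, ys: np.ndarray, idx: np.ndarray,
                   lam: float) -> tuple[np.ndarray, np.ndarray]:
    """Fit ridge on each row-resample; returns (betas (B,p), r2 (B,))."""
    Xb = Xs[idx]            # (B, n, p)
    yb = ys[idx]            # (B, n)
    p = Xs.shape[1]
    G = np.einsum("bni,bnj->bij", Xb, Xb) + lam * np.eye(p)
    r = np.einsum("bni,bn->bi", Xb, yb)
    beta = np.linalg.solve(G, r[..., None])[..., 0]
    resid = yb - np.einsum("bnp,bp->bn", Xb, beta)
    tss = np.einsum("bn,bn->b", yb, yb)
    tss = np.where(tss == 0, 1.0, tss)
    r2 = 1.0 - np.einsum("bn,bn->b", resid, resid) / tss
    return beta, r2


def _draw_indices(rng: np.random.Generator, B: int, pool: np.ndarray,
                  check: np.ndarray, max_tries: int = 100) -> tuple[np.ndarray, int]:
    """Resample row indices, redrawing replicates that leave a predictor constant.

    ``check`` is the (n_pool, p) matrix whose columns must stay non-constant
    within each replicate. Returns (indices into the pool rows, redraw count).
    """
    n = len(pool)
    idx = rng.integers(n, size=(B, n))
    redrawn = 0
    for _ in range(max_tries):
        vals = check[idx]                       # (B, n, p)
        bad = (vals.min(axis=1) == vals.max(axis=1)).any(axis=1)
        if not bad.any():
            break
        redrawn += int(bad.sum())
        idx[bad] = rng.integers(n, size=(int(bad.sum()), n))
    else:
        raise RuntimeError("could not draw resamples without constant predictors")
    if redrawn:
        logger.warning("redrew %d bootstrap replicates with constant predictors", redrawn)
    return idx, redrawn


def bootstrap_models(imputed: ImputedSet, specs: dict[str, ModelSpec],
                     B: int = 1000, seed: int = 0,
                     lambda_grid: Sequence[float] = LAMBDA_GRID,
                     skip_combined_if_neither: bool = True) -> BootstrapSummary:
    """Bootstrap the simple/simple/combined triple over the imputed tables.

    Replicate ``b`` resamples rows (with replacement) of imputed table
    ``b mod m``; the same row indices are used for all models of the
    replicate. Each penalty is selected once per model by cross-validation on
    the row-stacked imputed data and held fixed across replicates. Variables
    are standardized per imputed table (full data), not per resample, so
    coefficients stay comparable across replicates. When the model spec
    restricts to rows with observed amyloid PET, both standardization and
    resampling use only those rows. If both simple-model CIs cross zero the
    combined model is not fitted.
    """
    for key in ("simple_fluid", "simple_pet", "combined"):
        if key not in specs:
            raise ValueError(f"specs must include {key!r}")
    outcome = specs["simple_fluid"].outcome
    if any(s.outcome != outcome for s in specs.values()):
        raise ValueError("all specs must share the outcome")
    fluid = specs["simple_fluid"].tau_predictors[0]
    pet = specs["simple_pet"].tau_predictors[0]
    m = imputed.m
    rng = np.random.default_rng([seed, 4])

    # per-table standardized design/outcome per model, plus the resampling pool
    restrict = specs["combined"].restrict_to_amyloid_pet_available
    stacked = imputed.stacked()
    if restrict:
        stacked = stacked[stacked["amyloid_pet"].notna()]

    lambdas: dict[str, float] = {}
    prepared: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {k: [] for k in specs}
    for key, spec in specs.items():
        Xst = _encode(stacked, spec.predictors)
        yst = _encode(stacked, [spec.outcome])[:, 0]
        lam_stacked = select_lambda(Xst, yst, lambda_grid, seed=seed)
        # the penalty is selected on m row-stacked tables but applied to
        # single-table fits: rescale to penalty-per-observation so shrinkage
        # strength does not grow with the number of imputations
        n_table = int((imputed.tables[0]["amyloid_pet"].notna()).sum()) if restrict \
            else len(imputed.tables[0])
        lambdas[key] = lam_stacked * n_table / len(stacked)
        for t in imputed.tables:
            tt = t[t["amyloid_pet"].notna()] if restrict else t
            X = _encode(tt, spec.predictors)
            y = _encode(tt, [spec.outcome])[:, 0]
            Xs, _, _ = _standardize(X, list(spec.predictors))
            ys, _, _ = _standardize(y[:, None], [spec.outcome])
            prepared[key].append((Xs, ys[:, 0]))

    # shared row indices per replicate (per source table)
    table_of_b = np.arange(B) % m
    n_rows = prepared["combined"][0][0].shape[0]
    # all predictors of the combined model cover the simple models' columns
    idx_by_table: dict[int, tuple[np.ndarray, np.ndarray, int]] = {}
    n_redrawn = 0
    draws: dict[str, dict[str, np.ndarray]] = {k: {} for k in specs}
    r2s: dict[str, np.ndarray] = {}
    for key in ("simple_fluid", "simple_pet", "combined"):
        spec = specs[key]
        beta_all = np.empty((B, len(spec.predictors)))
        r2_all = np.empty(B)
        for ti in range(m):
            sel = np.flatnonzero(table_of_b == ti)
            if sel.size == 0:
                continue
            Xs, ys = prepared[key][ti]
            if ti not in idx_by_table:
                sub_rng = np.random.default_rng([seed, 4, ti])
                Xc, _ = prepared["combined"][ti]
                idx, redrawn = _draw_indices(sub_rng, sel.size, np.arange(len(ys)), Xc)
                idx_by_table[ti] = (idx, sel, redrawn)
                n_redrawn += redrawn
            idx, sel_stored, _ = idx_by_table[ti]
            beta, r2 = _batched_ridge(Xs, ys, idx, lambdas[key])
            beta_all[sel] = beta
            r2_all[sel] = r2
        for j, pred in enumerate(spec.predictors):
            if pred in spec.tau_predictors:
                draws[key][pred] = beta_all[:, j]
        r2s[key] = r2_all

    models = {
        key: ModelDraws(spec=specs[key], lambda_=lambdas[key],
                        draws=draws[key], r2_draws=r2s[key])
        for key in specs
    }
    if skip_combined_if_neither:
        fl_lo, fl_hi = models["simple_fluid"].ci(fluid)
        pe_lo, pe_hi = models["simple_pet"].ci(pet)
        if fl_lo <= 0 <= fl_hi and pe_lo <= 0 <= pe_hi:
            models.pop("combined")
    return BootstrapSummary(outcome=outcome, fluid=fluid, pet=pet, B=B,
                            models=models, n_redrawn=n_redrawn)


@dataclass
class Verdict:
    outcome: str
    decision: str
    firing_criterion: str  # "i", "ii", "iii" or "none"
    percent_change_fluid: float
    percent_change_pet: float


def percent_change(simple_median_beta: float, combined_median_beta: float) -> float:
    """Percent change of the coefficient from the simple to the combined model."""
    if simple_median_beta == 0:
        raise ValueError("simple-model median beta is zero; percent change undefined")
    return 100.0 * (combined_median_beta - simple_median_beta) / abs(simple_median_beta)


def _excludes_zero(ci: tuple[float, float]) -> bool:
    return ci[0] > 0 or ci[1] < 0


def _disjoint(a: tuple[float, float], b: tuple[float, float]) -> bool:
    return a[0] > b[1] or b[0] > a[1]


def apply_criteria(summary: BootstrapSummary,
                   significance_rule: str = "either") -> Verdict:
    """Evaluate the three-criterion differential-association rule.

    ``significance_rule`` controls criterion (ii): whether a modality counts
    as significant when its CI excludes zero in the simple model, the
    combined model, or either (default).
    """
    if significance_rule not in ("simple", "combined", "either"):
        raise ValueError("significance_rule must be 'simple', 'combined' or 'either'")
    sf = summary.models["simple_fluid"]
    sp = summary.models["simple_pet"]
    fluid, pet = summary.fluid, summary.pet
    ci_f, ci_p = sf.ci(fluid), sp.ci(pet)
    med_f, med_p = sf.median(fluid), sp.median(pet)

    combined = summary.models.get("combined")
    if combined is None:
        if _excludes_zero(ci_f) or _excludes_zero(ci_p):
            raise ValueError("combined model missing although a simple CI excludes zero")
        return Verdict(summary.outcome, NEITHER, "none", np.nan, np.nan)

    ci_cf, ci_cp = combined.ci(fluid), combined.ci(pet)
    pc_f = percent_change(med_f, combined.median(fluid)) if med_f != 0 else np.nan
    pc_p = percent_change(med_p, combined.median(pet)) if med_p != 0 else np.nan

    if not _excludes_zero(ci_f) and not _excludes_zero(ci_p):
        return Verdict(summary.outcome, NEITHER, "none", pc_f, pc_p)

    # (i) disjoint simple CIs: the modality with the larger |median| wins
    if _disjoint(ci_f, ci_p):
        decision = FLUID_STRONGER if abs(med_f) > abs(med_p) else PET_STRONGER
        return Verdict(summary.outcome, decision, "i", pc_f, pc_p)

    # (ii) exactly one modality significant (simple and/or combined CI excludes 0)
    def significant(simple_ci, combined_ci):
        if significance_rule == "simple":
            return _excludes_zero(simple_ci)
        if significance_rule == "combined":
            return _excludes_zero(combined_ci)
        return _excludes_zero(simple_ci) or _excludes_zero(combined_ci)

    sig_f = significant(ci_f, ci_cf)
    sig_p = significant(ci_p, ci_cp)
    if sig_f != sig_p:
        decision = FLUID_STRONGER if sig_f else PET_STRONGER
        return Verdict(summary.outcome, decision, "ii", pc_f, pc_p)

    # (iii) a significant simple->combined drop for exactly one modality
    drop_f = _disjoint(ci_f, ci_cf)
    drop_p = _disjoint(ci_p, ci_cp)
    if drop_f != drop_p:
        decision = PET_STRONGER if drop_f else FLUID_STRONGER
        return Verdict(summary.outcome, decision, "iii", pc_f, pc_p)

    return Verdict(summary.outcome, COMPARABLE, "none", pc_f, pc_p)


def compare_r_squared(fit_a: RidgeFit, fit_b: RidgeFit) -> dict[str, float]:
    """Both simple-model R-squared values and their difference (a minus b)."""
    if fit_a.n != fit_b.n:
        raise ValueError("fits must be on identical rows")
    return {"r2_a": fit_a.r_squared, "r2_b": fit_b.r_squared,
            "difference": fit_a.r_squared - fit_b.r_squared}


def ridge_vs_ols_check(train: pd.DataFrame, test: pd.DataFrame, spec: ModelSpec,
                       lambda_grid: Sequence[float] = LAMBDA_GRID,
                       seed: int = 0) -> dict[str, float]:
    """Out-of-sample R-squared of cross-validated ridge vs plain OLS.

    Both arms are fitted on ``train`` (standardized there) and evaluated on
    ``test`` using the training standardization; R2 = 1 - RSS/TSS with TSS
    taken about the training mean. The penalty is the plain CV minimizer
    (prediction target), not the 1-SE choice used for coefficient inference.
    A singular OLS solve is reported as a failure of the OLS arm only (NaN).
    """
    Xtr = _encode(train, spec.predictors)
    ytr = _encode(train, [spec.outcome])[:, 0]
    Xte = _encode(test, spec.predictors)
    yte = _encode(test, [spec.outcome])[:, 0]
    lam = select_lambda(Xtr, ytr, lambda_grid, seed=seed,
                        k_folds=min(10, len(ytr)), one_se=False)
    mx, sx = Xtr.mean(0), Xtr.std(0, ddof=1)
    my, sy = ytr.mean(), ytr.std(ddof=1)
    if np.any(sx == 0) or sy == 0:
        raise ValueError("zero-variance variable in training data")
    Xs, ys = (Xtr - mx) / sx, (ytr - my) / sy
    Xt, yt = (Xte - mx) / sx, (yte - my) / sy
    p = Xs.shape[1]
    out = {"lambda": lam}
    for arm, l in (("ridge", lam), ("ols", 0.0)):
        G = Xs.T @ Xs + l * np.eye(p)
        if l == 0.0 and np.linalg.matrix_rank(Xs) < p:
            out["ols_r2"] = float("nan")
            continue
        beta = np.linalg.solve(G, Xs.T @ ys)
        rss = float(np.sum((yt - Xt @ beta) ** 2))
        tss = float(np.sum(yt ** 2))
        out[f"{arm}_r2"] = 1.0 - rss / tss if tss > 0 else 0.0
    return out
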