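"""Multiple imputation by chained equations with predictive mean matching.

Missing cells are filled by cycling through incomplete columns in order of
ascending missingness: each column is regressed on all other columns (current
working values), coefficients are perturbed by a draw from their Bayesian
posterior, and each missing cell receives the observed value of one of the
``pmm_donors`` donors whose predicted values lie nearest the cell's
prediction. The sweep is repeated ``n_iterations`` times, and the whole chain
is run ``m`` times independently to yield ``m`` completed tables. Columns
declared structurally missing (e.g. amyloid PET, which is never acquired in
dementia) are left untouched: imputing them would bias the sample toward the
non-dementia distribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import IMPUTABLE_COLUMNS, STRUCTURAL_COLUMNS


@dataclass
class ImputationConfig:
    m: int = 25
    n_iterations: int = 5
    pmm_donors: int = 5
    seed: int = 0
    #: columns excluded from imputation (left missing in every completed table)
    structurally_missing: list[str] = field(default_factory=lambda: list(STRUCTURAL_COLUMNS))
    #: columns eligible for imputation; others pass through unchanged
    imputable: list[str] = field(default_factory=lambda: list(IMPUTABLE_COLUMNS))
    #: ridge stabilization added to the inner normal equations (scaled by
    #: the mean diagonal of X'X) when the predictor set is near-collinear
    ridge_eps: float = 1e-6

    def __post_init__(self) -> None:
        if self.m < 1 or self.n_iterations < 1 or self.pmm_donors < 1:
            raise ValueError("m, n_iterations and pmm_donors must all be >= 1")


@dataclass
class ImputedSet:
    """``m`` completed copies of a participant table plus the original mask."""

    tables: list[pd.DataFrame]
    #: boolean frame, True where the input cell was missing
    missing_mask: pd.DataFrame
    config: ImputationConfig

    @property
    def m(self) -> int:
        return len(self.tables)

    def stacked(self) -> pd.DataFrame:
        """All m tables row-stacked (used for one-shot penalty selection)."""
        return pd.concat(self.tables, ignore_index=True)

    def save(self, directory: str | Path, prefix: str = "imputed") -> list[Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for i, t in enumerate(self.tables):
            p = directory / f"{prefix}_{i:02d}.csv"
            t.to_csv(p, index=False, na_rep="")
            paths.append(p)
        manifest = directory / f"{prefix}_mask.json"
        mask_cells = {
            col: self.missing_mask.index[self.missing_mask[col]].tolist()
            for col in self.missing_mask.columns if self.missing_mask[col].any()
        }
        manifest.write_text(json.dumps({"m": self.m, "missing_rows_by_column": mask_cells}, indent=2))
        paths.append(manifest)
        return paths


def load_imputed(directory: str | Path, prefix: str = "imputed",
                 config: ImputationConfig | None = None) -> ImputedSet:
    """Reload an :class:`ImputedSet` saved with :meth:`ImputedSet.save`."""
    directory = Path(directory)
    paths = sorted(directory.glob(f"{prefix}_[0-9][0-9].csv"))
    if not paths:
        raise FileNotFoundError(f"no {prefix}_NN.csv files under {directory}")
    from .cohort import read_cohort_csv

    tables = [read_cohort_csv(p) for p in paths]
    manifest = json.loads((directory / f"{prefix}_mask.json").read_text())
    mask = pd.DataFrame(False, index=tables[0].index, columns=tables[0].columns)
    for col, rows in manifest["missing_rows_by_column"].items():
        mask.loc[rows, col] = True
    return ImputedSet(tables=tables, missing_mask=mask,
                      config=config or ImputationConfig(m=len(tables)))


def _posterior_draw_lstsq(X: np.ndarray, y: np.ndarray, rng: np.random.Generator,
                          ridge_eps: float) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares fit with a Bayesian posterior draw of the coefficients.

    Returns (beta_hat, beta_star). The solve is ridge-stabilized: a small
    multiple of the mean Gram diagonal is added so collinear predictor sets
    (e.g. a binary column plus its duplicate) stay solvable.
    """
    n, p = X.shape
    G = X.T @ X
    lam = ridge_eps * max(np.trace(G) / p, 1e-12)
    G_reg = G + lam * np.eye(p)
    Xty = X.T @ y
    beta_hat = np.linalg.solve(G_reg, Xty)
    resid = y - X @ beta_hat
    dof = max(n - p, 1)
    sigma2 = float(resid @ resid) / dof
    # sigma^2* ~ SSE / chi2(dof); beta* ~ N(beta_hat, sigma^2* (X'X)^-1)
    sigma2_star = float(resid @ resid) / max(rng.chisquare(dof), 1e-12)
    cov = sigma2_star * np.linalg.inv(G_reg)
    # symmetrize against round-off before the Cholesky factorization
    cov = (cov + cov.T) / 2.0 + 1e-12 * np.eye(p)
    beta_star = beta_hat + np.linalg.cholesky(cov) @ rng.standard_normal(p)
    return beta_hat, beta_star


def _pmm_fill(pred_obs: np.ndarray, y_obs: np.ndarray, pred_mis: np.ndarray,
              donors: int, rng: np.random.Generator) -> np.ndarray:
    """Predictive mean matching: draw one of the ``donors`` nearest observed values."""
    k = min(donors, len(pred_obs))
    out = np.empty(len(pred_mis))
    for i, pm in enumerate(pred_mis):
        d = np.abs(pred_obs - pm)
        nearest = np.argpartition(d, k - 1)[:k]
        out[i] = y_obs[nearest[rng.integers(k)]]
    return out


def impute(table: pd.DataFrame, config: ImputationConfig) -> ImputedSet:
    """Run chained-equation multiple imputation on a participant table.

    Observed cells are preserved exactly in every completed table;
    structurally missing columns remain missing. Raises if any imputable
    column with missing cells has fewer than 10 observed values.
    """
    cfg = config
    cols = [c for c in cfg.imputable if c in table.columns and c not in cfg.structurally_missing]
    numeric = table[cols].apply(pd.to_numeric, errors="coerce")
    mask = numeric.isna()
    incomplete = [c for c in cols if mask[c].any()]
    for c in incomplete:
        n_obs = int((~mask[c]).sum())
        if n_obs == 0:
            raise ValueError(f"column {c!r} has no observed values")
        if n_obs < 10:
            raise ValueError(f"column {c!r} has fewer than 10 observed values ({n_obs})")
    full_mask = pd.DataFrame(False, index=table.index, columns=table.columns)
    full_mask[cols] = mask
    for c in cfg.structurally_missing:
        if c in table.columns:
            full_mask[c] = table[c].isna()

    if not incomplete:
        return ImputedSet(tables=[table.copy() for _ in range(cfg.m)],
                          missing_mask=full_mask, config=cfg)

    # visit order: ascending missingness, name as tie-break
    visit = sorted(incomplete, key=lambda c: (int(mask[c].sum()), c))
    # predictors: every imputable column other than the target
    binary = {c for c in cols if set(numeric[c].dropna().unique()) <= {0.0, 1.0}}

    completed_tables = []
    for rep in range(cfg.m):
        rng = np.random.default_rng([cfg.seed, 2, rep])
        work = numeric.copy()
        for c in incomplete:  # initial fill: random draws from the observed values
            obs = work.loc[~mask[c], c].to_numpy()
            work.loc[mask[c], c] = rng.choice(obs, size=int(mask[c].sum()), replace=True)
        for _ in range(cfg.n_iterations):
            for c in visit:
                others = [o for o in cols if o != c]
                X = work[others].to_numpy(dtype=float)
                X = np.column_stack([np.ones(len(X)), X])
                y = work[c].to_numpy(dtype=float)
                obs_idx = (~mask[c]).to_numpy()
                mis_idx = mask[c].to_numpy()
                beta_hat, beta_star = _posterior_draw_lstsq(
                    X[obs_idx], y[obs_idx], rng, cfg.ridge_eps)
                pred_obs = X[obs_idx] @ beta_hat
                pred_mis = X[mis_idx] @ beta_star
                filled = _pmm_fill(pred_obs, y[obs_idx], pred_mis, cfg.pmm_donors, rng)
                work.loc[mis_idx, c] = filled
        out = table.copy()
        for c in cols:
            out[c] = work[c].astype(float)
            if c in binary:
                out[c] = out[c].astype(int)
        completed_tables.append(out)
    return ImputedSet(tables=completed_tables, missing_mask=full_mask, config=cfg)
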