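"""Multiple imputation of weight and stature by predictive mean matching.

Chained equations: each incomplete variable is regressed on the predictor
set among currently-complete rows, regression parameters are perturbed by
a Bayesian draw (type-1 matching), each missing case is matched to the k
observed cases with the nearest predicted mean, and one donor's observed
value is imputed.  m independent chains give m completed tables; observed
cells are never altered, and every imputed value is a member of the
observed donor pool.

The imputation model's predictor pool is by default reduced to the
clinical variables, compartment areas, mean attenuations and the outcome:
a linear PMM model over the full 200+ radiomics pool is numerically
fragile when predictors outnumber complete cases.  The full pool can be
requested explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .cohort import COMPARTMENTS

__all__ = ["ImputationConfig", "ImputedSet", "ImputationError", "impute", "stack_or_iterate"]


class ImputationError(ValueError):
    pass


@dataclass
class ImputationConfig:
    m: int = 10
    k_donors: int = 5
    n_iterations: int = 20
    impute_columns: tuple[str, ...] = ("weight", "stature")
    predictor_columns: tuple[str, ...] | None = None  # None -> reduced default pool
    include_outcome: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.m < 2:
            raise ValueError(f"m must be >= 2, got {self.m}")
        if self.k_donors < 1:
            raise ValueError(f"k_donors must be >= 1, got {self.k_donors}")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class ImputedSet:
    """m completed feature tables, indexed by imputation number (1..m)."""

    tables: list[pd.DataFrame] = field(default_factory=list)

    @property
    def m(self) -> int:
        return len(self.tables)

    def to_long_frame(self) -> pd.DataFrame:
        out = []
        for i, t in enumerate(self.tables, start=1):
            t = t.copy()
            t.insert(0, "imp", i)
            out.append(t)
        return pd.concat(out, ignore_index=True)

    @classmethod
    def from_long_frame(cls, frame: pd.DataFrame) -> "ImputedSet":
        tables = [
            g.drop(columns="imp").reset_index(drop=True)
            for _, g in frame.groupby("imp", sort=True)
        ]
        return cls(tables=tables)


def _default_pool(table: pd.DataFrame, config: ImputationConfig) -> list[str]:
    pool = ["age", "sex_male"]
    for comp in COMPARTMENTS:
        for stat in ("area_cm2", "mean"):
            col = f"{comp}_{stat}"
            if col in table.columns:
                pool.append(col)
    if config.include_outcome and "excretion" in table.columns:
        pool.append("excretion")
    return [c for c in pool if c in table.columns]


def _pmm_step(
    y: np.ndarray,
    x: np.ndarray,
    miss: np.ndarray,
    k: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """One PMM draw for a single variable.

    Observed rows define the donor pool; the regression of y on x over
    observed rows is perturbed by the standard Bayesian draw (sigma^2 from
    the scaled inverse chi-square, beta from its normal approximation);
    predicted means use the posterior draw for missing rows and the
    least-squares fit for donors.
    """
    obs = ~miss
    x_obs = x[obs]
    y_obs = y[obs]
    n, p = x_obs.shape
    xtx = x_obs.T @ x_obs + 1e-8 * np.eye(p)
    xty = x_obs.T @ y_obs
    beta_hat = np.linalg.solve(xtx, xty)
    resid = y_obs - x_obs @ beta_hat
    dof = max(n - p, 1)
    sigma2 = float(resid @ resid) / rng.chisquare(dof)
    cov = sigma2 * np.linalg.inv(xtx)
    # symmetrize for Cholesky stability
    cov = 0.5 * (cov + cov.T) + 1e-12 * np.eye(p)
    beta_star = beta_hat + np.linalg.cholesky(cov) @ rng.standard_normal(p)
    yhat_obs = x_obs @ beta_hat
    yhat_mis = x[miss] @ beta_star
    imputed = np.empty(int(miss.sum()))
    kk = min(k, len(y_obs))
    for j, pred in enumerate(yhat_mis):
        d = np.abs(yhat_obs - pred)
        donors = np.argpartition(d, kk - 1)[:kk]
        imputed[j] = y_obs[rng.choice(donors)]
    return imputed


def impute(table: pd.DataFrame, config: ImputationConfig | None = None) -> ImputedSet:
    """Chained-equations PMM producing m completed tables.

    Missingness is expected only in the configured impute columns.  Each of
    the m chains runs ``n_iterations`` sweeps over the incomplete variables
    (each variable's model uses the other's current working values) and is
    driven by its own substream of the seed, so results are deterministic
    per seed and observed cells are bit-identical across tables.
    """
    config = config or ImputationConfig()
    config.validate()
    targets = [c for c in config.impute_columns if c in table.columns]
    miss = {c: table[c].isna().to_numpy() for c in targets}
    for c in targets:
        if miss[c].all():
            raise ImputationError(f"column {c!r} has no observed values to donate")
    pool = list(config.predictor_columns) if config.predictor_columns else _default_pool(table, config)
    pool = [c for c in pool if c not in targets]

    base_x = table[pool].to_numpy(dtype=float)
    if np.isnan(base_x).any():
        raise ImputationError("predictor pool contains missing values")
    tables = []
    master = np.random.SeedSequence(config.seed, spawn_key=(11,))
    for chain_seq in master.spawn(config.m):
        rng = np.random.default_rng(chain_seq)
        work = {c: table[c].to_numpy(dtype=float).copy() for c in targets}
        # initialise missing entries with random observed donors
        for c in targets:
            if miss[c].any():
                obs_vals = work[c][~miss[c]]
                work[c][miss[c]] = rng.choice(obs_vals, size=int(miss[c].sum()))
        any_missing = any(m_.any() for m_ in miss.values())
        n_iter = config.n_iterations if any_missing else 0
        for _ in range(n_iter):
            for c in targets:
                if not miss[c].any():
                    continue
                others = [o for o in targets if o != c]
                x = np.column_stack(
                    [np.ones(len(table)), base_x] + [work[o] for o in others]
                )
                work[c][miss[c]] = _pmm_step(work[c], x, miss[c], config.k_donors, rng)
        completed = table.copy()
        for c in targets:
            completed[c] = work[c]
        tables.append(completed)
    return ImputedSet(tables=tables)


def stack_or_iterate(
    imputed: ImputedSet, stage_fn: Callable[[pd.DataFrame], object]
) -> list[object]:
    """Apply a downstream stage to each completed table, preserving order."""
    return [stage_fn(t) for t in imputed.tables]
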