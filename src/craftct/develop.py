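"""Consensus-LASSO development of creatinine-excretion equations.

The procedure mirrors equation development on multiply imputed data:

1. subject-level 60/40 split into development and validation sets;
2. per imputation, LASSO over the standardized predictor pool with the
   penalty chosen by internal 10-fold cross-validation;
3. consensus: keep variables selected in *more than half* of the m
   imputations (strict);
4. backward elimination over the consensus set by least squares with
   10-fold cross-validation, fold assignment shared across imputations,
   choosing the subset with the lowest mean CV RMSE (ties broken toward
   fewer variables);
5. ordinary least squares per imputation on the raw predictor scales,
   coefficients and intercept pooled by averaging over imputations.

Two variable pools are used: the full clinical + radiomics pool, and the
same pool with weight and stature removed (for use when those are not
recorded).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold

from .cohort import predictor_columns

__all__ = [
    "DevelopmentConfig",
    "EquationSpec",
    "SelectionTrace",
    "DevelopmentError",
    "PredictionError",
    "split_development_validation",
    "lasso_support_per_imputation",
    "consensus_select",
    "backward_cv_select",
    "fit_and_pool",
    "develop_equation",
    "predict",
]

#: relative / absolute tolerance under which two CV RMSEs count as tied;
#: ties are resolved toward the smaller model
_TIE_RTOL = 1e-10
_TIE_ATOL = 1e-12


class DevelopmentError(RuntimeError):
    pass


class PredictionError(KeyError):
    pass


@dataclass
class DevelopmentConfig:
    variable_pool: str = "craft1"  # "craft1" = all; "craft2" = without weight/stature
    lasso_lambda_rule: str = "cv_min"  # or "cv_1se"
    n_folds: int = 10
    split_fraction: float = 0.6
    n_alphas: int = 100
    per_imputation_backward: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must be in (0, 1)")
        if self.variable_pool not in ("craft1", "craft2"):
            raise ValueError("variable_pool must be 'craft1' or 'craft2'")
        if self.lasso_lambda_rule not in ("cv_min", "cv_1se"):
            raise ValueError("lasso_lambda_rule must be 'cv_min' or 'cv_1se'")


@dataclass
class EquationSpec:
    """A fitted estimating equation in clinical units (mmol/day)."""

    name: str
    variables: list[str]
    coefficients: list[float]
    intercept: float
    provenance: str = ""
    coefficient_se: list[float] | None = None
    config_hash: str | None = None

    def __post_init__(self):
        if len(self.variables) != len(self.coefficients):
            raise ValueError("variables and coefficients must have equal length")
        if not all(np.isfinite(self.coefficients)) or not np.isfinite(self.intercept):
            raise ValueError("equation coefficients must be finite")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "EquationSpec":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class SelectionTrace:
    per_imputation_support: list[list[str]]
    consensus: list[str]
    backward_path: list[tuple[tuple[str, ...], float]] = field(default_factory=list)
    chosen: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_variables": [len(s) for s, _ in self.backward_path],
                "subset": ["|".join(s) for s, _ in self.backward_path],
                "mean_cv_rmse": [r for _, r in self.backward_path],
                "chosen": [s == self.chosen for s, _ in self.backward_path],
            }
        )


def pool_columns(table: pd.DataFrame, pool: str) -> list[str]:
    cols = predictor_columns(table)
    if pool == "craft2":
        cols = [c for c in cols if c not in ("weight", "stature")]
    return cols


def split_development_validation(
    table: pd.DataFrame, fraction: float = 0.6, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random subject-level split: all records of a subject land on one side.

    The development side receives round(fraction * n_subjects) subjects.
    """
    if table["subject_id"].nunique() < 10:
        raise ValueError("need at least 10 subjects to split")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(21,)))
    subjects = np.sort(table["subject_id"].unique())
    perm = rng.permutation(len(subjects))
    n_dev = int(round(fraction * len(subjects)))
    dev_subjects = set(subjects[perm[:n_dev]])
    in_dev = table["subject_id"].isin(dev_subjects)
    return (
        table[in_dev].reset_index(drop=True),
        table[~in_dev].reset_index(drop=True),
    )


def _standardize(x: np.ndarray):
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    keep = sd > 0
    return (x[:, keep] - mu[keep]) / sd[keep], keep


def lasso_support_per_imputation(
    tables: Sequence[pd.DataFrame],
    pool: Sequence[str],
    outcome: str = "excretion",
    config: DevelopmentConfig | None = None,
    alpha_override: float | None = None,
) -> list[list[str]]:
    """LASSO support (nonzero standardized coefficients) per imputed table.

    The penalty is chosen per imputation by internal K-fold CV on the
    standardized predictors, either at the CV-minimum or by the one-SE
    rule.  Constant predictors are dropped.  Fold assignment and the
    penalty grid are fixed by the seed and shared across imputations.
    """
    config = config or DevelopmentConfig()
    config.validate()
    supports = []
    cv = KFold(n_splits=config.n_folds, shuffle=True, random_state=config.seed % (2**31))
    for t in tables:
        x_raw = t[list(pool)].to_numpy(dtype=float)
        y = t[outcome].to_numpy(dtype=float)
        x, keep = _standardize(x_raw)
        names = [c for c, k in zip(pool, keep) if k]
        if alpha_override is not None:
            model = Lasso(alpha=alpha_override, max_iter=10000, tol=1e-4).fit(x, y)
            supports.append([n for n, c in zip(names, model.coef_) if abs(c) > 1e-10])
            continue
        with warnings.catch_warnings():
            # near-zero penalties at the bottom of the CV path routinely stop
            # at max_iter; the selected penalty is far from that regime
            warnings.simplefilter("ignore", ConvergenceWarning)
            model = LassoCV(
                cv=cv, alphas=config.n_alphas, max_iter=10000, tol=1e-4
            ).fit(x, y)
        alpha = float(model.alpha_)
        if config.lasso_lambda_rule == "cv_1se":
            mean_mse = model.mse_path_.mean(axis=1)
            se = model.mse_path_.std(axis=1, ddof=1) / np.sqrt(model.mse_path_.shape[1])
            i_min = int(np.argmin(mean_mse))
            limit = mean_mse[i_min] + se[i_min]
            # alphas_ is decreasing; the largest admissible penalty is first
            admissible = np.nonzero(mean_mse <= limit)[0]
            alpha = float(model.alphas_[admissible[0]])
            model = Lasso(alpha=alpha, max_iter=10000, tol=1e-4).fit(x, y)
        coef = model.coef_
        supports.append([n for n, c in zip(names, coef) if abs(c) > 1e-10])
    return supports


def consensus_select(supports: Sequence[Sequence[str]]) -> list[str]:
    """Variables selected in strictly more than half of the m supports."""
    m = len(supports)
    counts: dict[str, int] = {}
    order: dict[str, int] = {}
    for s in supports:
        for v in s:
            counts[v] = counts.get(v, 0) + 1
            order.setdefault(v, len(order))
    return sorted(
        [v for v, c in counts.items() if c > m / 2.0], key=lambda v: order[v]
    )


def _cv_rmse(
    xs: list[np.ndarray],
    ys: list[np.ndarray],
    folds: list[tuple[np.ndarray, np.ndarray]],
    cols: np.ndarray,
) -> float:
    """Mean over imputations and folds of the held-out RMSE of OLS."""
    total = 0.0
    count = 0
    for x, y in zip(xs, ys):
        xsub = x[:, cols]
        for tr, te in folds:
            a = np.column_stack([np.ones(len(tr)), xsub[tr]])
            b = np.column_stack([np.ones(len(te)), xsub[te]])
            beta, *_ = np.linalg.lstsq(a, y[tr], rcond=None)
            err = b @ beta - y[te]
            total += float(np.sqrt(np.mean(err**2)))
            count += 1
    return total / count


def backward_cv_select(
    tables: Sequence[pd.DataFrame],
    consensus_vars: Sequence[str],
    outcome: str = "excretion",
    config: DevelopmentConfig | None = None,
    supports: Sequence[Sequence[str]] | None = None,
) -> SelectionTrace:
    """Greedy backward elimination scored by cross-validated mean RMSE.

    From the full consensus set down to a single variable, each step drops
    the variable whose removal gives the lowest mean CV RMSE (averaged over
    folds and imputations; fold assignment fixed by the seed and shared
    across imputations).  The chosen subset is the path point with the
    global minimum; exact ties go to the smaller model.
    """
    config = config or DevelopmentConfig()
    config.validate()
    if not consensus_vars:
        raise DevelopmentError("consensus set is empty; nothing to select from")
    cols = list(consensus_vars)
    xs = [t[cols].to_numpy(dtype=float) for t in tables]
    ys = [t[outcome].to_numpy(dtype=float) for t in tables]
    n = len(ys[0])
    kf = KFold(n_splits=config.n_folds, shuffle=True, random_state=config.seed % (2**31))
    folds = [(tr, te) for tr, te in kf.split(np.arange(n))]

    active = list(range(len(cols)))
    path: list[tuple[tuple[str, ...], float]] = []
    path.append((tuple(cols), _cv_rmse(xs, ys, folds, np.array(active))))
    while len(active) > 1:
        best_drop, best_rmse = None, np.inf
        for v in active:
            cand = np.array([a for a in active if a != v])
            r = _cv_rmse(xs, ys, folds, cand)
            if r < best_rmse:
                best_drop, best_rmse = v, r
        active = [a for a in active if a != best_drop]
        path.append((tuple(cols[a] for a in active), best_rmse))

    best = min(r for _, r in path)
    tol = max(_TIE_ATOL, _TIE_RTOL * best)
    chosen = next(s for s, r in reversed(path) if r <= best + tol)
    trace = SelectionTrace(
        per_imputation_support=[list(s) for s in supports] if supports else [],
        consensus=list(consensus_vars),
        backward_path=path,
        chosen=chosen,
    )
    return trace


def fit_and_pool(
    tables: Sequence[pd.DataFrame],
    chosen_vars: Sequence[str],
    outcome: str = "excretion",
    name: str = "craft",
    provenance: str = "",
) -> EquationSpec:
    """OLS on raw scales per imputation; coefficients pooled by averaging.

    Pooled standard errors follow the usual combination of within-
    imputation variance and (1 + 1/m)-inflated between-imputation variance.
    """
    cols = list(chosen_vars)
    m = len(tables)
    betas, ses = [], []
    for t in tables:
        x = np.column_stack([np.ones(len(t)), t[cols].to_numpy(dtype=float)])
        y = t[outcome].to_numpy(dtype=float)
        if np.linalg.matrix_rank(x) < x.shape[1]:
            raise DevelopmentError(
                f"rank-deficient design; collinear variables among {cols}"
            )
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ beta
        dof = max(len(y) - x.shape[1], 1)
        sigma2 = float(resid @ resid) / dof
        cov = sigma2 * np.linalg.inv(x.T @ x)
        betas.append(beta)
        ses.append(np.sqrt(np.diag(cov)))
    betas = np.array(betas)
    ses = np.array(ses)
    pooled = betas.mean(axis=0)
    within = (ses**2).mean(axis=0)
    between = betas.var(axis=0, ddof=1) if m > 1 else np.zeros_like(pooled)
    total_se = np.sqrt(within + (1 + 1 / m) * between)
    return EquationSpec(
        name=name,
        variables=cols,
        coefficients=[float(b) for b in pooled[1:]],
        intercept=float(pooled[0]),
        provenance=provenance,
        coefficient_se=[float(s) for s in total_se],
    )


def develop_equation(
    tables: Sequence[pd.DataFrame],
    pool: str | Sequence[str] = "craft1",
    outcome: str = "excretion",
    config: DevelopmentConfig | None = None,
    name: str | None = None,
) -> tuple[EquationSpec, SelectionTrace]:
    """Full development procedure on m imputed development tables."""
    config = config or DevelopmentConfig()
    config.validate()
    if isinstance(pool, str):
        cols = pool_columns(tables[0], pool)
        pool_name = pool
    else:
        cols = list(pool)
        pool_name = config.variable_pool
    if pool_name == "craft2" or (isinstance(pool, str) and pool == "craft2"):
        assert not {"weight", "stature"} & set(cols)
    supports = lasso_support_per_imputation(tables, cols, outcome, config)
    consensus = consensus_select(supports)
    if not consensus:
        raise DevelopmentError("no variable reached the consensus threshold")
    trace = backward_cv_select(tables, consensus, outcome, config, supports=supports)
    cfg_hash = hashlib.sha256(
        json.dumps(dataclasses.asdict(config), sort_keys=True).encode()
    ).hexdigest()[:12]
    eq = fit_and_pool(
        tables, trace.chosen, outcome,
        name=name or pool_name.upper().replace("CRAFT", "CRAFT "),
        provenance=pool_name,
    )
    eq.config_hash = cfg_hash
    return eq, trace


def predict(equation: EquationSpec, features: pd.DataFrame | dict) -> np.ndarray | float:
    """intercept + X . beta, no clipping; missing features are an error."""
    if isinstance(features, dict):
        missing = [v for v in equation.variables if v not in features or
                   (isinstance(features[v], float) and np.isnan(features[v]))]
        if missing:
            raise PredictionError(f"missing feature(s) {missing} for {equation.name}")
        return float(
            equation.intercept
            + sum(c * features[v] for v, c in zip(equation.variables, equation.coefficients))
        )
    missing = [v for v in equation.variables if v not in features.columns]
    if missing:
        raise PredictionError(f"missing feature(s) {missing} for {equation.name}")
    x = features[equation.variables].to_numpy(dtype=float)
    if np.isnan(x).any():
        bad = [v for v in equation.variables if features[v].isna().any()]
        raise PredictionError(f"missing values in feature(s) {bad} for {equation.name}")
    return equation.intercept + x @ np.array(equation.coefficients)
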