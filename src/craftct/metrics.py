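"""Validation statistics for creatinine-excretion equations.

Bias is the mean prediction error (MPE, predicted minus observed,
mmol/day); precision is the R^2 of least-squares regression of observed on
predicted; accuracy is the RMSE, the mean absolute percentage error
(MAPE), and the percentage of predictions within 15% (p15) and 30% (p30)
of the observed value.

Confidence intervals combine bootstrap and multiple-imputation variance:
per imputation the metric's bootstrap variance is computed by resampling
records (1000 replicates by default); the pooled point estimate is the
mean over imputations and the total variance is the mean within-imputation
variance plus (1 + 1/m) times the between-imputation variance, with a
normal-approximation interval (z = 1.96 at the 95% level) — the same
normal approximation is applied to p15/p30.  Relative accuracy of two
equations is summarised by the paired-bootstrap CI of their RMSE
difference.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MetricConfig",
    "MetricReport",
    "point_metrics",
    "pooled_ci",
    "delta_rmse",
    "tertile_metrics",
    "intraindividual_variability",
    "evaluate_equations",
]

METRIC_NAMES = ("mpe", "r2", "rmse", "mape", "p15", "p30")


@dataclass
class MetricConfig:
    n_bootstrap: int = 1000
    ci_level: float = 0.95
    seed: int = 0
    use_percentile_bootstrap: bool = False

    def validate(self) -> None:
        if self.n_bootstrap < 100:
            raise ValueError("n_bootstrap must be >= 100")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")

    @property
    def z(self) -> float:
        return float(stats.norm.ppf(0.5 + self.ci_level / 2.0))


def _r2(pred: np.ndarray, obs: np.ndarray) -> float:
    # least-squares R^2 of observed vs predicted == squared Pearson r
    if pred.std() == 0.0 or obs.std() == 0.0:
        return 1.0 if np.allclose(pred - pred.mean(), obs - obs.mean()) else 0.0
    r = np.corrcoef(pred, obs)[0, 1]
    return float(r * r)


def point_metrics(pred, obs) -> dict[str, float]:
    """MPE, R^2, RMSE, MAPE, p15 and p30 of predicted vs observed excretion.

    Percentage thresholds are inclusive: a prediction exactly 15% off
    counts toward p15.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.size < 2:
        raise ValueError("pred and obs must be equal-length vectors of size >= 2")
    if (obs <= 0).any():
        raise ValueError("observed excretion must be > 0 for percentage metrics")
    err = pred - obs
    rel = np.abs(err) / obs
    return {
        "mpe": float(err.mean()),
        "r2": _r2(pred, obs),
        "rmse": float(np.sqrt(np.mean(err**2))),
        "mape": float(100.0 * rel.mean()),
        "p15": float(100.0 * (rel <= 0.15).mean()),
        "p30": float(100.0 * (rel <= 0.30).mean()),
    }


def _bootstrap_points(
    metric: str, pred: np.ndarray, obs: np.ndarray, idx: np.ndarray
) -> np.ndarray:
    """Metric on each bootstrap resample; ``idx`` is (n_boot, n)."""
    p = pred[idx]
    o = obs[idx]
    if metric == "mpe":
        return (p - o).mean(axis=1)
    if metric == "rmse":
        return np.sqrt(((p - o) ** 2).mean(axis=1))
    if metric == "mape":
        return 100.0 * (np.abs(p - o) / o).mean(axis=1)
    if metric == "p15":
        return 100.0 * ((np.abs(p - o) / o) <= 0.15).mean(axis=1)
    if metric == "p30":
        return 100.0 * ((np.abs(p - o) / o) <= 0.30).mean(axis=1)
    if metric == "r2":
        pc = p - p.mean(axis=1, keepdims=True)
        oc = o - o.mean(axis=1, keepdims=True)
        denom = np.sqrt((pc**2).sum(axis=1) * (oc**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, (pc * oc).sum(axis=1) / denom, 0.0)
        return r**2
    raise ValueError(f"unknown metric {metric!r}")


def _boot_indices(config: MetricConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, n, size=(config.n_bootstrap, n))


def pooled_ci(
    imputed_predictions,
    obs,
    metric: str,
    config: MetricConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, float, float]:
    """Pooled point estimate and CI of one metric over m imputations.

    Per imputation the point estimate and its bootstrap variance are
    computed; pooling follows the multiple-imputation rule
    T = mean(within) + (1 + 1/m) * var(between) with a normal interval.
    A zero total variance collapses the CI onto the point.
    """
    config = config or MetricConfig()
    config.validate()
    obs = np.asarray(obs, dtype=float)
    preds = [np.asarray(p, dtype=float) for p in imputed_predictions]
    m = len(preds)
    rng = rng or np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(31,)))
    idx = _boot_indices(config, len(obs), rng)
    points = np.array([point_metrics(p, obs)[metric] for p in preds])
    within = np.array(
        [np.var(_bootstrap_points(metric, p, obs, idx), ddof=1) for p in preds]
    )
    point = float(points.mean())
    if config.use_percentile_bootstrap:
        draws = np.concatenate([_bootstrap_points(metric, p, obs, idx) for p in preds])
        a = (1.0 - config.ci_level) / 2.0
        lo, hi = np.quantile(draws, [a, 1.0 - a])
        return point, float(lo), float(hi)
    between = float(points.var(ddof=1)) if m > 1 else 0.0
    total = float(within.mean()) + (1.0 + 1.0 / m) * between
    half = config.z * np.sqrt(total)
    return point, point - half, point + half


def delta_rmse(
    preds_a,
    preds_b,
    obs,
    config: MetricConfig | None = None,
    rng: np.random.Generator | None = None,
    paired: bool = True,
) -> tuple[float, float, float]:
    """RMSE(a) - RMSE(b) with a bootstrap + imputation CI.

    Paired by default: each replicate resamples records once and evaluates
    both equations on the same resample, so the CI reflects the accuracy
    *difference* rather than the two marginal accuracies.
    """
    config = config or MetricConfig()
    config.validate()
    obs = np.asarray(obs, dtype=float)
    pa = [np.asarray(p, dtype=float) for p in preds_a]
    pb = [np.asarray(p, dtype=float) for p in preds_b]
    if len(pa) != len(pb):
        raise ValueError("prediction sets must have the same number of imputations")
    for p in pa + pb:
        if p.shape != obs.shape:
            raise ValueError("predictions and observations must align record-wise")
    m = len(pa)
    rng = rng or np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(32,)))
    idx = _boot_indices(config, len(obs), rng)
    points, withins = [], []
    for a, b in zip(pa, pb):
        points.append(
            float(np.sqrt(np.mean((a - obs) ** 2)) - np.sqrt(np.mean((b - obs) ** 2)))
        )
        ra = _bootstrap_points("rmse", a, obs, idx)
        if paired:
            rb = _bootstrap_points("rmse", b, obs, idx)
        else:
            idx_b = _boot_indices(config, len(obs), rng)
            rb = _bootstrap_points("rmse", b, obs, idx_b)
        withins.append(float(np.var(ra - rb, ddof=1)))
    points = np.array(points)
    point = float(points.mean())
    between = float(points.var(ddof=1)) if m > 1 else 0.0
    total = float(np.mean(withins)) + (1.0 + 1.0 / m) * between
    half = config.z * np.sqrt(total)
    return point, point - half, point + half


def tertile_metrics(pred, obs) -> list[dict[str, float]]:
    """Point metrics within tertiles of observed excretion.

    Boundaries are the empirical 33.3%/66.7% quantiles of the observed
    values; observations tied with a boundary fall in the lower tertile.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if obs.size < 9:
        raise ValueError("tertile analysis needs at least 9 records")
    q1, q2 = np.quantile(obs, [1.0 / 3.0, 2.0 / 3.0])
    groups = np.where(obs <= q1, 0, np.where(obs <= q2, 1, 2))
    out = []
    for g in range(3):
        sel = groups == g
        rec = point_metrics(pred[sel], obs[sel])
        rec["n"] = int(sel.sum())
        rec["tertile"] = g + 1
        out.append(rec)
    return out


def intraindividual_variability(collections_by_subject: dict[str, list[float]]) -> float:
    """Mean over subjects of the per-subject sample SD of repeat collections.

    Subjects with fewer than two collections are excluded with a warning.
    """
    sds = []
    skipped = 0
    for values in collections_by_subject.values():
        if len(values) < 2:
            skipped += 1
            continue
        sds.append(float(np.std(values, ddof=1)))
    if skipped:
        warnings.warn(
            f"{skipped} subject(s) with a single collection excluded from "
            "intraindividual variability",
            stacklevel=2,
        )
    if not sds:
        raise ValueError("no subject has >= 2 collections")
    return float(np.mean(sds))


# ---------------------------------------------------------------------------
# report assembly


@dataclass
class MetricReport:
    """Per-equation metrics with CIs plus paired RMSE differences."""

    dataset: str
    n_records: int
    equations: dict[str, dict[str, tuple[float, float, float]]] = field(default_factory=dict)
    delta_rmse_vs_reference: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    reference: str = ""

    def validate(self) -> None:
        for name, rec in self.equations.items():
            for metric, (pt, lo, hi) in rec.items():
                assert lo <= pt + 1e-9 and pt <= hi + 1e-9, (name, metric)
            assert rec["p30"][0] >= rec["p15"][0] - 1e-9
            assert rec["rmse"][0] >= abs(rec["mpe"][0]) - 1e-9

    def to_json(self, path) -> None:
        payload = {
            "dataset": self.dataset,
            "n_records": self.n_records,
            "reference": self.reference,
            "equations": {
                name: {k: list(v) for k, v in rec.items()}
                for name, rec in self.equations.items()
            },
            "delta_rmse_vs_reference": {
                k: list(v) for k, v in self.delta_rmse_vs_reference.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    def to_text(self) -> str:
        lines = [
            f"Equation performance — {self.dataset} (n = {self.n_records})",
            f"{'Formula':<18}{'MPE':>20}{'R2':>20}{'RMSE':>20}"
            f"{'MAPE%':>22}{'P15%':>18}{'P30%':>18}",
        ]

        def fmt(v):
            return f"{v[0]:.2f} [{v[1]:.2f};{v[2]:.2f}]"

        for name, rec in self.equations.items():
            lines.append(
                f"{name:<18}{fmt(rec['mpe']):>20}{fmt(rec['r2']):>20}"
                f"{fmt(rec['rmse']):>20}{fmt(rec['mape']):>22}"
                f"{fmt(rec['p15']):>18}{fmt(rec['p30']):>18}"
            )
        for name, v in self.delta_rmse_vs_reference.items():
            lines.append(f"dRMSE {name} vs {self.reference}: {fmt(v)}")
        return "\n".join(lines)


def evaluate_equations(
    predictions_by_equation: dict[str, list[np.ndarray]],
    obs,
    dataset: str = "validation",
    reference: str | None = None,
    config: MetricConfig | None = None,
) -> MetricReport:
    """Full metric report for several equations on one dataset.

    ``predictions_by_equation`` maps equation name to its m per-imputation
    prediction vectors (a single vector is treated as m = 1).  The same
    bootstrap resamples are used for every equation, so RMSE differences
    are paired.
    """
    config = config or MetricConfig()
    config.validate()
    obs = np.asarray(obs, dtype=float)
    report = MetricReport(dataset=dataset, n_records=len(obs), reference=reference or "")
    norm = {
        name: [np.asarray(p, dtype=float) for p in (preds if isinstance(preds, (list, tuple)) else [preds])]
        for name, preds in predictions_by_equation.items()
    }
    for name, preds in norm.items():
        report.equations[name] = {
            metric: pooled_ci(preds, obs, metric, config, rng=np.random.default_rng(
                np.random.SeedSequence(config.seed, spawn_key=(33, METRIC_NAMES.index(metric)))
            ))
            for metric in METRIC_NAMES
        }
    if reference:
        for name, preds in norm.items():
            if name == reference:
                continue
            report.delta_rmse_vs_reference[name] = delta_rmse(
                preds, norm[reference], obs, config,
                rng=np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(34,))),
            )
    report.validate()
    return report
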