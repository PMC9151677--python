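"""Record-selection rules for 24-h urine creatinine measurements.

When plasma creatinine is not in steady state, excretion no longer equals
production: creatinine accumulates in (or drains from) its volume of
distribution.  The daily change in total body creatinine is

    dTBCr (mmol/day) = dPCr (mmol/L/day) * VD (L),    VD = 0.6 * weight

and records whose |dTBCr| exceeds 1.5 mmol/day are excluded, together with
biologically implausible collections (< 3 or > 30 mmol/day) and repeat
scans of the same subject within one week.  Consecutive collections are
averaged into a single outcome value.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import SubjectRecord

__all__ = [
    "FilterConfig",
    "FilterOutcome",
    "delta_tbcr",
    "plasma_slope",
    "average_consecutive",
    "dedup_scans",
    "apply_filters",
    "filtered_records",
    "outcomes_frame",
]


@dataclass
class FilterConfig:
    tbcr_limit: float = 1.5  # mmol/day
    excretion_min: float = 3.0  # mmol/day
    excretion_max: float = 30.0  # mmol/day
    vd_fraction: float = 0.6  # volume of distribution as fraction of weight
    dedup_window_days: int = 7
    slope_window_days: int = 14  # plasma measurements within +/- this of the scan
    slope_method: str = "least_squares"  # or "two_point"
    # conservative weight bound for records with missing weight: if even at
    # this weight the implied |dTBCr| stays under the limit, the record is
    # steady regardless of its true weight and need not be excluded
    max_plausible_weight: float = 150.0

    def validate(self) -> None:
        if not 0 < self.excretion_min < self.excretion_max:
            raise ValueError("need 0 < excretion_min < excretion_max")
        if not self.tbcr_limit > 0:
            raise ValueError("tbcr_limit must be > 0")
        if not 0 < self.vd_fraction <= 1:
            raise ValueError("vd_fraction must be in (0, 1]")


@dataclass
class FilterOutcome:
    record_id: str
    included: bool
    reasons: list[str] = field(default_factory=list)
    delta_tbcr: float | None = None
    excretion: float | None = None

    def __post_init__(self):
        assert self.included == (len(self.reasons) == 0)


def delta_tbcr(delta_pcr: float, weight: float, vd_fraction: float = 0.6) -> float:
    """Daily change in total body creatinine (mmol/day), sign preserved."""
    if not weight > 0:
        raise ValueError(f"weight must be > 0, got {weight}")
    return delta_pcr * (vd_fraction * weight)


def plasma_slope(
    series: Sequence[tuple[datetime.date, float]],
    scan_date: datetime.date,
    config: FilterConfig,
) -> float | None:
    """Estimated daily change in plasma creatinine (mmol/L/day).

    Least-squares slope over measurements within +/- ``slope_window_days``
    of the scan (the published selection window for collections); the
    two-point first/last difference is available as an option.  Returns
    None when fewer than two usable measurements exist.
    """
    pts = [
        (float((d - scan_date).days), v)
        for d, v in series
        if abs((d - scan_date).days) <= config.slope_window_days
    ]
    if len(pts) < 2:
        return None
    t = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if config.slope_method == "two_point":
        if t[-1] == t[0]:
            return None
        return float((y[-1] - y[0]) / (t[-1] - t[0]))
    t = t - t.mean()
    denom = float((t**2).sum())
    if denom == 0.0:
        return None
    return float((t * (y - y.mean())).sum() / denom)


def average_consecutive(collections: Iterable[tuple[datetime.date, float] | float]) -> float:
    """Mean of a record's consecutive 24-h collection values."""
    values = [c[1] if isinstance(c, tuple) else float(c) for c in collections]
    if not values:
        raise ValueError("record has no urine collections")
    return float(np.mean(values))


def dedup_scans(
    records: Sequence[SubjectRecord], window_days: int = 7
) -> tuple[list[SubjectRecord], set[str]]:
    """Drop repeat scans of a subject within the window, keeping the earliest.

    Greedy left-to-right chaining: after a retained scan, every scan of the
    same subject within ``window_days`` of the *last retained* scan is
    dropped; the next scan beyond the window is retained and restarts the
    chain.  Returns (retained records, dropped record ids).
    """
    dropped: set[str] = set()
    retained: list[SubjectRecord] = []
    by_subject: dict[str, list[SubjectRecord]] = {}
    for r in records:
        by_subject.setdefault(r.subject_id, []).append(r)
    order = {id(r): i for i, r in enumerate(records)}
    for recs in by_subject.values():
        recs = sorted(recs, key=lambda r: (r.scan_date, r.record_id))
        last_kept: datetime.date | None = None
        for r in recs:
            if last_kept is not None and (r.scan_date - last_kept).days <= window_days:
                dropped.add(r.record_id)
            else:
                retained.append(r)
                last_kept = r.scan_date
    retained.sort(key=lambda r: order[id(r)])
    return retained, dropped


def apply_filters(
    records: Sequence[SubjectRecord], config: FilterConfig | None = None
) -> list[FilterOutcome]:
    """Evaluate every selection rule and return one outcome per record.

    Exclusion reasons: ``nonsteady`` (|dTBCr| above the limit),
    ``nonsteady_unevaluable`` (plasma series present but weight missing, so
    dTBCr cannot be computed), ``implausible_low`` / ``implausible_high``
    (collection outside the plausible range), ``duplicate_window`` (repeat
    scan within the dedup window).  Records with an empty plasma series are
    taken as steady state (the donor situation).  Boundary values (exactly
    3, 30 or 1.5) are retained, matching the strict inequalities of the
    published rules.
    """
    config = config or FilterConfig()
    config.validate()
    _, dupes = dedup_scans(records, config.dedup_window_days)
    outcomes = []
    for r in records:
        reasons: list[str] = []
        dtbcr: float | None = None
        excretion = average_consecutive(r.urine_collections) if r.urine_collections else None
        if r.record_id in dupes:
            reasons.append("duplicate_window")
        slope = plasma_slope(r.plasma_series, r.scan_date, config) if r.plasma_series else None
        if slope is not None:
            if r.weight is None:
                # weight missing: the steady-state check is unevaluable unless
                # the drift is too small to matter at any plausible weight
                bound = abs(delta_tbcr(slope, config.max_plausible_weight, config.vd_fraction))
                if bound > config.tbcr_limit:
                    reasons.append("nonsteady_unevaluable")
            else:
                dtbcr = delta_tbcr(slope, r.weight, config.vd_fraction)
                if abs(dtbcr) > config.tbcr_limit:
                    reasons.append("nonsteady")
        if excretion is not None:
            if excretion < config.excretion_min:
                reasons.append("implausible_low")
            elif excretion > config.excretion_max:
                reasons.append("implausible_high")
        outcomes.append(
            FilterOutcome(
                record_id=r.record_id,
                included=not reasons,
                reasons=reasons,
                delta_tbcr=dtbcr,
                excretion=excretion,
            )
        )
    return outcomes


def filtered_records(
    records: Sequence[SubjectRecord], config: FilterConfig | None = None
) -> list[SubjectRecord]:
    """Records surviving every selection rule, in input order."""
    outcomes = apply_filters(records, config)
    keep = {o.record_id for o in outcomes if o.included}
    return [r for r in records if r.record_id in keep]


def outcomes_frame(outcomes: Sequence[FilterOutcome]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "record_id": [o.record_id for o in outcomes],
            "included": [o.included for o in outcomes],
            "reasons": ["|".join(o.reasons) for o in outcomes],
            "delta_tbcr": [o.delta_tbcr for o in outcomes],
            "excretion": [o.excretion for o in outcomes],
        }
    )
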