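"""Synthetic study populations with a known creatinine-production model.

The generator emulates the kind of single-center cohort used to develop
CT-based creatinine-excretion equations: adult patients (in- and
outpatients) with an abdominal CT scan and a 24-h urine collection within
two weeks of the scan, plus healthy kidney donors screened with 2-3
consecutive collections.

A single latent "muscle mass" factor drives both the body-composition
features (compartment areas and attenuations at the L3 level) and the true
daily creatinine production, so downstream development stages have a
recoverable ground truth.  Observed 24-h excretion is the truth plus
Gaussian collection noise, truncated away from zero so percentage errors
stay defined.

Units: age years, weight kg, stature cm, plasma creatinine mmol/L,
urinary excretion mmol/day, areas cm^2, attenuation HU.
"""

from __future__ import annotations

import dataclasses
import datetime
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortConfig",
    "SubjectRecord",
    "GroundTruth",
    "generate_cohort",
    "inject_missingness",
    "generate_plasma_series",
    "generate_donor_collections",
    "build_feature_table",
    "calibrate_truth",
    "CLINICAL_COLUMNS",
    "COMPARTMENTS",
    "RADIOMIC_STATS",
]

#: body compartments segmented at the L3 level
COMPARTMENTS = (
    "psoas",
    "long_spine",
    "abdominal_wall",
    "subcutaneous_fat",
    "visceral_fat",
)

#: first-order statistics reported per compartment HU distribution
RADIOMIC_STATS = (
    "p10", "p25", "p75", "p90",
    "kurtosis", "skewness",
    "mean", "median", "sd", "min", "max",
)

CLINICAL_COLUMNS = ("age", "sex_male", "weight", "stature")

#: reference day for converting day offsets to calendar dates
EPOCH = datetime.date(2015, 1, 1)

#: excretion floor keeping MAPE defined (mmol/day)
EXCRETION_FLOOR = 0.5


class ConfigError(ValueError):
    """Invalid cohort configuration; message names the offending field."""


@dataclass
class CohortConfig:
    """Parameters of the simulated study population.

    Defaults reproduce the published cohort's marginals: ~49% female,
    age 55 +/- 14 y, weight 78 +/- 18 kg, stature 173 +/- 10 cm and a mean
    24-h creatinine excretion of ~12 mmol/day (SD ~4.1) with the truth
    equation explaining ~60% of its variance.
    """

    n_subjects: int = 400
    frac_female: float = 0.49
    age_mean_sd: tuple[float, float] = (55.0, 14.0)
    weight_mean_sd: tuple[float, float] = (78.0, 18.0)
    stature_mean_sd: tuple[float, float] = (173.0, 10.0)
    true_support: tuple[str, ...] = ()
    true_coefficients: dict[str, float] = field(default_factory=dict)
    true_intercept: float = 12.0
    noise_sd: float = 2.6
    missing_rate_weight: float = 0.22
    missing_rate_stature: float = 0.09
    frac_nonsteady: float = 0.10
    frac_inpatient: float = 0.33
    donor_mode: bool = False
    intraindividual_sd: float = 1.47
    seed: int = 0
    # extra pure-noise texture columns, for high-dimensional experiments
    n_texture: int = 0
    # fraction of subjects with a second scan inside / beyond the dedup window
    frac_repeat_near: float = 0.05
    frac_repeat_far: float = 0.05
    # fraction of patients with two consecutive urine collections
    frac_two_collections: float = 0.15
    # correlation among radiomics nuisance columns is a modelling choice,
    # not a published quantity; it is controlled here
    radiomics_noise_sd: float = 1.5

    def validate(self) -> None:
        fracs = {
            "frac_female": self.frac_female,
            "missing_rate_weight": self.missing_rate_weight,
            "missing_rate_stature": self.missing_rate_stature,
            "frac_nonsteady": self.frac_nonsteady,
            "frac_inpatient": self.frac_inpatient,
            "frac_repeat_near": self.frac_repeat_near,
            "frac_repeat_far": self.frac_repeat_far,
            "frac_two_collections": self.frac_two_collections,
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {value}")
        if self.n_subjects < 1:
            raise ConfigError(f"n_subjects must be >= 1, got {self.n_subjects}")
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.intraindividual_sd < 0:
            raise ConfigError(
                f"intraindividual_sd must be >= 0, got {self.intraindividual_sd}"
            )
        for name in self.true_support:
            if name not in self.true_coefficients:
                raise ConfigError(
                    f"true_support entry {name!r} missing from true_coefficients"
                )

    @classmethod
    def default_study(cls, n_subjects: int = 400, seed: int = 0, **kw) -> "CohortConfig":
        """Patient-cohort config with a calibrated truth equation.

        The truth spans compartment areas, one attenuation and the clinical
        variables, scaled so that marginal excretion is ~12 +/- 4.1 mmol/day
        and the truth explains ~60% of its variance.
        """
        cfg = cls(n_subjects=n_subjects, seed=seed, **kw)
        return calibrate_truth(
            cfg,
            base_direction={
                "psoas_area_cm2": 0.25,
                "abdominal_wall_area_cm2": 0.08,
                "long_spine_mean": 0.06,
                "weight": 0.035,
                "age": -0.030,
                "sex_male": 1.0,
            },
            target_r2=0.60,
            target_mean=12.0,
            target_sd=4.1,
        )

    @classmethod
    def donor_study(cls, n_subjects: int = 287, seed: int = 0, **kw) -> "CohortConfig":
        """Kidney-donor config: mostly female, no missingness, steady-state,
        2-3 consecutive collections with intraindividual SD 1.47 mmol/day."""
        base = cls.default_study(n_subjects=n_subjects, seed=seed)
        return dataclasses.replace(
            base,
            donor_mode=True,
            frac_female=0.61,
            age_mean_sd=(54.0, 12.0),
            weight_mean_sd=(76.0, 12.0),
            stature_mean_sd=(172.0, 13.0),
            frac_nonsteady=0.0,
            frac_inpatient=0.0,
            missing_rate_weight=0.005,
            missing_rate_stature=0.005,
            frac_repeat_near=0.0,
            frac_repeat_far=0.0,
            **kw,
        )


@dataclass
class SubjectRecord:
    """One scan event: demographics, plasma series and urine collections."""

    subject_id: str
    record_id: str
    scan_date: datetime.date
    age: float
    sex: str  # "male" | "female"
    weight: float | None
    stature: float | None
    setting: str  # "inpatient" | "outpatient" | "donor"
    plasma_series: list[tuple[datetime.date, float]] = field(default_factory=list)
    urine_collections: list[tuple[datetime.date, float]] = field(default_factory=list)
    features: dict[str, float] = field(default_factory=dict)
    latent_muscle: float = 0.0  # truth only; never exposed downstream

    def validate(self) -> None:
        for _, v in self.plasma_series:
            if not v > 0:
                raise ValueError("plasma concentrations must be > 0")
        for _, v in self.urine_collections:
            if not v > 0:
                raise ValueError("urinary excretions must be > 0")
        for series in (self.plasma_series, self.urine_collections):
            days = [d for d, _ in series]
            if any(b <= a for a, b in zip(days, days[1:])):
                raise ValueError("dates within a series must be strictly increasing")


@dataclass
class GroundTruth:
    """The generating equation and each record's noiseless excretion."""

    variables: list[str]
    coefficients: list[float]
    intercept: float
    per_record_true_excretion: dict[str, float]

    def predict(self, features: dict[str, float]) -> float:
        return self.intercept + sum(
            c * features[v] for v, c in zip(self.variables, self.coefficients)
        )

    def to_equation(self):
        from .develop import EquationSpec

        return EquationSpec(
            name="truth",
            variables=list(self.variables),
            coefficients=list(self.coefficients),
            intercept=self.intercept,
            provenance="truth",
        )


# ---------------------------------------------------------------------------
# latent model


def _rng(config: CohortConfig, stage: int) -> np.random.Generator:
    """Per-stage substream derived from the master seed by a fixed key."""
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(stage,)))


def _draw_base_population(config: CohortConfig, rng: np.random.Generator):
    n = config.n_subjects
    female = rng.random(n) < config.frac_female
    age = np.clip(rng.normal(*config.age_mean_sd, n), 18.0, 90.0)
    # weight and stature share a Gaussian copula (r = 0.5); marginals as configured
    z1 = rng.standard_normal(n)
    z2 = 0.5 * z1 + math.sqrt(1 - 0.25) * rng.standard_normal(n)
    weight = np.clip(config.weight_mean_sd[0] + config.weight_mean_sd[1] * z1, 35.0, None)
    stature = np.clip(config.stature_mean_sd[0] + config.stature_mean_sd[1] * z2, 130.0, 215.0)
    sex_sign = np.where(female, -1.0, 1.0)
    z_age = (age - config.age_mean_sd[0]) / config.age_mean_sd[1]
    z_w = (weight - config.weight_mean_sd[0]) / config.weight_mean_sd[1]
    latent = 0.8 * sex_sign + 0.55 * z_w - 0.5 * z_age + 0.75 * rng.standard_normal(n)
    setting = np.where(
        female * 0 + (rng.random(n) < config.frac_inpatient), "inpatient", "outpatient"
    )
    if config.donor_mode:
        setting = np.full(n, "donor")
    return female, age, weight, stature, latent, setting, z_age, z_w, sex_sign


def _compartment_targets(config, rng, age, latent, z_w, sex_sign):
    """Per-subject target areas (cm^2) and mean attenuations (HU).

    Affine in the latent muscle factor; attenuation declines with age.
    Base values match the published compartment means/SDs (psoas 19+/-7,
    long spine 44+/-10, abdominal wall 68+/-20 cm^2; attenuations 44, 38,
    34 HU).
    """
    n = len(age)
    d_age = age - 55.0
    t = {}
    t["psoas_area_cm2"] = np.clip(18.5 + 4.8 * latent + rng.normal(0, 2.2, n), 2.0, None)
    t["long_spine_area_cm2"] = np.clip(44.0 + 6.8 * latent + rng.normal(0, 4.0, n), 5.0, None)
    t["abdominal_wall_area_cm2"] = np.clip(67.0 + 13.0 * latent + rng.normal(0, 8.0, n), 8.0, None)
    t["subcutaneous_fat_area_cm2"] = np.clip(
        180.0 + 60.0 * z_w - 20.0 * sex_sign + rng.normal(0, 40.0, n), 5.0, None
    )
    t["visceral_fat_area_cm2"] = np.clip(
        120.0 + 45.0 * z_w + 25.0 * sex_sign + 0.5 * d_age + rng.normal(0, 35.0, n), 5.0, None
    )
    t["psoas_mean"] = 44.0 - 0.25 * d_age + 2.0 * latent + rng.normal(0, 7.5, n)
    t["long_spine_mean"] = 38.0 - 0.30 * d_age + 2.2 * latent + rng.normal(0, 9.5, n)
    t["abdominal_wall_mean"] = 34.0 - 0.30 * d_age + 2.0 * latent + rng.normal(0, 9.5, n)
    t["subcutaneous_fat_mean"] = -100.0 + 3.0 * z_w + rng.normal(0, 8.0, n)
    t["visceral_fat_mean"] = -90.0 + rng.normal(0, 8.0, n)
    return t


def _nuisance_radiomics(config, rng, targets):
    """Remaining first-order statistics, derived from each compartment's mean
    attenuation and a per-subject dispersion; these are realistic correlated
    nuisance predictors, not part of the default truth support."""
    n = len(next(iter(targets.values())))
    s = config.radiomics_noise_sd
    cols = {}
    for comp in COMPARTMENTS:
        mean = targets[f"{comp}_mean"]
        disp = np.clip(rng.normal(12.0, 2.0, n), 4.0, None)
        cols[f"{comp}_sd"] = disp + rng.normal(0, 0.5 * s, n)
        cols[f"{comp}_median"] = mean + rng.normal(0, 0.7 * s, n)
        cols[f"{comp}_p10"] = mean - 1.2816 * disp + rng.normal(0, s, n)
        cols[f"{comp}_p25"] = mean - 0.6745 * disp + rng.normal(0, s, n)
        cols[f"{comp}_p75"] = mean + 0.6745 * disp + rng.normal(0, s, n)
        cols[f"{comp}_p90"] = mean + 1.2816 * disp + rng.normal(0, s, n)
        cols[f"{comp}_min"] = mean - 3.5 * disp + rng.normal(0, 2 * s, n)
        cols[f"{comp}_max"] = mean + 3.2 * disp + rng.normal(0, 2 * s, n)
        cols[f"{comp}_skewness"] = rng.normal(-0.3, 0.25, n)
        cols[f"{comp}_kurtosis"] = rng.normal(0.3, 0.35, n)
    return cols


def subject_feature_frame(config: CohortConfig) -> tuple[pd.DataFrame, dict]:
    """Draw the per-subject clinical + body-composition feature matrix.

    Returns the frame (one row per subject) and a dict of auxiliary arrays
    (latent factor, setting, sex flag) used by :func:`generate_cohort`.
    """
    rng = _rng(config, 1)
    female, age, weight, stature, latent, setting, z_age, z_w, sex_sign = (
        _draw_base_population(config, rng)
    )
    targets = _compartment_targets(config, rng, age, latent, z_w, sex_sign)
    frame = pd.DataFrame(
        {
            "age": age,
            "sex_male": (~female).astype(float),
            "weight": weight,
            "stature": stature,
            **targets,
            **_nuisance_radiomics(config, rng, targets),
        }
    )
    if config.n_texture:
        texture = pd.DataFrame(
            rng.standard_normal((config.n_subjects, config.n_texture)),
            columns=[f"texture_{k:03d}" for k in range(config.n_texture)],
        )
        frame = pd.concat([frame, texture], axis=1)
    aux = {"latent": latent, "setting": setting, "female": female}
    return frame, aux


# ---------------------------------------------------------------------------
# truth calibration


def calibrate_truth(
    config: CohortConfig,
    base_direction: dict[str, float],
    target_r2: float = 0.60,
    target_mean: float = 12.0,
    target_sd: float = 4.1,
    n_cal: int = 4000,
    cal_seed: int = 987_654,
) -> CohortConfig:
    """Scale a coefficient direction so the generated excretion hits the
    requested marginal mean/SD and truth R^2.

    A large calibration sample of features is drawn with a fixed internal
    seed; the direction is rescaled so sd(X beta) = target_sd * sqrt(R^2),
    the intercept centres the mean, and noise_sd = target_sd * sqrt(1-R^2).
    """
    if not 0 < target_r2 < 1:
        raise ConfigError(f"target_r2 must be in (0,1), got {target_r2}")
    probe = dataclasses.replace(
        config, n_subjects=n_cal, seed=cal_seed, donor_mode=False
    )
    frame, _ = subject_feature_frame(probe)
    x = frame[list(base_direction)].to_numpy()
    beta0 = np.array(list(base_direction.values()))
    s = x @ beta0
    scale = target_sd * math.sqrt(target_r2) / s.std(ddof=1)
    beta = beta0 * scale
    intercept = target_mean - float((x @ beta).mean())
    return dataclasses.replace(
        config,
        true_support=tuple(base_direction),
        true_coefficients={k: float(b) for k, b in zip(base_direction, beta)},
        true_intercept=float(intercept),
        noise_sd=float(target_sd * math.sqrt(1.0 - target_r2)),
    )


# ---------------------------------------------------------------------------
# record assembly


def _sd_bias_factor(k: int) -> float:
    """c4(k): E[sample SD] / sigma for normal samples of size k."""
    return math.sqrt(2.0 / (k - 1)) * math.gamma(k / 2.0) / math.gamma((k - 1) / 2.0)


def generate_donor_collections(
    record: SubjectRecord,
    k: int,
    intraindividual_sd: float,
    rng: np.random.Generator,
    true_excretion: float,
) -> SubjectRecord:
    """Attach k consecutive 24-h collections around the true excretion.

    The per-donor spread is inflated by 1/c4(k) so the *mean of per-donor
    sample SDs* — the statistic the study reports — is centred on
    ``intraindividual_sd`` despite the small-sample bias of the SD.
    """
    if k not in (2, 3):
        raise ValueError(f"donor collection count must be 2 or 3, got {k}")
    sigma = intraindividual_sd / _sd_bias_factor(k) if intraindividual_sd > 0 else 0.0
    values = np.maximum(true_excretion + rng.normal(0.0, sigma, k) if sigma else
                        np.full(k, true_excretion), EXCRETION_FLOOR)
    start = record.scan_date + datetime.timedelta(days=15)
    record.urine_collections = [
        (start + datetime.timedelta(days=i), float(v)) for i, v in enumerate(values)
    ]
    return record


def generate_plasma_series(
    record: SubjectRecord,
    nonsteady: bool,
    config: CohortConfig,
    rng: np.random.Generator,
) -> SubjectRecord:
    """Attach a plasma-creatinine series around the scan date.

    Steady subjects get a near-constant series (fitted daily change implies
    a change in total body creatinine well below the 1.5 mmol/day filter
    limit).  Non-steady subjects get a linear drift whose implied change
    exceeds that limit given their weight (60% of weight as the creatinine
    volume of distribution, in litres).
    """
    baseline = max(0.03, rng.normal(0.085, 0.015))
    days = np.array([-10, -6, -2, 0], dtype=float)
    if nonsteady:
        weight = record.weight if record.weight is not None else 78.0
        vd = 0.6 * weight
        slope = (1.5 / vd) * rng.uniform(1.3, 2.5) * (1 if rng.random() < 0.5 else -1)
    else:
        slope = 0.0
    # anchor a drifting series at its lowest end so it never hits the
    # positivity floor (which would flatten the fitted slope)
    start = baseline if slope >= 0 else baseline + abs(slope) * (days[-1] - days[0])
    values = start + slope * (days - days[0]) + rng.normal(0.0, 0.0008, len(days))
    values = np.maximum(values, 0.01)
    record.plasma_series = [
        (record.scan_date + datetime.timedelta(days=d), float(v))
        for d, v in zip(days, values)
    ]
    return record


def _observed_excretion(rng, truth_value, config) -> float:
    return float(
        max(truth_value + rng.normal(0.0, config.noise_sd) if config.noise_sd > 0
            else truth_value, EXCRETION_FLOOR)
    )


def generate_cohort(
    config: CohortConfig,
    feature_hook: Callable[[SubjectRecord], dict[str, float]] | None = None,
) -> tuple[list[SubjectRecord], GroundTruth]:
    """Simulate a cohort of scan events with known ground truth.

    ``feature_hook``, if given, maps a record (carrying the generator's
    target features) to the features actually used — e.g. by rendering a CT
    phantom and extracting features from it.  The truth equation is then
    applied to the hook's output, so truth holds exactly over whatever
    features downstream stages see.

    Returns complete records (no missingness); apply
    :func:`inject_missingness` for the MAR mechanism.
    """
    config.validate()
    frame, aux = subject_feature_frame(config)
    rng = _rng(config, 2)

    truth_vars = list(config.true_support)
    truth_beta = [config.true_coefficients[v] for v in truth_vars]
    records: list[SubjectRecord] = []
    true_excretion: dict[str, float] = {}

    n = config.n_subjects
    nonsteady_flags = rng.random(n) < config.frac_nonsteady
    repeat_draw = rng.random(n)
    k_collections = rng.integers(2, 4, size=n)  # donors: 2 or 3
    two_coll = rng.random(n) < config.frac_two_collections

    for i in range(n):
        subject_id = f"S{i:05d}"
        scan_date = EPOCH + datetime.timedelta(days=int(rng.integers(0, 1460)))
        base_feats = {c: float(frame.iloc[i][c]) for c in frame.columns}
        n_records = 1
        offset_days = 0
        if not config.donor_mode:
            if repeat_draw[i] < config.frac_repeat_near:
                n_records, offset_days = 2, int(rng.integers(2, 7))
            elif repeat_draw[i] < config.frac_repeat_near + config.frac_repeat_far:
                n_records, offset_days = 2, int(rng.integers(10, 60))
        for j in range(n_records):
            rec = SubjectRecord(
                subject_id=subject_id,
                record_id=f"{subject_id}R{j}",
                scan_date=scan_date + datetime.timedelta(days=j * offset_days),
                age=base_feats["age"],
                sex="male" if base_feats["sex_male"] == 1.0 else "female",
                weight=base_feats["weight"],
                stature=base_feats["stature"],
                setting=str(aux["setting"][i]),
                latent_muscle=float(aux["latent"][i]),
            )
            feats = dict(base_feats)
            if j > 0:  # repeat scan: body composition wobbles slightly
                for key in feats:
                    if key not in CLINICAL_COLUMNS and not key.startswith("texture"):
                        feats[key] += rng.normal(0.0, 0.3)
            rec.features = feats
            if feature_hook is not None:
                rec.features = {**feats, **feature_hook(rec)}
            truth_value = config.true_intercept + sum(
                b * rec.features[v] for v, b in zip(truth_vars, truth_beta)
            )
            true_excretion[rec.record_id] = truth_value
            if config.donor_mode:
                generate_donor_collections(
                    rec, int(k_collections[i]), config.intraindividual_sd, rng,
                    true_excretion=max(truth_value, EXCRETION_FLOOR),
                )
            else:
                n_coll = 2 if two_coll[i] else 1
                day0 = rec.scan_date + datetime.timedelta(days=int(rng.integers(-13, 14)))
                rec.urine_collections = [
                    (day0 + datetime.timedelta(days=t),
                     _observed_excretion(rng, truth_value, config))
                    for t in range(n_coll)
                ]
                generate_plasma_series(rec, bool(nonsteady_flags[i]), config, rng)
            rec.validate()
            records.append(rec)

    truth = GroundTruth(
        variables=truth_vars,
        coefficients=[float(b) for b in truth_beta],
        intercept=float(config.true_intercept),
        per_record_true_excretion=true_excretion,
    )
    return records, truth


def inject_missingness(
    records: Sequence[SubjectRecord], config: CohortConfig
) -> list[SubjectRecord]:
    """Set weight/stature to missing under a MAR mechanism.

    Missingness is logistic in setting and age (inpatients and older
    subjects more often lack a recorded weight); the intercept is solved so
    the realised marginal rate matches the configured one in expectation.
    Donor cohorts are forced below 1%.
    """
    for name, rate in (
        ("missing_rate_weight", config.missing_rate_weight),
        ("missing_rate_stature", config.missing_rate_stature),
    ):
        if not 0.0 <= rate <= 1.0:
            raise ConfigError(f"{name} must be in [0, 1], got {rate}")
    rng = _rng(config, 3)
    out = [dataclasses.replace(r, features=dict(r.features)) for r in records]
    inpat = np.array([r.setting == "inpatient" for r in out], dtype=float)
    age = np.array([r.age for r in out])
    lin = 0.9 * inpat + 0.025 * (age - age.mean())

    def mar_mask(rate: float) -> np.ndarray:
        if config.donor_mode:
            rate = min(rate, 0.005)
        if rate <= 0:
            return np.zeros(len(out), dtype=bool)
        if rate >= 1:
            return np.ones(len(out), dtype=bool)
        # solve the logistic intercept for the target marginal rate
        lo, hi = -20.0, 20.0
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            p = 1.0 / (1.0 + np.exp(-(mid + lin)))
            if p.mean() < rate:
                lo = mid
            else:
                hi = mid
        p = 1.0 / (1.0 + np.exp(-(0.5 * (lo + hi) + lin)))
        return rng.random(len(out)) < p

    for rec, miss in zip(out, mar_mask(config.missing_rate_weight)):
        if miss:
            rec.weight = None
            rec.features["weight"] = float("nan")
    for rec, miss in zip(out, mar_mask(config.missing_rate_stature)):
        if miss:
            rec.stature = None
            rec.features["stature"] = float("nan")
    return out


# ---------------------------------------------------------------------------
# feature table


def build_feature_table(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """One row per record: identifiers, outcome and predictors.

    The outcome column ``excretion`` is the mean of the record's (consecutive)
    24-h collections.  Missing weight/stature appear as NaN.
    """
    rows = []
    for r in records:
        row = {
            "record_id": r.record_id,
            "subject_id": r.subject_id,
            "scan_date": r.scan_date.isoformat(),
            "setting": r.setting,
            "excretion": float(np.mean([v for _, v in r.urine_collections]))
            if r.urine_collections else float("nan"),
        }
        row.update(r.features)
        row["weight"] = r.weight if r.weight is not None else float("nan")
        row["stature"] = r.stature if r.stature is not None else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def predictor_columns(table: pd.DataFrame) -> list[str]:
    """All predictor columns (clinical + body-composition + texture)."""
    meta = {"record_id", "subject_id", "scan_date", "setting", "excretion"}
    return [c for c in table.columns if c not in meta]
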