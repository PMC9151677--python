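"""End-to-end workflow: simulate, extract, filter, impute, develop, evaluate.

Stage order mirrors the published analysis: a patient cohort and a donor
cohort are simulated; per-record CT phantoms are rendered and features
extracted (threshold segmentation, areas, first-order radiomics); records
failing the creatinine mass-balance filter, plausibility bounds or the
one-week dedup rule are excluded; the patient table is split 60/40 by
subject; weight and stature are multiply imputed by PMM (m = 10) in the
development, validation and donor sets separately; two equations are
developed (full pool, and without weight/stature) by consensus LASSO plus
cross-validated backward elimination; and all equations plus the
Cockcroft-Gault and Ix comparators are evaluated with combined
bootstrap/imputation confidence intervals.

Every stage draws from a substream of one master seed, so a rerun with the
same config and seed is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .cohort import (
    CohortConfig,
    build_feature_table,
    generate_cohort,
    inject_missingness,
)
from .develop import DevelopmentConfig, EquationSpec, develop_equation, predict, split_development_validation
from .filters import FilterConfig, apply_filters, outcomes_frame
from .impute import ImputationConfig, ImputedSet, impute
from .metrics import MetricConfig, evaluate_equations, intraindividual_variability
from .phantom import SegmentationConfig, default_phantom_spec, extract_features, generate_phantom
from .reference import comparator_predictions

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("craftct")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    n_patients: int = 650
    n_donors: int = 290
    use_phantoms: bool = True
    phantom_spacing_mm: float = 2.0
    cohort: CohortConfig | None = None
    donor_cohort: CohortConfig | None = None
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    imputation: ImputationConfig = field(default_factory=ImputationConfig)
    development: DevelopmentConfig = field(default_factory=DevelopmentConfig)
    metrics: MetricConfig = field(default_factory=MetricConfig)
    seed: int = 0

    def resolve(self) -> "PipelineConfig":
        cfg = dataclasses.replace(self)
        seed = int(self.seed) % (2**31)
        if cfg.cohort is None:
            cfg.cohort = CohortConfig.default_study(n_subjects=cfg.n_patients, seed=seed)
        if cfg.donor_cohort is None:
            cfg.donor_cohort = CohortConfig.donor_study(n_subjects=cfg.n_donors, seed=seed + 1)
        cfg.imputation = dataclasses.replace(cfg.imputation, seed=seed + 2)
        cfg.development = dataclasses.replace(cfg.development, seed=seed + 3)
        cfg.metrics = dataclasses.replace(cfg.metrics, seed=seed + 4)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        kw = dict(data)
        for key, sub in (
            ("cohort", CohortConfig),
            ("donor_cohort", CohortConfig),
            ("segmentation", SegmentationConfig),
            ("filters", FilterConfig),
            ("imputation", ImputationConfig),
            ("development", DevelopmentConfig),
            ("metrics", MetricConfig),
        ):
            if key in kw and isinstance(kw[key], dict):
                kw[key] = sub(**kw[key])
        return cls(**kw)


def _phantom_hook(config: PipelineConfig, seed: int):
    """Per-record feature extraction from a rendered phantom.

    Compartment ellipse areas are scaled to each record's target areas and
    HU means set to its target attenuations, so extracted features track
    the cohort's latent body-composition model.
    """
    names = list(default_phantom_spec().compartments)
    names = [e.name for e in names]
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(41,)))

    def hook(record):
        t = record.features
        spec = default_phantom_spec(
            pixel_spacing_mm=config.phantom_spacing_mm,
            areas_cm2={name: max(t[f"{name}_area_cm2"], 1.0) for name in names},
            hu_means={name: t[f"{name}_mean"] for name in names},
        )
        stack = generate_phantom(spec, rng)
        return extract_features(stack, config.segmentation)

    return hook


def _stage(name: str, msg: str) -> None:
    print(f"[craftct:{name}] {msg}", file=sys.stderr)


def _impute_or_copy(table: pd.DataFrame, config: ImputationConfig) -> ImputedSet:
    return impute(table, config)


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute the full workflow and write all artifacts to ``outdir``.

    Returns a manifest dict (also written as ``manifest.json``) listing the
    seed, the config hash and the produced files.
    """
    cfg = config.resolve()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []

    def save(name: str):
        artifacts.append(name)
        return out / name

    stage = "simulate"
    try:
        hook = _phantom_hook(cfg, cfg.cohort.seed) if cfg.use_phantoms else None
        patients, truth = generate_cohort(cfg.cohort, feature_hook=hook)
        donor_hook = _phantom_hook(cfg, cfg.donor_cohort.seed) if cfg.use_phantoms else None
        donors, donor_truth = generate_cohort(cfg.donor_cohort, feature_hook=donor_hook)
        patients = inject_missingness(patients, cfg.cohort)
        donors = inject_missingness(donors, cfg.donor_cohort)
        _stage(stage, f"simulated {len(patients)} patient records, {len(donors)} donors")
        cio.write_cohort(patients, save("cohort_patients.csv"))
        cio.write_cohort(donors, save("cohort_donors.csv"))
        cio.write_ground_truth(truth, save("ground_truth_patients.json"))
        cio.write_ground_truth(donor_truth, save("ground_truth_donors.json"))

        stage = "filter"
        outcomes = apply_filters(patients, cfg.filters)
        outcomes_frame(outcomes).to_csv(save("filter_outcomes.csv"), index=False)
        keep = {o.record_id for o in outcomes if o.included}
        kept = [r for r in patients if r.record_id in keep]
        _stage(stage, f"retained {len(kept)}/{len(patients)} patient records")
        if len(kept) < 50:
            raise PipelineError("too few records survive filtering")

        stage = "features"
        table = build_feature_table(kept)
        donor_table = build_feature_table(donors)
        table.to_csv(save("features_patients.csv"), index=False)
        donor_table.to_csv(save("features_donors.csv"), index=False)

        stage = "split"
        dev, val = split_development_validation(
            table, cfg.development.split_fraction, cfg.development.seed
        )
        _stage(stage, f"development n={len(dev)}, validation n={len(val)}")

        stage = "impute"
        imp_dev = _impute_or_copy(dev, cfg.imputation)
        imp_val = _impute_or_copy(val, dataclasses.replace(cfg.imputation, seed=cfg.imputation.seed + 1))
        imp_don = _impute_or_copy(donor_table, dataclasses.replace(cfg.imputation, seed=cfg.imputation.seed + 2))
        imp_dev.to_long_frame().to_csv(save("imputed_development.csv"), index=False)

        stage = "develop"
        equations: dict[str, EquationSpec] = {}
        for pool, name in (("craft1", "CRAFT 1"), ("craft2", "CRAFT 2")):
            dev_cfg = dataclasses.replace(cfg.development, variable_pool=pool)
            eq, trace = develop_equation(imp_dev.tables, pool, config=dev_cfg, name=name)
            equations[name] = eq
            eq.to_json(save(f"equation_{pool}.json"))
            trace.to_frame().to_csv(save(f"selection_trace_{pool}.csv"), index=False)
            _stage(stage, f"{name}: {len(eq.variables)} variables {eq.variables}")

        stage = "evaluate"
        reports = {}
        for label, imp_set in (("validation", imp_val), ("donors", imp_don)):
            obs = imp_set.tables[0]["excretion"].to_numpy(dtype=float)
            preds = {}
            for name, eq in equations.items():
                preds[name] = [predict(eq, t) for t in imp_set.tables]
            cg, ix = [], []
            for t in imp_set.tables:
                comp = comparator_predictions(t)
                cg.append(comp["cockcroft_gault"])
                ix.append(comp["ix"])
            preds["Cockcroft-Gault"] = cg
            preds["Ix"] = ix
            report = evaluate_equations(
                preds, obs, dataset=label, reference="CRAFT 1", config=cfg.metrics
            )
            reports[label] = report
            report.to_json(save(f"metrics_{label}.json"))
        donor_collections = {
            r.subject_id: [v for _, v in r.urine_collections] for r in donors
        }
        intra = intraindividual_variability(donor_collections)
        with open(save("summary.txt"), "w") as fh:
            for report in reports.values():
                fh.write(report.to_text() + "\n\n")
            fh.write(f"Donor intraindividual SD: {intra:.3f} mmol/day\n")
        _stage(stage, f"donor intraindividual SD {intra:.3f} mmol/day")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "seed": cfg.seed,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "artifacts": sorted(artifacts),
        "intraindividual_sd": intra,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
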