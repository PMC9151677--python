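"""Tests of the synthetic-cohort generator: determinism, calibration of the
marginal distributions against the study's characteristics, the MAR
missingness mechanism, plasma-series construction and donor collections."""

import dataclasses
import io

import numpy as np
import pytest

from craftct.cohort import (
    CohortConfig,
    ConfigError,
    build_feature_table,
    generate_cohort,
    inject_missingness,
)
from craftct.filters import FilterConfig, plasma_slope
from craftct import io as cio


def _cohort_bytes(records) -> bytes:
    import tempfile, os

    with tempfile.NamedTemporaryFile("w", suffix=".csv", delete=False) as fh:
        path = fh.name
    try:
        cio.write_cohort(records, path)
        with open(path, "rb") as fh:
            return fh.read()
    finally:
        os.unlink(path)


def test_same_seed_gives_byte_identical_cohorts():
    cfg = CohortConfig.default_study(n_subjects=60, seed=1)
    a, _ = generate_cohort(cfg)
    b, _ = generate_cohort(cfg)
    assert _cohort_bytes(a) == _cohort_bytes(b)


def test_different_seed_changes_cohort():
    a, _ = generate_cohort(CohortConfig.default_study(n_subjects=60, seed=1))
    b, _ = generate_cohort(CohortConfig.default_study(n_subjects=60, seed=2))
    assert _cohort_bytes(a) != _cohort_bytes(b)


def test_zero_noise_excretion_equals_truth(clean_config):
    records, truth = generate_cohort(clean_config)
    for r in records:
        for _, v in r.urine_collections:
            assert v == pytest.approx(truth.per_record_true_excretion[r.record_id], abs=1e-12)


def test_truth_explains_configured_fraction_of_variance():
    """The calibration routine targets R^2 = 0.6 of truth vs observed."""
    cfg = CohortConfig.default_study(n_subjects=2000, seed=7)
    records, truth = generate_cohort(cfg)
    table = build_feature_table(records)
    tv = np.array([truth.per_record_true_excretion[r] for r in table.record_id])
    obs = table.excretion.to_numpy()
    r2 = np.corrcoef(tv, obs)[0, 1] ** 2
    assert 0.55 <= r2 <= 0.65


def test_marginals_match_configured_values_within_5pct():
    cfg = CohortConfig.default_study(n_subjects=1200, seed=3)
    records, _ = generate_cohort(cfg)
    t = build_feature_table(records)
    for col, (mean, sd) in (
        ("age", cfg.age_mean_sd),
        ("weight", cfg.weight_mean_sd),
        ("stature", cfg.stature_mean_sd),
        ("excretion", (12.0, 4.1)),
    ):
        assert t[col].mean() == pytest.approx(mean, rel=0.05)
        assert t[col].std() == pytest.approx(sd, rel=0.10)


def test_latent_muscle_correlations():
    """Latent factor rises with male sex and weight, falls with age."""
    records, _ = generate_cohort(CohortConfig.default_study(n_subjects=2000, seed=5))
    lat = np.array([r.latent_muscle for r in records])
    male = np.array([r.sex == "male" for r in records], dtype=float)
    age = np.array([r.age for r in records])
    weight = np.array([r.weight for r in records])
    assert np.corrcoef(lat, male)[0, 1] > 0.2
    assert np.corrcoef(lat, weight)[0, 1] > 0.2
    assert np.corrcoef(lat, age)[0, 1] < -0.2


@pytest.mark.parametrize(
    "rates, lo, hi",
    [((0.22, 0.09), (0.19, 0.06), (0.25, 0.12)), ((0.0, 0.0), (0.0, 0.0), (0.0, 0.0))],
)
def test_missingness_rates_within_binomial_bounds(rates, lo, hi):
    cfg = dataclasses.replace(
        CohortConfig.default_study(n_subjects=1000, seed=17),
        missing_rate_weight=rates[0],
        missing_rate_stature=rates[1],
    )
    records, _ = generate_cohort(cfg)
    masked = inject_missingness(records, cfg)
    rw = np.mean([r.weight is None for r in masked])
    rs = np.mean([r.stature is None for r in masked])
    assert lo[0] <= rw <= hi[0]
    assert lo[1] <= rs <= hi[1]


def test_donor_mode_forces_near_complete_data():
    cfg = CohortConfig.donor_study(n_subjects=500, seed=2)
    records, _ = generate_cohort(cfg)
    masked = inject_missingness(records, cfg)
    assert np.mean([r.weight is None for r in masked]) < 0.01
    assert np.mean([r.stature is None for r in masked]) < 0.01


def test_missingness_is_mar_in_setting():
    """Inpatients lose their weight record more often than outpatients."""
    cfg = dataclasses.replace(CohortConfig.default_study(n_subjects=2000, seed=23), frac_inpatient=0.5)
    masked = inject_missingness(*generate_cohort(cfg)[:1], cfg)
    inp = [r.weight is None for r in masked if r.setting == "inpatient"]
    out = [r.weight is None for r in masked if r.setting == "outpatient"]
    assert np.mean(inp) > np.mean(out)


def test_steady_plasma_series_stays_below_filter_limit(study_cohort):
    records, _ = generate_cohort(
        dataclasses.replace(CohortConfig.default_study(n_subjects=200, seed=31), frac_nonsteady=0.0)
    )
    fc = FilterConfig()
    for r in records:
        slope = plasma_slope(r.plasma_series, r.scan_date, fc)
        assert abs(slope) * 0.6 * r.weight < 1.5


def test_nonsteady_plasma_drift_exceeds_inverted_limit():
    """At VD = 0.6 * weight, the drift implies |dTBCr| > 1.5 mmol/day."""
    cfg = dataclasses.replace(CohortConfig.default_study(n_subjects=200, seed=37), frac_nonsteady=1.0)
    records, _ = generate_cohort(cfg)
    fc = FilterConfig()
    for r in records:
        slope = plasma_slope(r.plasma_series, r.scan_date, fc)
        assert abs(slope) >= 1.5 / (0.6 * r.weight) * 0.99


def test_series_dates_strictly_increasing(study_cohort):
    records, _ = study_cohort
    for r in records:
        for series in (r.plasma_series, r.urine_collections):
            days = [d for d, _ in series]
            assert all(b > a for a, b in zip(days, days[1:]))


def test_donor_collection_count_is_two_or_three():
    records, _ = generate_cohort(CohortConfig.donor_study(n_subjects=200, seed=5))
    counts = {len(r.urine_collections) for r in records}
    assert counts == {2, 3}


def test_zero_intraindividual_sd_gives_identical_collections():
    cfg = dataclasses.replace(CohortConfig.donor_study(n_subjects=50, seed=5), intraindividual_sd=0.0)
    records, _ = generate_cohort(cfg)
    for r in records:
        values = [v for _, v in r.urine_collections]
        assert len(set(values)) == 1


def test_mean_per_donor_sd_recovers_configured_value():
    """With sd = 1.47 and 500 donors, the mean of per-donor sample SDs lands
    in the simulation-derived band [1.30, 1.64]."""
    records, _ = generate_cohort(CohortConfig.donor_study(n_subjects=500, seed=13))
    sds = [np.std([v for _, v in r.urine_collections], ddof=1) for r in records]
    assert 1.30 <= np.mean(sds) <= 1.64


@pytest.mark.parametrize(
    "field, value, match",
    [
        ("frac_female", 1.5, "frac_female"),
        ("n_subjects", 0, "n_subjects"),
        ("noise_sd", -1.0, "noise_sd"),
        ("missing_rate_weight", -0.1, "missing_rate_weight"),
    ],
)
def test_invalid_config_errors_name_the_field(field, value, match):
    cfg = dataclasses.replace(CohortConfig.default_study(n_subjects=10, seed=0), **{field: value})
    with pytest.raises(ConfigError, match=match):
        generate_cohort(cfg)


def test_unknown_truth_variable_is_a_config_error():
    cfg = dataclasses.replace(
        CohortConfig(n_subjects=10), true_support=("nope",), true_coefficients={}
    )
    with pytest.raises(ConfigError, match="nope"):
        generate_cohort(cfg)
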