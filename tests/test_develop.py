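"""Equation development: subject-level splitting, LASSO supports, the
strict majority consensus rule, cross-validated backward elimination,
coefficient pooling and prediction."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from craftct.cohort import CohortConfig, build_feature_table, generate_cohort
from craftct.develop import (
    DevelopmentConfig,
    DevelopmentError,
    EquationSpec,
    PredictionError,
    backward_cv_select,
    consensus_select,
    develop_equation,
    fit_and_pool,
    lasso_support_per_imputation,
    pool_columns,
    predict,
    split_development_validation,
)


def _toy_table(n, betas, noise_sd, rng, n_noise=0, subject_records=1):
    p = len(betas)
    x = rng.standard_normal((n, p + n_noise))
    y = 12.0 + x[:, :p] @ np.asarray(betas) + rng.normal(0, noise_sd, n)
    cols = [f"v{i}" for i in range(p)] + [f"noise{i}" for i in range(n_noise)]
    t = pd.DataFrame(x, columns=cols)
    t.insert(0, "excretion", y)
    t.insert(0, "setting", "outpatient")
    t.insert(0, "scan_date", "2015-01-01")
    t.insert(0, "subject_id", [f"S{i // subject_records}" for i in range(n)])
    t.insert(0, "record_id", [f"R{i}" for i in range(n)])
    return t


# ---------------------------------------------------------------------------
# split


def test_split_sizes_and_reproducibility(study_table):
    table, _ = study_table
    dev, val = split_development_validation(table, 0.6, seed=5)
    n_subjects = table["subject_id"].nunique()
    assert dev["subject_id"].nunique() == round(0.6 * n_subjects)
    assert len(dev) + len(val) == len(table)
    assert set(dev["subject_id"]).isdisjoint(val["subject_id"])
    dev2, val2 = split_development_validation(table, 0.6, seed=5)
    pd.testing.assert_frame_equal(dev, dev2)
    pd.testing.assert_frame_equal(val, val2)


def test_split_keeps_repeat_records_of_a_subject_together(rng):
    t = _toy_table(100, [1.0], 0.1, rng, subject_records=2)
    dev, val = split_development_validation(t, 0.6, seed=1)
    for side in (dev, val):
        assert side.groupby("subject_id").size().eq(2).all()


# ---------------------------------------------------------------------------
# consensus rule


@pytest.mark.parametrize(
    "count, kept", [(6, True), (5, False), (10, True), (0, False)]
)
def test_strict_majority_consensus(count, kept):
    supports = [["x"] if i < count else [] for i in range(10)]
    assert ("x" in consensus_select(supports)) is kept


# ---------------------------------------------------------------------------
# LASSO supports


def test_strong_signal_is_selected_in_every_imputation(rng):
    tables = [_toy_table(200, [3.0], 0.5, rng, n_noise=20) for _ in range(5)]
    supports = lasso_support_per_imputation(
        tables, [c for c in tables[0].columns if c.startswith(("v", "noise"))],
        config=DevelopmentConfig(seed=2),
    )
    assert all("v0" in s for s in supports)


def test_huge_penalty_empties_the_support(rng):
    t = _toy_table(100, [3.0], 0.5, rng, n_noise=5)
    supports = lasso_support_per_imputation(
        [t], [c for c in t.columns if c.startswith(("v", "noise"))],
        config=DevelopmentConfig(seed=2), alpha_override=1e6,
    )
    assert supports == [[]]


def test_pure_noise_pool_with_one_se_rule_selects_little(rng):
    """Under the null (no predictor relates to the outcome) the one-SE rule
    keeps the median support at <= 2 variables over 20 seeded repeats."""
    sizes = []
    for seed in range(20):
        r = np.random.default_rng(seed)
        t = _toy_table(120, [0.0], 1.0, r, n_noise=30)
        (support,) = lasso_support_per_imputation(
            [t], [c for c in t.columns if c.startswith("noise")],
            config=DevelopmentConfig(seed=seed, lasso_lambda_rule="cv_1se"),
        )
        sizes.append(len(support))
    assert np.median(sizes) <= 2


def test_constant_predictor_is_dropped(rng):
    t = _toy_table(100, [2.0], 0.5, rng)
    t["flat"] = 1.0
    (support,) = lasso_support_per_imputation(
        [t], ["v0", "flat"], config=DevelopmentConfig(seed=0)
    )
    assert "flat" not in support and "v0" in support


# ---------------------------------------------------------------------------
# backward elimination


def test_irrelevant_variable_eliminated_before_true_ones():
    """With well-separated effects, the pure-noise variable leaves the path
    before any true variable in >= 90% of 50 seeded replicates."""
    wins = 0
    for seed in range(50):
        r = np.random.default_rng(seed)
        t = _toy_table(150, [1.0, 0.9, 0.8], 0.7, r, n_noise=1)
        trace = backward_cv_select(
            [t], ["v0", "v1", "v2", "noise0"], config=DevelopmentConfig(seed=seed)
        )
        # position in the path where each variable disappears
        drop_order = []
        for (prev, _), (cur, _) in zip(trace.backward_path, trace.backward_path[1:]):
            drop_order.append((set(prev) - set(cur)).pop())
        wins += drop_order[0] == "noise0"
    assert wins >= 45


def test_single_variable_consensus_gives_trivial_trace(rng):
    t = _toy_table(80, [2.0], 0.5, rng)
    trace = backward_cv_select([t], ["v0"], config=DevelopmentConfig(seed=0))
    assert len(trace.backward_path) == 1
    assert trace.chosen == ("v0",)


def test_chosen_subset_never_worse_than_full_consensus_model(rng):
    t = _toy_table(120, [1.0, 0.5, 0.0], 1.0, rng, n_noise=2)
    trace = backward_cv_select(
        [t], ["v0", "v1", "v2", "noise0", "noise1"], config=DevelopmentConfig(seed=1)
    )
    full_rmse = trace.backward_path[0][1]
    chosen_rmse = dict(trace.backward_path)[trace.chosen]
    assert chosen_rmse <= full_rmse + 1e-9


def test_empty_consensus_raises(rng):
    t = _toy_table(50, [1.0], 0.5, rng)
    with pytest.raises(DevelopmentError):
        backward_cv_select([t], [], config=DevelopmentConfig(seed=0))


# ---------------------------------------------------------------------------
# fitting, pooling, prediction


def test_identical_tables_pool_to_single_fit(rng):
    t = _toy_table(100, [1.5, -0.5], 0.5, rng)
    single = fit_and_pool([t], ["v0", "v1"])
    pooled = fit_and_pool([t, t, t], ["v0", "v1"])
    assert pooled.coefficients == pytest.approx(single.coefficients)
    assert pooled.intercept == pytest.approx(single.intercept)


def test_zero_noise_fit_recovers_exact_coefficients(rng):
    t = _toy_table(100, [1.5, -0.5], 0.0, rng)
    eq = fit_and_pool([t], ["v0", "v1"])
    assert eq.coefficients == pytest.approx([1.5, -0.5], abs=1e-8)
    assert eq.intercept == pytest.approx(12.0, abs=1e-8)


def test_pooled_coefficients_within_three_pooled_ses(rng):
    """Parameter recovery at moderate noise: every pooled coefficient lies
    within 3 pooled SEs of its generating value."""
    truth = [1.2, -0.8, 0.5]
    tables = [_toy_table(500, truth, 2.0, np.random.default_rng(s)) for s in range(5)]
    eq = fit_and_pool(tables, ["v0", "v1", "v2"])
    for b, se, want in zip(eq.coefficients, eq.coefficient_se[1:], truth):
        assert abs(b - want) <= 3 * se


def test_collinear_design_raises_named_error(rng):
    t = _toy_table(50, [1.0], 0.5, rng)
    t["dup"] = t["v0"]
    with pytest.raises(DevelopmentError, match="collinear"):
        fit_and_pool([t], ["v0", "dup"])


def test_predict_is_affine_and_checks_features():
    eq = EquationSpec("toy", ["a", "b"], [2.0, -1.0], 5.0)
    assert predict(eq, {"a": 0.0, "b": 0.0}) == 5.0
    assert predict(eq, {"a": 1.0, "b": 2.0}) == 5.0
    base = predict(eq, {"a": 3.0, "b": 1.0})
    assert predict(eq, {"a": 4.0, "b": 1.0}) - base == pytest.approx(2.0)
    with pytest.raises(PredictionError, match="b"):
        predict(eq, {"a": 1.0})
    frame = pd.DataFrame({"a": [1.0, 2.0], "b": [0.0, 1.0]})
    assert predict(eq, frame) == pytest.approx([7.0, 8.0])


def test_truth_equation_reproduces_true_excretion(study_table):
    table, truth = study_table
    eq = truth.to_equation()
    pred = predict(eq, table)
    want = np.array([truth.per_record_true_excretion[r] for r in table.record_id])
    assert pred == pytest.approx(want)


# ---------------------------------------------------------------------------
# full procedure


def test_craft2_pool_excludes_weight_and_stature(study_table):
    table, _ = study_table
    cols = pool_columns(table, "craft2")
    assert "weight" not in cols and "stature" not in cols
    assert "psoas_area_cm2" in cols


def test_development_is_reproducible(rng):
    tables = [_toy_table(150, [2.0, 1.5], 0.8, np.random.default_rng(s), n_noise=10) for s in range(3)]
    cfg = DevelopmentConfig(seed=13)
    eq1, tr1 = develop_equation(tables, [c for c in tables[0].columns if c.startswith(("v", "noise"))], config=cfg)
    eq2, tr2 = develop_equation(tables, [c for c in tables[0].columns if c.startswith(("v", "noise"))], config=cfg)
    assert eq1.variables == eq2.variables
    assert eq1.coefficients == eq2.coefficients
    assert tr1.backward_path == tr2.backward_path


def test_equation_json_round_trip(tmp_path, rng):
    t = _toy_table(80, [1.0], 0.3, rng)
    eq = fit_and_pool([t], ["v0"], name="CRAFT 1", provenance="craft1")
    path = tmp_path / "eq.json"
    eq.to_json(path)
    back = EquationSpec.from_json(path)
    assert back == eq
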