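"""Phantom rendering, threshold segmentation, area and radiomics tests,
including an independent brute-force radiomics oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from craftct.phantom import (
    EllipseSpec,
    GeometryError,
    PhantomSpec,
    SegmentationConfig,
    compute_area,
    compute_radiomics,
    default_phantom_spec,
    extract_features,
    generate_phantom,
    load_stack_nifti,
    quality_check,
    rasterize_ellipse,
    save_stack_nifti,
    segment_compartments,
)


def _single_ellipse_spec(a_mm, b_mm, spacing, hu=45.0, sd=5.0):
    half = max(a_mm, b_mm) + 10.0
    n = int(round(2 * half / spacing))
    return PhantomSpec(
        shape=(n, n),
        pixel_spacing_mm=(spacing, spacing),
        compartments=[EllipseSpec("psoas", (0.0, 0.0), (a_mm, b_mm), hu, sd)],
    )


# ---------------------------------------------------------------------------
# geometry / areas


def test_rasterized_ellipse_area_matches_analytic_within_2pct():
    spec = _single_ellipse_spec(20.0, 15.0, 1.0)
    stack = generate_phantom(spec, 0)
    area = compute_area(stack.truth_mask("psoas"), stack.pixel_spacing_mm)
    assert area == pytest.approx(math.pi * 2.0 * 1.5, rel=0.02)


def test_area_error_decreases_with_finer_spacing():
    """Mean relative rasterisation error over a set of ellipse geometries
    falls strictly as the grid refines (a single geometry can tie by
    grid-alignment coincidence)."""
    rng = np.random.default_rng(1)
    geometries = [(rng.uniform(12, 35), rng.uniform(8, 25)) for _ in range(8)]
    mean_errors = []
    for spacing in (2.0, 1.0, 0.5):
        errs = []
        for a_mm, b_mm in geometries:
            stack = generate_phantom(_single_ellipse_spec(a_mm, b_mm, spacing), 0)
            area = compute_area(stack.truth_mask("psoas"), stack.pixel_spacing_mm)
            analytic = math.pi * a_mm * b_mm / 100.0
            errs.append(abs(area - analytic) / analytic)
        mean_errors.append(np.mean(errs))
    assert mean_errors[0] > mean_errors[1] > mean_errors[2]


def test_phantom_is_deterministic_per_seed():
    spec = default_phantom_spec(2.0)
    a = generate_phantom(spec, 42)
    b = generate_phantom(spec, 42)
    assert np.array_equal(a.slices, b.slices)
    assert np.array_equal(a.truth_labels, b.truth_labels)


def test_overlapping_compartments_raise_geometry_error():
    spec = _single_ellipse_spec(20.0, 15.0, 1.0)
    spec.compartments.append(
        EllipseSpec("long_spine", (5.0, 0.0), (20.0, 15.0), 40.0, 5.0)
    )
    with pytest.raises(GeometryError, match="long_spine"):
        generate_phantom(spec, 0)


def test_cut_off_phantom_touches_border_and_fails_quality():
    stack = generate_phantom(default_phantom_spec(2.0, cut_off=True), 0)
    ok, reason = quality_check(stack)
    assert (ok, reason) == (False, "cut_off")


def test_clean_phantom_passes_quality():
    stack = generate_phantom(default_phantom_spec(2.0), 0)
    assert quality_check(stack) == (True, None)


def test_artefact_pixels_fail_quality(rng):
    stack = generate_phantom(default_phantom_spec(2.0), 0)
    body = stack.truth_labels > 0
    idx = np.flatnonzero(body.ravel())
    hit = rng.choice(idx, size=max(1, int(0.05 * idx.size)), replace=False)
    flat = stack.slices.ravel()
    flat[hit] = 3000.0
    ok, reason = quality_check(stack)
    assert (ok, reason) == (False, "artefact")


def test_five_slice_average_area():
    """Counts (100,100,100,100,200) at 1 mm^2 pixels average to 1.2 cm^2."""
    mask = np.zeros((5, 20, 20), dtype=bool)
    for z, count in enumerate((100, 100, 100, 100, 200)):
        mask[z].ravel()[:count] = True
    assert compute_area(mask, (1.0, 1.0)) == pytest.approx(1.2)
    assert compute_area(np.zeros((5, 4, 4), bool), (1.0, 1.0)) == 0.0


# ---------------------------------------------------------------------------
# segmentation


def test_segmentation_keeps_uniform_muscle_and_drops_fatlike_hu():
    spec = _single_ellipse_spec(20.0, 15.0, 1.0, hu=40.0, sd=1e-9)
    stack = generate_phantom(spec, 0)
    stack.slices[stack.truth_mask("psoas")] = 40.0
    masks = segment_compartments(stack)
    assert np.array_equal(masks["psoas"], stack.truth_mask("psoas"))
    stack.slices[stack.truth_mask("psoas")] = -50.0
    masks = segment_compartments(stack)
    assert masks["psoas"].sum() == 0


def test_segmentation_retains_normal_tail_fraction(rng):
    """70% N(45, 5^2) / 30% N(-60, 5^2) mixture: the > -15 HU rule keeps
    essentially the 70% component (plus negligible tail mass)."""
    spec = _single_ellipse_spec(40.0, 30.0, 1.0)
    stack = generate_phantom(spec, 0)
    mask = stack.truth_mask("psoas")
    n = int(mask.sum())
    comp = rng.random(n) < 0.7
    values = np.where(comp, rng.normal(45, 5, n), rng.normal(-60, 5, n))
    stack.slices[mask] = values
    kept = segment_compartments(stack)["psoas"].sum()
    p_expected = 0.7 * norm.sf(-15, 45, 5) + 0.3 * norm.sf(-15, -60, 5)
    assert kept / n == pytest.approx(p_expected, abs=3 * math.sqrt(p_expected * (1 - p_expected) / n))


# ---------------------------------------------------------------------------
# radiomics


def brute_force_radiomics(values):
    """Independent oracle: sorting-based percentiles, direct moment sums."""
    v = sorted(float(x) for x in values)
    n = len(v)
    if n == 0:
        return {k: float("nan") for k in ("p10", "p25", "p75", "p90", "kurtosis",
                                          "skewness", "mean", "median", "sd", "min", "max")}

    def quantile(q):
        # linear interpolation between order statistics
        h = (n - 1) * q
        lo = math.floor(h)
        hi = min(lo + 1, n - 1)
        return v[lo] + (h - lo) * (v[hi] - v[lo])

    mean = sum(v) / n
    m2 = sum((x - mean) ** 2 for x in v) / n
    if m2 == 0.0:
        sd = skew = kurt = 0.0
    else:
        m3 = sum((x - mean) ** 3 for x in v) / n
        m4 = sum((x - mean) ** 4 for x in v) / n
        sd = math.sqrt(sum((x - mean) ** 2 for x in v) / (n - 1)) if n > 1 else 0.0
        skew = m3 / m2**1.5
        kurt = m4 / m2**2 - 3.0
    return {
        "p10": quantile(0.10),
        "p25": quantile(0.25),
        "p75": quantile(0.75),
        "p90": quantile(0.90),
        "kurtosis": kurt,
        "skewness": skew,
        "mean": mean,
        "median": quantile(0.5),
        "sd": sd,
        "min": v[0],
        "max": v[-1],
    }


def test_radiomics_symmetric_three_point_set():
    r = compute_radiomics(np.array([10.0, 20.0, 30.0]))
    assert r["mean"] == 20 and r["median"] == 20
    assert r["min"] == 10 and r["max"] == 30
    assert r["skewness"] == pytest.approx(0.0, abs=1e-12)


def test_radiomics_constant_input_convention():
    r = compute_radiomics(np.full(100, 50.0))
    assert r["sd"] == 0.0 and r["skewness"] == 0.0 and r["kurtosis"] == 0.0
    assert r["p10"] == r["p90"] == 50.0


def test_radiomics_empty_input_is_all_missing():
    r = compute_radiomics(np.array([]))
    assert all(math.isnan(x) for x in r.values())


def test_radiomics_normal_sample_moments(rng):
    v = rng.normal(40, 10, 100_000)
    r = compute_radiomics(v)
    assert r["mean"] == pytest.approx(40, abs=0.1)
    assert r["p90"] == pytest.approx(40 + 1.2816 * 10, abs=0.3)


def test_radiomics_match_brute_force_oracle(rng):
    """All 11 statistics agree with the independent oracle to 1e-9 relative
    on 100 random HU multisets (with ties and varying sizes)."""
    for _ in range(100):
        n = int(rng.integers(2, 400))
        v = np.round(rng.normal(10, 40, n), 1)  # rounding creates ties
        got = compute_radiomics(v)
        want = brute_force_radiomics(v)
        for k in want:
            assert got[k] == pytest.approx(want[k], rel=1e-9, abs=1e-9), k


def test_radiomics_affine_shift_invariants(rng):
    v = rng.normal(0, 25, 500)
    c = 37.5
    base = compute_radiomics(v)
    shifted = compute_radiomics(v + c)
    for k in ("p10", "p25", "p75", "p90", "mean", "median", "min", "max"):
        assert shifted[k] == pytest.approx(base[k] + c, rel=1e-12, abs=1e-9)
    for k in ("sd", "skewness", "kurtosis"):
        assert shifted[k] == pytest.approx(base[k], rel=1e-9, abs=1e-9)


def test_affine_hu_shift_leaves_areas_unchanged():
    """Shifting all HU by +c with thresholds shifted by +c keeps every mask."""
    stack = generate_phantom(default_phantom_spec(2.0), 3)
    base = segment_compartments(stack, SegmentationConfig())
    c = 60.0
    stack.slices += c
    shifted_cfg = SegmentationConfig(
        muscle_hu_threshold=-15.0 + c, fat_hu_window=(-190.0 + c, -30.0 + c)
    )
    shifted = segment_compartments(stack, shifted_cfg)
    for name in base:
        assert np.array_equal(base[name], shifted[name])


@settings(max_examples=60, deadline=None)
@given(st.lists(st.floats(min_value=-1000, max_value=3000, allow_nan=False), min_size=1, max_size=60))
def test_order_statistic_chain_invariant(values):
    r = compute_radiomics(np.array(values))
    assert (
        r["min"] <= r["p10"] + 1e-9
        and r["p10"] <= r["p25"] + 1e-9
        and r["p25"] <= r["median"] + 1e-9
        and r["median"] <= r["p75"] + 1e-9
        and r["p75"] <= r["p90"] + 1e-9
        and r["p90"] <= r["max"] + 1e-9
    )
    assert r["sd"] >= 0.0


# ---------------------------------------------------------------------------
# extraction + I/O


def test_extract_features_produces_all_compartment_stats():
    stack = generate_phantom(default_phantom_spec(2.0), 1)
    feats = extract_features(stack)
    assert len(feats) == 5 * 12
    assert feats["psoas_area_cm2"] > 0
    assert feats["subcutaneous_fat_mean"] < -50


def test_nifti_round_trip(tmp_path):
    stack = generate_phantom(default_phantom_spec(2.0), 9)
    hu = tmp_path / "stack.nii"
    lab = tmp_path / "labels.nii"
    save_stack_nifti(stack, hu, lab)
    back = load_stack_nifti(hu, lab)
    assert np.array_equal(back.slices, np.round(stack.slices))
    assert np.array_equal(back.truth_labels, stack.truth_labels)
    assert back.pixel_spacing_mm == stack.pixel_spacing_mm
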