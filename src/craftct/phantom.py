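"""L3-like CT phantoms and the body-composition measurements made on them.

A phantom stack is five contiguous 5-mm axial slices (a 2.5-cm range around
the L3 level) with known, disjoint compartment masks: psoas, long spine and
abdominal wall muscles plus subcutaneous and visceral fat.  HU values are
drawn per compartment from truncated normals on an air background
(~ -1000 HU).  The measurements reproduce the analysis applied to real
scans: threshold segmentation within each compartment (muscle > -15 HU,
fat in [-190, -30] HU), cross-sectional areas averaged over the five
slices, and eleven first-order radiomics statistics of the HU distribution.

Ground-truth masks stand in for the segmentation network used on real
images; everything downstream of segmentation is computed exactly as it
would be on network output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cohort import COMPARTMENTS, RADIOMIC_STATS

__all__ = [
    "EllipseSpec",
    "PhantomSpec",
    "PhantomStack",
    "SegmentationConfig",
    "GeometryError",
    "generate_phantom",
    "segment_compartments",
    "compute_area",
    "compute_radiomics",
    "quality_check",
    "extract_features",
    "default_phantom_spec",
    "save_stack_nifti",
    "load_stack_nifti",
]

MUSCLE_COMPARTMENTS = ("psoas", "long_spine", "abdominal_wall")
FAT_COMPARTMENTS = ("subcutaneous_fat", "visceral_fat")
BACKGROUND_HU = -1000.0

LABELS = {name: i + 1 for i, name in enumerate(COMPARTMENTS)}


class GeometryError(ValueError):
    pass


@dataclass
class EllipseSpec:
    """One compartment: an axis-aligned ellipse in mm plus its HU law."""

    name: str
    center_mm: tuple[float, float]  # (x, y) with origin at grid centre
    semiaxes_mm: tuple[float, float]  # (a along x, b along y)
    hu_mean: float
    hu_sd: float
    hu_bounds: tuple[float, float] = (-300.0, 300.0)

    @property
    def analytic_area_cm2(self) -> float:
        return float(np.pi * self.semiaxes_mm[0] * self.semiaxes_mm[1] / 100.0)


@dataclass
class PhantomSpec:
    shape: tuple[int, int] = (160, 220)  # rows (y), cols (x)
    pixel_spacing_mm: tuple[float, float] = (1.0, 1.0)  # (row, col)
    slice_thickness_mm: float = 5.0
    compartments: list[EllipseSpec] = field(default_factory=list)
    allow_cut_off: bool = False


@dataclass
class PhantomStack:
    """Five HU slices with spacing metadata and ground-truth label masks."""

    slices: np.ndarray  # (5, rows, cols) float HU
    truth_labels: np.ndarray  # (5, rows, cols) uint8, values in LABELS
    pixel_spacing_mm: tuple[float, float]
    slice_thickness_mm: float = 5.0

    def __post_init__(self):
        if self.slices.shape[0] != 5:
            raise ValueError("a stack has exactly 5 slices")
        if self.slices.shape != self.truth_labels.shape:
            raise ValueError("slices and truth labels must share shape")

    def truth_mask(self, compartment: str) -> np.ndarray:
        return self.truth_labels == LABELS[compartment]


@dataclass
class SegmentationConfig:
    muscle_hu_threshold: float = -15.0
    fat_hu_window: tuple[float, float] = (-190.0, -30.0)
    border_margin: int = 2
    artefact_hu_bounds: tuple[float, float] = (-500.0, 2000.0)
    artefact_fraction_limit: float = 0.01
    # whether radiomics are computed on the thresholded HU distribution
    radiomics_on_thresholded: bool = True

    def validate(self) -> None:
        if not np.isfinite(self.muscle_hu_threshold):
            raise ValueError("muscle_hu_threshold must be finite")
        lo, hi = self.fat_hu_window
        if not lo < hi:
            raise ValueError("fat_hu_window lower bound must be below upper")


#: typical cross-sectional areas (cm^2) of each compartment at L3
DEFAULT_AREAS_CM2 = {
    "psoas": 19.0,
    "long_spine": 44.0,
    "abdominal_wall": 68.0,
    "subcutaneous_fat": 180.0,
    "visceral_fat": 120.0,
}

DEFAULT_HU = {
    "psoas": (45.0, 12.0, (-200.0, 150.0)),
    "long_spine": (40.0, 12.0, (-200.0, 150.0)),
    "abdominal_wall": (35.0, 12.0, (-200.0, 150.0)),
    "subcutaneous_fat": (-100.0, 10.0, (-250.0, 20.0)),
    "visceral_fat": (-90.0, 10.0, (-250.0, 20.0)),
}

#: ellipse elongation (a/b) per compartment
_ASPECT = {
    "psoas": 1.3,
    "long_spine": 1.4,
    "abdominal_wall": 2.8,
    "subcutaneous_fat": 1.5,
    "visceral_fat": 1.5,
}


def default_phantom_spec(
    pixel_spacing_mm: float = 1.0,
    areas_cm2: dict[str, float] | None = None,
    hu_means: dict[str, float] | None = None,
    cut_off: bool = False,
) -> PhantomSpec:
    """Layout of five disjoint compartment ellipses sized to target areas.

    Each ellipse's semi-axes are derived from its target area (defaults are
    typical L3 values) at a fixed per-compartment aspect ratio; muscles sit
    in the lower row and fat in the upper row with an 8-mm gap, and the
    grid is sized to fit with a margin, so the layout stays disjoint for
    any realistic set of areas.  ``hu_means`` overrides mean attenuations.
    With ``cut_off`` the psoas is shifted onto the image border, emulating
    a scan that truncates muscle.
    """
    areas = {**DEFAULT_AREAS_CM2, **(areas_cm2 or {})}
    gap, margin = 8.0, 10.0
    axes = {}
    for name, area in areas.items():
        ab = max(area, 0.5) * 100.0 / np.pi  # a*b in mm^2
        b = float(np.sqrt(ab / _ASPECT[name]))
        axes[name] = (_ASPECT[name] * b, b)
    rows = [MUSCLE_COMPARTMENTS, FAT_COMPARTMENTS]
    row_widths = [
        sum(2 * axes[n][0] for n in row) + gap * (len(row) - 1) for row in rows
    ]
    width = max(row_widths) + 2 * margin
    b_max = [max(axes[n][1] for n in row) for row in rows]
    y_centers = [-(b_max[0] + gap / 2.0), b_max[1] + gap / 2.0]
    height = 2 * b_max[0] + 2 * b_max[1] + gap + 2 * margin
    comps = []
    for row, y_c, row_w in zip(rows, y_centers, row_widths):
        x = -row_w / 2.0
        for name in row:
            a, b = axes[name]
            hu_mean, hu_sd, bounds = DEFAULT_HU[name]
            if hu_means and name in hu_means:
                hu_mean = float(hu_means[name])
            comps.append(EllipseSpec(name, (x + a, y_c), (a, b), hu_mean, hu_sd, bounds))
            x += 2 * a + gap
    if cut_off:
        psoas = comps[0]
        psoas.center_mm = (-width / 2.0, psoas.center_mm[1])
    n_rows = int(np.ceil(height / pixel_spacing_mm))
    n_cols = int(np.ceil(width / pixel_spacing_mm))
    return PhantomSpec(
        shape=(n_rows, n_cols),
        pixel_spacing_mm=(pixel_spacing_mm, pixel_spacing_mm),
        compartments=comps,
        allow_cut_off=cut_off,
    )


def _pixel_centers(spec: PhantomSpec):
    rows, cols = spec.shape
    sy, sx = spec.pixel_spacing_mm
    y = (np.arange(rows) - (rows - 1) / 2.0) * sy
    x = (np.arange(cols) - (cols - 1) / 2.0) * sx
    return np.meshgrid(x, y)  # xx, yy


def rasterize_ellipse(spec: PhantomSpec, ell: EllipseSpec) -> np.ndarray:
    """Pixel-center-in-ellipse membership mask."""
    xx, yy = _pixel_centers(spec)
    a, b = ell.semiaxes_mm
    cx, cy = ell.center_mm
    return ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0


def _truncnorm_draw(rng, mean, sd, bounds, size):
    """Truncated-normal sample by rejection (bounds are several SDs out for
    every default compartment, so acceptance is near 1)."""
    lo, hi = bounds
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    for _ in range(100):
        n_bad = int(bad.sum())
        if not n_bad:
            return out
        out[bad] = rng.normal(mean, sd, n_bad)
        bad = (out < lo) | (out > hi)
    # pathological truncation: fall back to exact inverse-CDF sampling
    a, b = (lo - mean) / sd, (hi - mean) / sd
    out[bad] = stats.truncnorm.rvs(
        a, b, loc=mean, scale=sd, size=int(bad.sum()), random_state=rng
    )
    return out


def generate_phantom(spec: PhantomSpec, seed: int | np.random.Generator = 0) -> PhantomStack:
    """Render a 5-slice stack from the geometric spec.

    HU values are drawn independently per slice from each compartment's
    truncated normal; the background is air.  Overlapping compartments are
    a geometry error (truth labels must be disjoint).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = np.zeros(spec.shape, dtype=np.uint8)
    masks = {}
    for ell in spec.compartments:
        m = rasterize_ellipse(spec, ell)
        if (labels[m] != 0).any():
            raise GeometryError(f"compartment {ell.name!r} overlaps another compartment")
        labels[m] = LABELS[ell.name]
        masks[ell.name] = m
    slices = np.full((5,) + spec.shape, BACKGROUND_HU, dtype=np.float64)
    truth = np.broadcast_to(labels, (5,) + spec.shape).copy()
    for ell in spec.compartments:
        m = masks[ell.name]
        npx = int(m.sum())
        for z in range(5):
            slices[z][m] = _truncnorm_draw(rng, ell.hu_mean, ell.hu_sd, ell.hu_bounds, npx)
    return PhantomStack(
        slices=slices,
        truth_labels=truth,
        pixel_spacing_mm=spec.pixel_spacing_mm,
        slice_thickness_mm=spec.slice_thickness_mm,
    )


def segment_compartments(
    stack: PhantomStack, config: SegmentationConfig | None = None
) -> dict[str, np.ndarray]:
    """Threshold segmentation within the known compartments.

    Muscle keeps pixels above the muscle threshold (> -15 HU by default);
    fat keeps pixels inside the adipose HU window.
    """
    config = config or SegmentationConfig()
    config.validate()
    out = {}
    for name in MUSCLE_COMPARTMENTS:
        out[name] = stack.truth_mask(name) & (stack.slices > config.muscle_hu_threshold)
    lo, hi = config.fat_hu_window
    for name in FAT_COMPARTMENTS:
        out[name] = stack.truth_mask(name) & (stack.slices >= lo) & (stack.slices <= hi)
    return out


def compute_area(mask: np.ndarray, pixel_spacing_mm: tuple[float, float]) -> float:
    """Cross-sectional area in cm^2, averaged over the five slices."""
    if mask.ndim != 3 or mask.shape[0] != 5:
        raise ValueError("expected a (5, rows, cols) mask stack")
    pixel_area_mm2 = pixel_spacing_mm[0] * pixel_spacing_mm[1]
    per_slice = mask.reshape(5, -1).sum(axis=1) * pixel_area_mm2
    return float(per_slice.mean() / 100.0)


def compute_radiomics(hu_values: np.ndarray) -> dict[str, float]:
    """Eleven first-order statistics of an HU sample.

    Percentiles use linear interpolation between order statistics; sd is
    the sample SD (ddof=1); skewness and excess kurtosis are moment-based.
    A constant sample gets sd/skewness/kurtosis of 0 by convention; an
    empty sample yields NaN for every statistic.
    """
    v = np.asarray(hu_values, dtype=np.float64).ravel()
    if v.size == 0:
        return {k: float("nan") for k in RADIOMIC_STATS}
    p10, p25, p75, p90 = np.percentile(v, [10, 25, 75, 90])
    constant = np.ptp(v) == 0.0
    return {
        "p10": float(p10),
        "p25": float(p25),
        "p75": float(p75),
        "p90": float(p90),
        "kurtosis": 0.0 if constant else float(stats.kurtosis(v, fisher=True, bias=True)),
        "skewness": 0.0 if constant else float(stats.skew(v, bias=True)),
        "mean": float(v.mean()),
        "median": float(np.median(v)),
        "sd": 0.0 if constant or v.size < 2 else float(v.std(ddof=1)),
        "min": float(v.min()),
        "max": float(v.max()),
    }


def quality_check(
    stack: PhantomStack, config: SegmentationConfig | None = None
) -> tuple[bool, str | None]:
    """Automated surrogate for the manual scan-quality review.

    Fails with reason ``"cut_off"`` when any muscle truth mask touches the
    border margin, or ``"artefact"`` when the fraction of body pixels with
    extreme HU exceeds the configured limit.
    """
    config = config or SegmentationConfig()
    m = config.border_margin
    muscle = np.isin(
        stack.truth_labels, [LABELS[c] for c in MUSCLE_COMPARTMENTS]
    )
    border = np.zeros_like(muscle)
    border[:, :m, :] = True
    border[:, -m:, :] = True
    border[:, :, :m] = True
    border[:, :, -m:] = True
    if (muscle & border).any():
        return False, "cut_off"
    body = stack.truth_labels > 0
    if body.any():
        lo, hi = config.artefact_hu_bounds
        extreme = body & ((stack.slices < lo) | (stack.slices > hi))
        if extreme.sum() / body.sum() > config.artefact_fraction_limit:
            return False, "artefact"
    return True, None


def extract_features(
    stack: PhantomStack, config: SegmentationConfig | None = None
) -> dict[str, float]:
    """Areas plus radiomics for every compartment, as ``<compartment>_<stat>``.

    Radiomics are computed on the thresholded HU distribution by default
    (switchable via the segmentation config), pooling the five slices.
    """
    config = config or SegmentationConfig()
    masks = segment_compartments(stack, config)
    feats: dict[str, float] = {}
    for name in COMPARTMENTS:
        mask = masks[name] if config.radiomics_on_thresholded else stack.truth_mask(name)
        feats[f"{name}_area_cm2"] = compute_area(masks[name], stack.pixel_spacing_mm)
        for stat, value in compute_radiomics(stack.slices[mask]).items():
            feats[f"{name}_{stat}"] = value
    return feats


# ---------------------------------------------------------------------------
# NIfTI I/O


def save_stack_nifti(stack: PhantomStack, hu_path, labels_path=None) -> None:
    """Write HU slices (int16) and optionally truth labels as NIfTI-1."""
    import nibabel as nib

    sy, sx = stack.pixel_spacing_mm
    affine = np.diag([sx, sy, stack.slice_thickness_mm, 1.0])
    vol = np.moveaxis(stack.slices, 0, -1)  # (rows, cols, 5)
    nib.save(nib.Nifti1Image(np.round(vol).astype(np.int16), affine), str(hu_path))
    if labels_path is not None:
        lab = np.moveaxis(stack.truth_labels, 0, -1)
        nib.save(nib.Nifti1Image(lab.astype(np.uint8), affine), str(labels_path))


def load_stack_nifti(hu_path, labels_path) -> PhantomStack:
    import nibabel as nib

    img = nib.load(str(hu_path))
    lab = nib.load(str(labels_path))
    slices = np.moveaxis(np.asarray(img.dataobj, dtype=np.float64), -1, 0)
    labels = np.moveaxis(np.asarray(lab.dataobj, dtype=np.uint8), -1, 0)
    zooms = img.header.get_zooms()
    return PhantomStack(
        slices=slices,
        truth_labels=labels,
        pixel_spacing_mm=(float(zooms[1]), float(zooms[0])),
        slice_thickness_mm=float(zooms[2]),
    )
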