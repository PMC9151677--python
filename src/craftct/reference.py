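"""Published demographic comparators for daily creatinine excretion.

Two closed-form equations estimate 24-h urinary creatinine excretion from
age, weight and sex:

* Cockcroft-Gault: excretion (mg/kg/day) = 28 - 0.2 * age for men, times
  0.85 for women, multiplied by weight.
* Ix (CKD-EPI creatinine excretion): excretion (mg/day) =
  879.89 + 12.51 * weight - 6.19 * age - 379.42 * [female]
  (+ 34.51 * [black]); the race term is dropped when ethnicity is not
  recorded.

Both are published in mg/day; results are converted to mmol/day via the
molar mass of creatinine (113.12 g/mol).  Coefficients live in a versioned
JSON constants file with citations, not in code.
"""

from __future__ import annotations

import importlib.resources
import json
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = [
    "ComparatorInput",
    "comparator_constants",
    "cockcroft_gault_excretion",
    "ix_excretion",
    "mg_to_mmol",
    "mmol_to_mg",
    "comparator_predictions",
]


@dataclass
class ComparatorInput:
    age: float
    weight: float
    sex: str  # "male" | "female"

    def validate(self) -> None:
        if not self.age > 0:
            raise ValueError(f"age must be > 0, got {self.age}")
        if not self.weight > 0:
            raise ValueError(f"weight must be > 0, got {self.weight}")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")


@lru_cache(maxsize=1)
def comparator_constants() -> dict:
    ref = importlib.resources.files("craftct") / "data" / "comparator_coefficients.json"
    return json.loads(ref.read_text())


def mg_to_mmol(mg_per_day):
    """Convert creatinine mass to amount of substance (113.12 g/mol)."""
    return np.asarray(mg_per_day, dtype=float) / comparator_constants()[
        "creatinine_molar_mass_g_per_mol"
    ]


def mmol_to_mg(mmol_per_day):
    return np.asarray(mmol_per_day, dtype=float) * comparator_constants()[
        "creatinine_molar_mass_g_per_mol"
    ]


def cockcroft_gault_excretion(inp: ComparatorInput) -> float:
    """Cockcroft-Gault estimate of 24-h creatinine excretion (mmol/day)."""
    inp.validate()
    c = comparator_constants()["cockcroft_gault"]
    per_kg = (
        c["male_intercept_mg_per_kg_day"]
        - c["male_age_slope_mg_per_kg_day_per_year"] * inp.age
    )
    if per_kg <= 0:
        warnings.warn(
            f"Cockcroft-Gault excretion is nonpositive at age {inp.age}; "
            "the rule is outside its domain",
            stacklevel=2,
        )
    mg = per_kg * inp.weight
    if inp.sex == "female":
        mg *= c["female_factor"]
    return float(mg_to_mmol(mg))


def ix_excretion(inp: ComparatorInput, black: bool = False) -> float:
    """Ix estimate of 24-h creatinine excretion (mmol/day), race optional."""
    inp.validate()
    c = comparator_constants()["ix"]
    mg = (
        c["intercept"]
        + c["weight_kg"] * inp.weight
        + c["age_years"] * inp.age
        + (c["female"] if inp.sex == "female" else 0.0)
        + (c["black"] if black else 0.0)
    )
    return float(mg_to_mmol(mg))


def comparator_predictions(table) -> dict[str, np.ndarray]:
    """Vectorised CG and Ix predictions from a feature table.

    Requires nonmissing ``age``, ``weight``, ``sex_male`` columns (run on
    imputed tables).
    """
    age = table["age"].to_numpy(dtype=float)
    weight = table["weight"].to_numpy(dtype=float)
    female = table["sex_male"].to_numpy(dtype=float) == 0.0
    cc = comparator_constants()
    cg = (
        cc["cockcroft_gault"]["male_intercept_mg_per_kg_day"]
        - cc["cockcroft_gault"]["male_age_slope_mg_per_kg_day_per_year"] * age
    ) * weight
    cg = np.where(female, cg * cc["cockcroft_gault"]["female_factor"], cg)
    ix = (
        cc["ix"]["intercept"]
        + cc["ix"]["weight_kg"] * weight
        + cc["ix"]["age_years"] * age
        + np.where(female, cc["ix"]["female"], 0.0)
    )
    return {"cockcroft_gault": mg_to_mmol(cg), "ix": mg_to_mmol(ix)}
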