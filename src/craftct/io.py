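"""Delimited-text serialization of cohorts and ground truth.

One CSV row per scan event.  Dates are ISO-8601; an empty field is a
missing value (never zero).  The plasma series and urine collections are
packed into a single cell as ``date:value`` pairs joined by ``|``, with
floats written in ``repr`` form so a write-read round trip is exact.
"""

from __future__ import annotations

import csv
import datetime
import json
from typing import Sequence

from .cohort import GroundTruth, SubjectRecord

__all__ = ["write_cohort", "read_cohort", "write_ground_truth", "read_ground_truth", "CohortParseError"]

_FIXED = ["subject_id", "record_id", "scan_date", "age", "sex", "weight",
          "stature", "setting", "plasma_series", "urine_collections",
          "latent_muscle"]


class CohortParseError(ValueError):
    pass


def _pack_series(series) -> str:
    return "|".join(f"{d.isoformat()}:{v!r}" for d, v in series)


def _unpack_series(text: str, line: int):
    if not text:
        return []
    out = []
    for part in text.split("|"):
        try:
            day, value = part.split(":", 1)
            out.append((datetime.date.fromisoformat(day), float(value)))
        except ValueError as exc:
            raise CohortParseError(f"line {line}: bad series entry {part!r}") from exc
    return out


def _parse_date(text: str, line: int) -> datetime.date:
    try:
        return datetime.date.fromisoformat(text)
    except ValueError as exc:
        raise CohortParseError(f"line {line}: non-ISO date {text!r}") from exc


def write_cohort(records: Sequence[SubjectRecord], path) -> None:
    feature_cols = sorted({k for r in records for k in r.features})
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_FIXED + feature_cols)
        for r in records:
            row = [
                r.subject_id,
                r.record_id,
                r.scan_date.isoformat(),
                repr(r.age),
                r.sex,
                "" if r.weight is None else repr(r.weight),
                "" if r.stature is None else repr(r.stature),
                r.setting,
                _pack_series(r.plasma_series),
                _pack_series(r.urine_collections),
                repr(r.latent_muscle),
            ]
            for c in feature_cols:
                v = r.features.get(c)
                row.append("" if v is None or v != v else repr(v))
            writer.writerow(row)


def read_cohort(path) -> list[SubjectRecord]:
    records = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header[: len(_FIXED)] != _FIXED:
            raise CohortParseError(f"line 1: unexpected header {header[:3]}...")
        feature_cols = header[len(_FIXED):]
        for line, row in enumerate(reader, start=2):
            if len(row) != len(header):
                raise CohortParseError(f"line {line}: expected {len(header)} fields, got {len(row)}")
            try:
                rec = SubjectRecord(
                    subject_id=row[0],
                    record_id=row[1],
                    scan_date=_parse_date(row[2], line),
                    age=float(row[3]),
                    sex=row[4],
                    weight=None if row[5] == "" else float(row[5]),
                    stature=None if row[6] == "" else float(row[6]),
                    setting=row[7],
                    plasma_series=_unpack_series(row[8], line),
                    urine_collections=_unpack_series(row[9], line),
                    latent_muscle=float(row[10]),
                )
            except CohortParseError:
                raise
            except ValueError as exc:
                raise CohortParseError(f"line {line}: {exc}") from exc
            rec.features = {
                c: float("nan") if v == "" else float(v)
                for c, v in zip(feature_cols, row[len(_FIXED):])
            }
            records.append(rec)
    return records


def write_ground_truth(truth: GroundTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "variables": truth.variables,
                "coefficients": truth.coefficients,
                "intercept": truth.intercept,
                "per_record_true_excretion": truth.per_record_true_excretion,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")


def read_ground_truth(path) -> GroundTruth:
    with open(path) as fh:
        d = json.load(fh)
    return GroundTruth(
        variables=d["variables"],
        coefficients=d["coefficients"],
        intercept=d["intercept"],
        per_record_true_excretion=d["per_record_true_excretion"],
    )
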