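"""Cohort serialisation.

A cohort is stored as three UTF-8 CSVs in one directory:

* ``cohort.csv``   — one row per patient; UKPEN codes as a
  semicolon-separated token list (``P2;A3;E5``), complications as
  ``grade:period`` tokens, missing values empty.
* ``resources.csv`` — one row per resource line
  (patient_id, category, item, quantity).
* ``proms.csv``    — one row per (patient, timepoint) with five EQ5D
  level columns and five DRS item columns; blank = not completed.

``write_cohort`` then ``read_cohort`` is a field-level identity.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Optional, Sequence

from .cohort import (
    Complication,
    ComplexityClass,
    Margin,
    PatientRecord,
    UKPENCode,
    ValidationError,
)
from .costing import ResourceLine
from .proms import EQ5D_DIMENSIONS, PromResponse

_COHORT_COLUMNS = [
    "id", "codes", "historical_codes", "diagnosis", "cancer_primary",
    "cancer_recurrent", "cancer_metastatic", "exenteration_level",
    "reconstruction", "survival_time", "survival_event", "recurrence_time",
    "recurrence_event", "local_recurrence_time", "local_recurrence_event",
    "margin", "benign_flag", "complications", "prom_participant",
    "age", "sex", "bmi", "asa", "smoking",
]


def _fmt_codes(codes) -> str:
    return ";".join(str(c) for c in sorted(codes))


def _parse_codes(text: str) -> frozenset:
    text = text.strip()
    if not text:
        return frozenset()
    return frozenset(UKPENCode.parse(tok) for tok in text.split(";"))


def _fmt_opt(v) -> str:
    return "" if v is None else str(v)


def _parse_float(text: str) -> Optional[float]:
    return float(text) if text.strip() else None


def _parse_bool(text: str) -> bool:
    return text.strip().lower() in ("true", "1", "yes")


def write_cohort(cohort: Sequence[PatientRecord], directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    with open(directory / "cohort.csv", "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=_COHORT_COLUMNS)
        w.writeheader()
        for p in cohort:
            w.writerow(
                {
                    "id": p.id,
                    "codes": _fmt_codes(p.codes),
                    "historical_codes": _fmt_codes(p.historical_codes),
                    "diagnosis": p.diagnosis,
                    "cancer_primary": p.cancer_primary,
                    "cancer_recurrent": p.cancer_recurrent,
                    "cancer_metastatic": p.cancer_metastatic,
                    "exenteration_level": p.exenteration_level,
                    "reconstruction": p.reconstruction,
                    "survival_time": repr(p.survival_time),
                    "survival_event": p.survival_event,
                    "recurrence_time": _fmt_opt(
                        None if p.recurrence_time is None else repr(p.recurrence_time)
                    ),
                    "recurrence_event": p.recurrence_event,
                    "local_recurrence_time": _fmt_opt(
                        None
                        if p.local_recurrence_time is None
                        else repr(p.local_recurrence_time)
                    ),
                    "local_recurrence_event": p.local_recurrence_event,
                    "margin": p.margin.value,
                    "benign_flag": p.benign_flag,
                    "complications": ";".join(
                        f"{c.grade}:{c.period}" for c in p.complications
                    ),
                    "prom_participant": p.prom_participant,
                    "age": _fmt_opt(p.age),
                    "sex": _fmt_opt(p.sex),
                    "bmi": _fmt_opt(p.bmi),
                    "asa": _fmt_opt(p.asa),
                    "smoking": _fmt_opt(p.smoking),
                }
            )

    with open(directory / "resources.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "category", "item", "quantity"])
        for p in cohort:
            for line in p.resources:
                w.writerow([p.id, line.category, line.item, repr(line.quantity)])

    with open(directory / "proms.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["patient_id", "timepoint"]
            + list(EQ5D_DIMENSIONS)
            + [f"drs{i}" for i in range(1, 6)]
        )
        for p in cohort:
            for r in p.proms:
                eq = list(r.eq5d) if r.eq5d is not None else [""] * 5
                drs = list(r.drs_items) if r.drs_items is not None else [""] * 5
                w.writerow([p.id, r.timepoint] + eq + drs)


def read_cohort(directory) -> list:
    """Load a cohort directory; malformed rows raise with the row number."""
    directory = Path(directory)

    resources: dict[str, list] = {}
    res_path = directory / "resources.csv"
    if res_path.exists():
        with open(res_path, newline="") as fh:
            for row_no, row in enumerate(csv.DictReader(fh), start=2):
                try:
                    resources.setdefault(row["patient_id"], []).append(
                        ResourceLine(row["category"], row["item"], float(row["quantity"]))
                    )
                except (ValueError, KeyError, ValidationError) as exc:
                    raise ValidationError(f"resources.csv row {row_no}: {exc}") from exc

    proms: dict[str, list] = {}
    prom_path = directory / "proms.csv"
    if prom_path.exists():
        with open(prom_path, newline="") as fh:
            for row_no, row in enumerate(csv.DictReader(fh), start=2):
                try:
                    eq_vals = [row[d].strip() for d in EQ5D_DIMENSIONS]
                    drs_vals = [row[f"drs{i}"].strip() for i in range(1, 6)]
                    eq5d = tuple(int(v) for v in eq_vals) if all(eq_vals) else None
                    drs = tuple(int(v) for v in drs_vals) if all(drs_vals) else None
                    proms.setdefault(row["patient_id"], []).append(
                        PromResponse(row["timepoint"], eq5d=eq5d, drs_items=drs)
                    )
                except (ValueError, KeyError, ValidationError) as exc:
                    raise ValidationError(f"proms.csv row {row_no}: {exc}") from exc

    cohort = []
    with open(directory / "cohort.csv", newline="") as fh:
        for row_no, row in enumerate(csv.DictReader(fh), start=2):
            try:
                complications = [
                    Complication(*tok.split(":", 1))
                    for tok in row["complications"].split(";")
                    if tok.strip()
                ]
                cohort.append(
                    PatientRecord(
                        id=row["id"],
                        codes=_parse_codes(row["codes"]),
                        historical_codes=_parse_codes(row["historical_codes"]),
                        diagnosis=row["diagnosis"],
                        cancer_primary=_parse_bool(row["cancer_primary"]),
                        cancer_recurrent=_parse_bool(row["cancer_recurrent"]),
                        cancer_metastatic=_parse_bool(row["cancer_metastatic"]),
                        exenteration_level=row["exenteration_level"],
                        reconstruction=row["reconstruction"],
                        survival_time=float(row["survival_time"]),
                        survival_event=_parse_bool(row["survival_event"]),
                        recurrence_time=_parse_float(row["recurrence_time"]),
                        recurrence_event=_parse_bool(row["recurrence_event"]),
                        local_recurrence_time=_parse_float(row["local_recurrence_time"]),
                        local_recurrence_event=_parse_bool(row["local_recurrence_event"]),
                        margin=Margin(row["margin"]),
                        benign_flag=_parse_bool(row["benign_flag"]),
                        complications=complications,
                        resources=resources.get(row["id"], []),
                        proms=proms.get(row["id"], []),
                        prom_participant=_parse_bool(row["prom_participant"]),
                        age=_parse_float(row["age"]),
                        sex=row["sex"] or None,
                        bmi=_parse_float(row["bmi"]),
                        asa=int(row["asa"]) if row["asa"].strip() else None,
                        smoking=row["smoking"] or None,
                    )
                )
            except (ValueError, KeyError, ValidationError) as exc:
                raise ValidationError(f"cohort.csv row {row_no}: {exc}") from exc
    return cohort
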