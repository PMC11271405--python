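"""Readers/writers for the four-table CSV interchange format.

The column contract lives in ``data/data_dictionary.json``; all four tables
are UTF-8 CSV with a mandatory header row. Optional fields serialize as empty
strings, booleans as ``true``/``false`` and integer-day lists as
semicolon-joined integers, so a write/read cycle is lossless.
"""

from __future__ import annotations

import csv
import json
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml

from .model import (
    AberrationClass,
    AnalysisConfig,
    Assessment,
    BaselineState,
    Cohort,
    CohortValidationError,
    CourseCategory,
    DiagnosisGroup,
    EnrollmentStatus,
    Modality,
    NonmeasurableStatus,
    Patient,
    Recommendation,
    TherapyType,
    Tier,
    TreatmentCourse,
)

TABLE_FILES = {
    "patients": "patients.csv",
    "recommendations": "recommendations.csv",
    "courses": "courses.csv",
    "assessments": "assessments.csv",
}


def data_dictionary() -> dict:
    with resources.files("pgtflow.data").joinpath("data_dictionary.json").open() as fh:
        return json.load(fh)


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, Enum):
        return str(value.value)
    if isinstance(value, float):
        return format(value, "g")
    if isinstance(value, list):
        return ";".join(str(v) for v in value)
    return str(value)


def _opt_int(s: str) -> Optional[int]:
    return int(s) if s not in ("", None) else None


def _opt_float(s: str) -> Optional[float]:
    return float(s) if s not in ("", None) else None


def _bool(s: str) -> bool:
    return s.strip().lower() in ("true", "1", "yes")


def _opt_bool(s: str) -> Optional[bool]:
    return _bool(s) if s not in ("", None) else None


def _int_list(s: str) -> list[int]:
    if s in ("", None):
        return []
    return [int(tok) for tok in s.split(";")]


def _check_header(name: str, header: list[str], expected: list[str]) -> None:
    missing = [c for c in expected if c not in header]
    if missing:
        raise CohortValidationError(f"{name}: missing columns {missing}")


def _read_rows(path: Path, name: str, expected: list[str]) -> list[dict]:
    if not path.exists():
        raise FileNotFoundError(f"{name} table not found: {path}")
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_header(name, reader.fieldnames or [], expected)
        return list(reader)


def read_cohort(in_dir: str | Path, validate: bool = True) -> Cohort:
    """Load and cross-validate the four cohort tables from a directory."""
    in_dir = Path(in_dir)
    dd = data_dictionary()

    rows = _read_rows(
        in_dir / TABLE_FILES["patients"], "patients", list(dd["patients"])
    )
    patients = [
        Patient(
            patient_id=r["patient_id"],
            diagnosis_group=DiagnosisGroup(r["diagnosis_group"]),
            enrollment_day=int(r["enrollment_day"]),
            enrollment_status=EnrollmentStatus(r["enrollment_status"]),
            mtb_day=int(r["mtb_day"]),
            death_day=_opt_int(r["death_day"]),
            last_followup_day=int(r["last_followup_day"]),
            progression_days=_int_list(r.get("progression_days", "")),
        )
        for r in rows
    ]

    rows = _read_rows(
        in_dir / TABLE_FILES["recommendations"],
        "recommendations",
        list(dd["recommendations"]),
    )
    recommendations = [
        Recommendation(
            recommendation_id=r["recommendation_id"],
            patient_id=r["patient_id"],
            tier=Tier(r["tier"]),
            target_gene=r["target_gene"],
            aberration_class=AberrationClass(r["aberration_class"]),
            therapy_type=TherapyType(r["therapy_type"]),
        )
        for r in rows
    ]

    rows = _read_rows(in_dir / TABLE_FILES["courses"], "courses", list(dd["courses"]))
    courses = [
        TreatmentCourse(
            course_id=r["course_id"],
            patient_id=r["patient_id"],
            category=CourseCategory(r["category"]),
            recommendation_id=r["recommendation_id"] or None,
            start_day=int(r["start_day"]),
            stop_day=int(r["stop_day"]),
            baseline_state=BaselineState(r["baseline_state"]),
            n_progressions_before_start=int(r["n_progressions_before_start"]),
            modality=Modality(r["modality"]),
            pre_mtb=_bool(r.get("pre_mtb", "")),
        )
        for r in rows
    ]

    rows = _read_rows(
        in_dir / TABLE_FILES["assessments"], "assessments", list(dd["assessments"])
    )
    assessments = [
        Assessment(
            course_id=r["course_id"],
            day=int(r["day"]),
            target_sum=_opt_float(r["target_sum"]),
            nonmeasurable_status=(
                NonmeasurableStatus(r["nonmeasurable_status"])
                if r["nonmeasurable_status"]
                else None
            ),
            new_lesions=_bool(r.get("new_lesions", "")),
            marrow_blast_pct=_opt_float(r["marrow_blast_pct"]),
            circulating_blast_abs=_opt_float(r["circulating_blast_abs"]),
            extramedullary=_opt_bool(r.get("extramedullary", "")),
        )
        for r in rows
    ]

    cohort = Cohort(patients, recommendations, courses, assessments)
    if validate:
        cohort.validate()
    return cohort


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the four cohort tables; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dd = data_dictionary()
    paths: dict[str, Path] = {}

    def dump(name: str, records: list[dict]) -> None:
        path = out_dir / TABLE_FILES[name]
        cols = list(dd[name])
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=cols, lineterminator="\n")
            writer.writeheader()
            for rec in records:
                writer.writerow({c: _fmt(rec.get(c)) for c in cols})
        paths[name] = path

    dump("patients", [vars(p).copy() for p in cohort.patients])
    dump("recommendations", [vars(r).copy() for r in cohort.recommendations])
    dump(
        "courses",
        [{**vars(c), "pre_mtb": c.pre_mtb or None} for c in cohort.courses],
    )
    dump("assessments", [vars(a).copy() for a in cohort.assessments])
    return paths


def load_config(path: Optional[str | Path]) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from YAML/JSON, or defaults if None."""
    if path is None:
        return AnalysisConfig()
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return AnalysisConfig.from_dict(data)
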