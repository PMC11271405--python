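"""Core data model for treatment-outcome cohorts.

All timestamps are integer day offsets from study start; calendar dates never
enter the system. Week-based rules translate as 1 week = 7 days (4 weeks = 28,
6 weeks = 42, 24 weeks = 168, 2 years = 730).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class DiagnosisGroup(str, Enum):
    CNS = "CNS"
    SOLID = "SOLID"
    HM = "HM"


class EnrollmentStatus(str, Enum):
    DIAGNOSIS = "DIAGNOSIS"
    FIRST_RELAPSE = "FIRST_RELAPSE"
    GE2_RELAPSE = "GE2_RELAPSE"


class Tier(str, Enum):
    T1 = "T1"
    T2 = "T2"
    T3 = "T3"
    T4 = "T4"
    T5 = "T5"


class AberrationClass(str, Enum):
    FUSION_SV = "FUSION_SV"
    SNV = "SNV"
    CNV = "CNV"
    HIGH_RNA_ONLY = "HIGH_RNA_ONLY"
    OTHER = "OTHER"


class TherapyType(str, Enum):
    TARGETED_MONO = "TARGETED_MONO"
    TARGETED_DUAL = "TARGETED_DUAL"
    TARGETED_PLUS_CHEMO = "TARGETED_PLUS_CHEMO"
    CHEMO = "CHEMO"


class CourseCategory(str, Enum):
    PGT = "PGT"
    UGT = "UGT"
    SOC = "SOC"
    OTHER = "OTHER"


class BaselineState(str, Enum):
    MEASURABLE = "MEASURABLE"
    NONMEASURABLE_EVALUABLE = "NONMEASURABLE_EVALUABLE"
    NED = "NED"


class Modality(str, Enum):
    RECIST = "RECIST"
    RANO = "RANO"
    PERCIST = "PERCIST"
    LEUKEMIA = "LEUKEMIA"


class NonmeasurableStatus(str, Enum):
    DISAPPEARED = "DISAPPEARED"
    PERSISTS = "PERSISTS"
    UNEQUIVOCAL_PROGRESSION = "UNEQUIVOCAL_PROGRESSION"


class ResponseCategory(str, Enum):
    CR = "CR"
    PR = "PR"
    SD = "SD"
    PD = "PD"
    NON_CR_NON_PD = "NON_CR_NON_PD"
    NE = "NE"


#: Severity ordering used to pick a best response (lower index = better).
RESPONSE_ORDER = [
    ResponseCategory.CR,
    ResponseCategory.PR,
    ResponseCategory.SD,
    ResponseCategory.NON_CR_NON_PD,
    ResponseCategory.PD,
]


class OcbStatus(str, Enum):
    YES = "YES"
    NO = "NO"
    NE = "NE"


class CohortValidationError(ValueError):
    """Raised when a cohort table violates a structural invariant."""


@dataclass
class Patient:
    patient_id: str
    diagnosis_group: DiagnosisGroup
    enrollment_day: int
    enrollment_status: EnrollmentStatus
    mtb_day: int
    death_day: Optional[int]
    last_followup_day: int
    progression_days: list[int] = field(default_factory=list)

    def validate(self) -> None:
        if not (self.enrollment_day <= self.mtb_day <= self.last_followup_day):
            raise CohortValidationError(
                f"patient {self.patient_id}: require enrollment_day <= mtb_day "
                f"<= last_followup_day, got ({self.enrollment_day}, "
                f"{self.mtb_day}, {self.last_followup_day})"
            )
        if self.death_day is not None and self.death_day != self.last_followup_day:
            raise CohortValidationError(
                f"patient {self.patient_id}: death_day must equal "
                f"last_followup_day when present"
            )
        if any(b <= a for a, b in zip(self.progression_days, self.progression_days[1:])):
            raise CohortValidationError(
                f"patient {self.patient_id}: progression_days must be strictly increasing"
            )


@dataclass
class Recommendation:
    recommendation_id: str
    patient_id: str
    tier: Tier
    target_gene: str
    aberration_class: AberrationClass
    therapy_type: TherapyType


@dataclass
class TreatmentCourse:
    course_id: str
    patient_id: str
    category: CourseCategory
    recommendation_id: Optional[str]
    start_day: int
    stop_day: int
    baseline_state: BaselineState
    n_progressions_before_start: int
    modality: Modality
    pre_mtb: bool = False

    def validate(self) -> None:
        if not self.start_day < self.stop_day:
            raise CohortValidationError(
                f"course {self.course_id}: start_day must precede stop_day"
            )
        if self.category is CourseCategory.PGT and not self.recommendation_id:
            raise CohortValidationError(
                f"course {self.course_id}: PGT course requires recommendation_id"
            )
        if self.n_progressions_before_start < 0:
            raise CohortValidationError(
                f"course {self.course_id}: n_progressions_before_start must be >= 0"
            )

    @property
    def duration(self) -> int:
        return self.stop_day - self.start_day


@dataclass
class Assessment:
    course_id: str
    day: int
    target_sum: Optional[float] = None
    nonmeasurable_status: Optional[NonmeasurableStatus] = None
    new_lesions: bool = False
    marrow_blast_pct: Optional[float] = None
    circulating_blast_abs: Optional[float] = None
    extramedullary: Optional[bool] = None

    def validate(self) -> None:
        if self.target_sum is not None and self.target_sum < 0:
            raise CohortValidationError(
                f"assessment for {self.course_id} day {self.day}: negative target_sum"
            )
        for name in ("marrow_blast_pct", "circulating_blast_abs"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise CohortValidationError(
                    f"assessment for {self.course_id} day {self.day}: negative {name}"
                )
        if self.marrow_blast_pct is not None and self.marrow_blast_pct > 100:
            raise CohortValidationError(
                f"assessment for {self.course_id} day {self.day}: "
                f"marrow_blast_pct above 100"
            )


@dataclass
class EndpointRecord:
    """Derived per-course outcomes."""

    course_id: str
    evaluable: bool
    exclusion_reason: Optional[str]
    best_response: ResponseCategory
    objective_response: bool
    ocb: OcbStatus
    pfs_days: Optional[int]
    pfs_event: Optional[bool]
    pfs_ratio: Optional[float] = None
    pfs_ratio_benefit: Optional[bool] = None
    pfs_ratio_reason: Optional[str] = None
    favorable_factors: Optional[int] = None


@dataclass
class Cohort:
    patients: list[Patient]
    recommendations: list[Recommendation]
    courses: list[TreatmentCourse]
    assessments: list[Assessment]

    def __post_init__(self) -> None:
        self._patients_by_id = {p.patient_id: p for p in self.patients}
        self._recs_by_id = {r.recommendation_id: r for r in self.recommendations}
        self._courses_by_id = {c.course_id: c for c in self.courses}

    def patient(self, patient_id: str) -> Patient:
        return self._patients_by_id[patient_id]

    def recommendation(self, recommendation_id: str) -> Recommendation:
        return self._recs_by_id[recommendation_id]

    def course(self, course_id: str) -> TreatmentCourse:
        return self._courses_by_id[course_id]

    def course_assessments(self, course_id: str) -> list[Assessment]:
        out = [a for a in self.assessments if a.course_id == course_id]
        out.sort(key=lambda a: a.day)
        return out

    def courses_for_patient(self, patient_id: str) -> list[TreatmentCourse]:
        out = [c for c in self.courses if c.patient_id == patient_id]
        out.sort(key=lambda c: (c.start_day, c.course_id))
        return out

    def counts(self) -> tuple[int, int, int, int]:
        return (
            len(self.patients),
            len(self.recommendations),
            len(self.courses),
            len(self.assessments),
        )

    def validate(self) -> None:
        """Check per-record invariants and referential integrity."""
        seen_pid: set[str] = set()
        for p in self.patients:
            if p.patient_id in seen_pid:
                raise CohortValidationError(f"duplicate patient_id {p.patient_id}")
            seen_pid.add(p.patient_id)
            p.validate()
        seen_rid: set[str] = set()
        for r in self.recommendations:
            if r.recommendation_id in seen_rid:
                raise CohortValidationError(
                    f"duplicate recommendation_id {r.recommendation_id}"
                )
            seen_rid.add(r.recommendation_id)
            if r.patient_id not in seen_pid:
                raise CohortValidationError(
                    f"recommendation {r.recommendation_id}: unknown patient_id "
                    f"{r.patient_id}"
                )
        seen_cid: set[str] = set()
        for c in self.courses:
            if c.course_id in seen_cid:
                raise CohortValidationError(f"duplicate course_id {c.course_id}")
            seen_cid.add(c.course_id)
            c.validate()
            if c.patient_id not in seen_pid:
                raise CohortValidationError(
                    f"course {c.course_id}: unknown patient_id {c.patient_id}"
                )
            if c.recommendation_id and c.recommendation_id not in seen_rid:
                raise CohortValidationError(
                    f"course {c.course_id}: unknown recommendation_id "
                    f"{c.recommendation_id}"
                )
            patient = self._patients_by_id[c.patient_id]
            if not c.pre_mtb and c.start_day < patient.mtb_day:
                raise CohortValidationError(
                    f"course {c.course_id}: starts before patient MTB day and is "
                    f"not flagged pre_mtb"
                )
        for a in self.assessments:
            a.validate()
            if a.course_id not in seen_cid:
                raise CohortValidationError(
                    f"assessment day {a.day}: unknown course_id {a.course_id}"
                )
            course = self._courses_by_id[a.course_id]
            if a.day < course.start_day:
                raise CohortValidationError(
                    f"assessment for {a.course_id} day {a.day}: precedes course start"
                )
            if course.modality is Modality.LEUKEMIA and a.marrow_blast_pct is None:
                raise CohortValidationError(
                    f"assessment for {a.course_id} day {a.day}: leukemia course "
                    f"requires marrow_blast_pct"
                )


#: Evidence flags feeding aberration classification, strongest first.
_ABERRATION_PRECEDENCE = ("FUSION_SV", "SNV", "CNV")


def classify_aberration(evidence_flags: set[str]) -> AberrationClass:
    """Collapse a set of molecular evidence flags into a single class.

    Precedence is FUSION_SV > SNV > CNV; HIGH_RNA_ONLY is assigned only when
    elevated RNA expression is the sole evidence for the target.
    """
    if not evidence_flags:
        raise ValueError("evidence_flags must be non-empty")
    allowed = set(_ABERRATION_PRECEDENCE) | {"HIGH_RNA"}
    unknown = evidence_flags - allowed
    if unknown:
        raise ValueError(f"unknown evidence flags: {sorted(unknown)}")
    for flag in _ABERRATION_PRECEDENCE:
        if flag in evidence_flags:
            return AberrationClass(flag)
    return AberrationClass.HIGH_RNA_ONLY


def round_pct(x: float) -> int:
    """Round a percentage half away from zero to an integer.

    Matches the reporting convention where 42.97 -> 43 and 54.64 -> 55.
    """
    if x >= 0:
        return int(math.floor(x + 0.5))
    return -int(math.floor(-x + 0.5))


@dataclass
class AnalysisConfig:
    """Knobs for adjudication and endpoint derivation."""

    cutoff_day: int = 1650
    thresholds: str = "paper"  # "paper" (+25% PD) or "recist11" (+20% PD)
    sd_min_day: int = 42  # SD only countable at >= this many days after start
    evaluable_min_days: int = 28
    ocb_min_days: int = 168
    pfs_ratio_cut: float = 1.3
    pfs_ratio_min_gain: int = 28

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        unknown = set(d) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)
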