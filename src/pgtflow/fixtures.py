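"""Deterministic hand-built fixtures.

``printed_counts`` is a fully worked cohort engineered so that the
adjudication and endpoint pipeline reproduces the published course-level
tallies exactly: 117 administered index treatments of which 18 are excluded
(14 shorter than 4 weeks, 4 with early progression), 99 eligible; 70 with
measurable disease adjudicating to 6 CR / 19 PR / 24 SD / 21 PD; 20
non-measurable adjudicating to 2 CR / 10 non-CR-non-PD / 8 PD; 9 disease-free
at start; 97 courses assessable for 24-week clinical benefit with 53
successes; and 31 courses assessable for the intra-patient PFS ratio with 13
showing benefit. Uptake denominators match as well: 256 patients carry at
least one recommendation, 110 of whom were treated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .model import (
    AberrationClass,
    Assessment,
    BaselineState,
    Cohort,
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

FIXTURE_NAMES = ("printed_counts", "km_toy", "leukemia_edge")

# ---------------------------------------------------------------------------
# printed_counts
# ---------------------------------------------------------------------------

# Per-course scripts. Days are relative to the course start (start = MTB + 10).
# kind: MEAS / NONMEAS / NED / SHORT / EARLY_PD
# resp: target best response; ocb: YES / NO / NE via the constructed timeline.


@dataclass
class _CourseScript:
    kind: str
    resp: Optional[str] = None
    pd_day: Optional[int] = None  # relative first-progression day
    stop_day: Optional[int] = None  # relative stop; defaults to pd_day or 400
    ratio: Optional[str] = None  # None | "benefit" | "no_benefit"
    tier: Tier = Tier.T3
    aberration: AberrationClass = AberrationClass.SNV
    extra: dict = field(default_factory=dict)


def _printed_counts_scripts() -> list[_CourseScript]:
    scripts: list[_CourseScript] = []

    # 14 too-short courses, 4 early-progression courses -> 18 exclusions
    scripts += [_CourseScript(kind="SHORT") for _ in range(14)]
    scripts += [_CourseScript(kind="EARLY_PD") for _ in range(4)]

    # 70 measurable: 6 CR, 19 PR (17 sustained, 2 progressing at day 100),
    # 24 SD (20 holding past 24 weeks, 1 stopping early in SD, 3 progressing
    # at day 100), 21 PD at day 56
    scripts += [_CourseScript(kind="MEAS", resp="CR") for _ in range(6)]
    scripts += [_CourseScript(kind="MEAS", resp="PR") for _ in range(17)]
    scripts += [
        _CourseScript(kind="MEAS", resp="PR", pd_day=100) for _ in range(2)
    ]
    scripts += [
        _CourseScript(kind="MEAS", resp="SD", pd_day=200) for _ in range(20)
    ]
    scripts += [_CourseScript(kind="MEAS", resp="SD", stop_day=100)]
    scripts += [
        _CourseScript(kind="MEAS", resp="SD", pd_day=100) for _ in range(3)
    ]
    scripts += [_CourseScript(kind="MEAS", resp="PD", pd_day=56) for _ in range(21)]

    # 20 non-measurable: 2 CR, 10 non-CR-non-PD (8 holding past 24 weeks,
    # 1 stopping early, 1 progressing at day 100), 8 PD
    scripts += [_CourseScript(kind="NONMEAS", resp="CR") for _ in range(2)]
    scripts += [
        _CourseScript(kind="NONMEAS", resp="NON_CR_NON_PD", pd_day=200)
        for _ in range(8)
    ]
    scripts += [_CourseScript(kind="NONMEAS", resp="NON_CR_NON_PD", stop_day=100)]
    scripts += [_CourseScript(kind="NONMEAS", resp="NON_CR_NON_PD", pd_day=100)]
    scripts += [
        _CourseScript(kind="NONMEAS", resp="PD", pd_day=56) for _ in range(8)
    ]

    # 9 disease-free at start, all relapsing at day 90
    scripts += [_CourseScript(kind="NED", pd_day=90) for _ in range(9)]

    # PFS-ratio comparators: 13 benefit cases on SD courses holding 200 days
    # (comparator progressed at 100 days -> ratio 2.0, gain 100 >= 28) and 18
    # non-benefit cases on PD courses (comparator also 56 days -> ratio 1.0)
    n_benefit = 0
    n_no_benefit = 0
    for s in scripts:
        if (
            n_benefit < 13
            and s.kind == "MEAS"
            and s.resp == "SD"
            and s.pd_day == 200
        ):
            s.ratio = "benefit"
            n_benefit += 1
        elif n_no_benefit < 18 and s.kind == "MEAS" and s.resp == "PD":
            s.ratio = "no_benefit"
            n_no_benefit += 1
    assert n_benefit == 13 and n_no_benefit == 18

    # spread tiers/aberrations deterministically for stratified reporting
    tiers = [Tier.T1, Tier.T2, Tier.T3, Tier.T1, Tier.T2]
    abs_cycle = [
        AberrationClass.SNV,
        AberrationClass.FUSION_SV,
        AberrationClass.HIGH_RNA_ONLY,
        AberrationClass.CNV,
        AberrationClass.SNV,
    ]
    for idx, s in enumerate(scripts):
        s.tier = tiers[idx % len(tiers)]
        s.aberration = abs_cycle[idx % len(abs_cycle)]
    return scripts


_CUTOFF = 1600
_MTB = 120
_START = _MTB + 10  # absolute start day of every index course
_BASE_SUM = 50.0


def _build_printed_counts() -> Cohort:
    patients: list[Patient] = []
    recommendations: list[Recommendation] = []
    courses: list[TreatmentCourse] = []
    assessments: list[Assessment] = []

    scripts = _printed_counts_scripts()

    # 117 courses distributed over 110 treated patients: 104 patients with one
    # course, 5 with two, 1 with three. Seven of the 14 too-short courses are
    # second/third courses of the multi-course patients, so the endpoint
    # tallies are carried entirely by each patient's index course.
    short_indices = [i for i, s in enumerate(scripts) if s.kind == "SHORT"]
    second_courses = dict(zip(short_indices[:7], [104, 105, 106, 107, 108, 109, 109]))
    next_patient = 0
    owners: list[int] = [0] * len(scripts)
    for i in range(len(scripts)):
        if i in second_courses:
            owners[i] = second_courses[i]
        else:
            owners[i] = next_patient
            next_patient += 1
    assert next_patient == 110

    made_patient: set[int] = set()
    for i, s in enumerate(scripts):
        p_idx = owners[i]
        pid = f"T{p_idx + 1:04d}"
        rid = f"RT{p_idx + 1:04d}"
        needs_prior = s.ratio is not None
        if p_idx not in made_patient:
            made_patient.add(p_idx)
            status = (
                EnrollmentStatus.FIRST_RELAPSE
                if needs_prior
                else EnrollmentStatus.DIAGNOSIS
            )
            progression: list[int] = []
            if needs_prior:
                prior_pfs = 100 if s.ratio == "benefit" else 56
                progression.append(prior_pfs)
            if s.pd_day is not None:
                progression.append(_START + s.pd_day)
            patients.append(
                Patient(
                    patient_id=pid,
                    diagnosis_group=DiagnosisGroup.SOLID
                    if i % 2
                    else DiagnosisGroup.CNS,
                    enrollment_day=0,
                    enrollment_status=status,
                    mtb_day=_MTB,
                    death_day=None,
                    last_followup_day=_CUTOFF,
                    progression_days=sorted(set(progression)),
                )
            )
            recommendations.append(
                Recommendation(
                    recommendation_id=rid,
                    patient_id=pid,
                    tier=s.tier,
                    target_gene=f"GENE{i:03d}",
                    aberration_class=s.aberration,
                    therapy_type=TherapyType.TARGETED_MONO,
                )
            )

        patient = next(p for p in patients if p.patient_id == pid)
        modality = (
            Modality.RANO
            if patient.diagnosis_group is DiagnosisGroup.CNS
            else Modality.RECIST
        )
        cid = f"CT{i + 1:04d}"

        if needs_prior:
            # comparator treatment: starts at enrollment, progresses at its
            # PFS; given for relapsed disease
            prior_pfs = 100 if s.ratio == "benefit" else 56
            prior_id = f"{cid}P"
            courses.append(
                TreatmentCourse(
                    course_id=prior_id,
                    patient_id=pid,
                    category=CourseCategory.SOC,
                    recommendation_id=None,
                    start_day=0,
                    stop_day=prior_pfs,
                    baseline_state=BaselineState.MEASURABLE,
                    n_progressions_before_start=1,
                    modality=modality,
                    pre_mtb=True,
                )
            )
            assessments.append(
                Assessment(course_id=prior_id, day=0, target_sum=_BASE_SUM)
            )
            assessments.append(
                Assessment(
                    course_id=prior_id, day=prior_pfs, target_sum=_BASE_SUM * 1.6
                )
            )

        start = _START
        if s.kind == "SHORT":
            if i in second_courses:
                start = _START + 420  # later line of therapy for multi patients
            stop = start + 21
            courses.append(
                TreatmentCourse(
                    course_id=cid,
                    patient_id=pid,
                    category=CourseCategory.PGT,
                    recommendation_id=rid,
                    start_day=start,
                    stop_day=stop,
                    baseline_state=BaselineState.MEASURABLE,
                    n_progressions_before_start=1 if needs_prior else 0,
                    modality=modality,
                    pre_mtb=False,
                )
            )
            assessments.append(
                Assessment(course_id=cid, day=start, target_sum=_BASE_SUM)
            )
            continue

        if s.kind == "EARLY_PD":
            stop = start + 60
            courses.append(
                TreatmentCourse(
                    course_id=cid,
                    patient_id=pid,
                    category=CourseCategory.PGT,
                    recommendation_id=rid,
                    start_day=start,
                    stop_day=stop,
                    baseline_state=BaselineState.MEASURABLE,
                    n_progressions_before_start=0,
                    modality=modality,
                    pre_mtb=False,
                )
            )
            assessments.append(
                Assessment(course_id=cid, day=start, target_sum=_BASE_SUM)
            )
            assessments.append(
                Assessment(course_id=cid, day=start + 20, target_sum=_BASE_SUM * 1.6)
            )
            continue

        pd_day = s.pd_day
        default_stop = pd_day if pd_day is not None else 400
        stop_rel = s.stop_day if s.stop_day is not None else default_stop
        baseline_state = {
            "MEAS": BaselineState.MEASURABLE,
            "NONMEAS": BaselineState.NONMEASURABLE_EVALUABLE,
            "NED": BaselineState.NED,
        }[s.kind]
        courses.append(
            TreatmentCourse(
                course_id=cid,
                patient_id=pid,
                category=CourseCategory.PGT,
                recommendation_id=rid,
                start_day=start,
                stop_day=start + stop_rel,
                baseline_state=baseline_state,
                n_progressions_before_start=1 if needs_prior else 0,
                modality=modality,
                pre_mtb=False,
            )
        )

        if s.kind == "MEAS":
            assessments.append(
                Assessment(course_id=cid, day=start, target_sum=_BASE_SUM)
            )
            resp_sum = {
                "CR": 0.0,
                "PR": _BASE_SUM * (0.4 if modality is Modality.RANO else 0.6),
                "SD": _BASE_SUM * 0.9,
            }
            if s.resp in ("CR", "PR"):
                assessments.append(
                    Assessment(course_id=cid, day=start + 56, target_sum=resp_sum[s.resp])
                )
            elif s.resp == "SD":
                assessments.append(
                    Assessment(course_id=cid, day=start + 49, target_sum=resp_sum["SD"])
                )
            if pd_day is not None and s.resp != "PD":
                assessments.append(
                    Assessment(
                        course_id=cid, day=start + pd_day, target_sum=_BASE_SUM * 1.6
                    )
                )
            if s.resp == "PD":
                assessments.append(
                    Assessment(
                        course_id=cid, day=start + pd_day, target_sum=_BASE_SUM * 1.6
                    )
                )
        elif s.kind == "NONMEAS":
            assessments.append(
                Assessment(
                    course_id=cid,
                    day=start,
                    nonmeasurable_status=NonmeasurableStatus.PERSISTS,
                )
            )
            if s.resp == "CR":
                assessments.append(
                    Assessment(
                        course_id=cid,
                        day=start + 56,
                        nonmeasurable_status=NonmeasurableStatus.DISAPPEARED,
                    )
                )
            elif s.resp == "NON_CR_NON_PD":
                assessments.append(
                    Assessment(
                        course_id=cid,
                        day=start + 49,
                        nonmeasurable_status=NonmeasurableStatus.PERSISTS,
                    )
                )
            if pd_day is not None:
                assessments.append(
                    Assessment(
                        course_id=cid,
                        day=start + pd_day,
                        nonmeasurable_status=NonmeasurableStatus.UNEQUIVOCAL_PROGRESSION,
                    )
                )
        else:  # NED
            assessments.append(Assessment(course_id=cid, day=start, new_lesions=False))
            assessments.append(
                Assessment(course_id=cid, day=start + pd_day, new_lesions=True)
            )

    # 146 patients with a recommendation but no treatment (-> 256 recommended)
    for j in range(146):
        pid = f"U{j + 1:04d}"
        patients.append(
            Patient(
                patient_id=pid,
                diagnosis_group=DiagnosisGroup.SOLID if j % 2 else DiagnosisGroup.CNS,
                enrollment_day=0,
                enrollment_status=EnrollmentStatus.DIAGNOSIS,
                mtb_day=_MTB,
                death_day=None,
                last_followup_day=_CUTOFF,
                progression_days=[],
            )
        )
        recommendations.append(
            Recommendation(
                recommendation_id=f"RU{j + 1:04d}",
                patient_id=pid,
                tier=Tier.T3,
                target_gene=f"GENE{j:03d}",
                aberration_class=AberrationClass.SNV,
                therapy_type=TherapyType.TARGETED_MONO,
            )
        )

    cohort = Cohort(patients, recommendations, courses, assessments)
    cohort.validate()
    return cohort


# ---------------------------------------------------------------------------
# km_toy and leukemia_edge
# ---------------------------------------------------------------------------

KM_TOY = {"durations": [1, 2, 3, 4, 5], "events": [True, False, True, False, True]}


def _build_leukemia_edge() -> Cohort:
    """One leukemia patient per rule branch: CR, band PR, reduction PR,
    PD after CR, PD after PR, circulating-blast PD, and SD."""
    specs = [
        ("CR", [(56, 3.0, 0.0)]),
        ("PR_band", [(56, 15.0, 0.0)]),
        ("PR_reduction", [(56, 30.0, 0.0)]),  # 80 -> 30: >50% relative, 50 abs
        ("PD_after_CR", [(56, 3.0, 0.0), (120, 12.0, 0.0)]),
        ("PD_after_PR", [(56, 15.0, 0.0), (120, 45.0, 0.0)]),
        ("PD_circulating", [(56, 85.0, 40.0)]),
        ("SD", [(56, 70.0, 0.0)]),
    ]
    patients, recs, courses, assessments = [], [], [], []
    for i, (label, points) in enumerate(specs):
        pid = f"L{i + 1:03d}"
        cid = f"CL{i + 1:03d}"
        rid = f"RL{i + 1:03d}"
        patients.append(
            Patient(
                patient_id=pid,
                diagnosis_group=DiagnosisGroup.HM,
                enrollment_day=0,
                enrollment_status=EnrollmentStatus.FIRST_RELAPSE,
                mtb_day=30,
                death_day=None,
                last_followup_day=800,
                progression_days=[],
            )
        )
        recs.append(
            Recommendation(
                recommendation_id=rid,
                patient_id=pid,
                tier=Tier.T1,
                target_gene="GENE001",
                aberration_class=AberrationClass.FUSION_SV,
                therapy_type=TherapyType.TARGETED_MONO,
            )
        )
        courses.append(
            TreatmentCourse(
                course_id=cid,
                patient_id=pid,
                category=CourseCategory.PGT,
                recommendation_id=rid,
                start_day=40,
                stop_day=240,
                baseline_state=BaselineState.MEASURABLE,
                n_progressions_before_start=1,
                modality=Modality.LEUKEMIA,
                pre_mtb=False,
            )
        )
        assessments.append(
            Assessment(
                course_id=cid,
                day=40,
                marrow_blast_pct=80.0,
                circulating_blast_abs=0.0,
                extramedullary=False,
            )
        )
        for day_rel, marrow, circ in points:
            assessments.append(
                Assessment(
                    course_id=cid,
                    day=40 + day_rel,
                    marrow_blast_pct=marrow,
                    circulating_blast_abs=circ,
                    extramedullary=False,
                )
            )
    cohort = Cohort(patients, recs, courses, assessments)
    cohort.validate()
    return cohort


#: Expected best responses for the leukemia_edge courses, in course order.
LEUKEMIA_EDGE_EXPECTED = ["CR", "PR", "PR", "CR", "PR", "PD", "SD"]


def make_fixture(name: str):
    """Return a shipped deterministic fixture by name.

    ``printed_counts`` and ``leukemia_edge`` return :class:`Cohort` objects;
    ``km_toy`` returns a dict with ``durations`` and ``events``.
    """
    if name == "printed_counts":
        return _build_printed_counts()
    if name == "km_toy":
        return {k: list(v) for k, v in KM_TOY.items()}
    if name == "leukemia_edge":
        return _build_leukemia_edge()
    raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
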