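"""Analysis-set filters and per-course/per-patient endpoint derivation.

Implements the evaluability filter (>= 4 weeks on treatment, no progression
in the first 4 weeks, a response evaluation available), treatment-anchored
PFS, objective clinical benefit (OCB), the intra-patient PFS ratio with its
five eligibility criteria, overall-survival grouping by first post-MTB
treatment, and the 0-3 favorable-factor score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .adjudication import AdjudicatedCourse, adjudicate_cohort
from .model import (
    AberrationClass,
    AnalysisConfig,
    BaselineState,
    Cohort,
    CourseCategory,
    DiagnosisGroup,
    EndpointRecord,
    EnrollmentStatus,
    OcbStatus,
    Patient,
    ResponseCategory,
    Tier,
    TreatmentCourse,
)

# Exclusion reason codes (audit trail vocabulary)
REASON_SHORT_DURATION = "duration<4wk"
REASON_EARLY_PD = "early PD"
REASON_NO_EVALUATION = "no evaluation"


@dataclass
class PfsResult:
    days: int
    event: bool
    event_is_pd: bool = False


@dataclass
class PfsRatioResult:
    eligible: bool
    reason: Optional[str] = None
    ratio: Optional[float] = None
    benefit: Optional[bool] = None
    pfs1_days: Optional[int] = None
    pfs2_days: Optional[int] = None
    comparator_course_id: Optional[str] = None


@dataclass
class OsGroupAssignment:
    patient_id: str
    group: CourseCategory  # category of the first post-MTB treatment
    origin_day: int  # OS clock origin
    first_course_id: str


@dataclass
class AnalysisSets:
    """Reason-coded audit trail of every analysis-set decision."""

    pfs_set: list[str] = field(default_factory=list)
    exclusions: dict[str, str] = field(default_factory=dict)  # course_id -> reason
    os_groups: dict[str, OsGroupAssignment] = field(default_factory=dict)
    os_excluded: list[str] = field(default_factory=list)  # patient ids, no new course
    ocb_set: list[str] = field(default_factory=list)
    pfs_ratio_set: list[str] = field(default_factory=list)
    response_evaluable_set: list[str] = field(default_factory=list)
    response_measurable_set: list[str] = field(default_factory=list)


def is_evaluable(
    course: TreatmentCourse,
    adjudicated: AdjudicatedCourse,
    config: Optional[AnalysisConfig] = None,
) -> tuple[bool, Optional[str]]:
    """Outcome-analysis evaluability with a reason code on failure."""
    config = config or AnalysisConfig()
    if course.duration < config.evaluable_min_days:
        return False, REASON_SHORT_DURATION
    if (
        adjudicated.first_pd_day is not None
        and adjudicated.first_pd_day - course.start_day < config.evaluable_min_days
    ):
        return False, REASON_EARLY_PD
    if not adjudicated.has_post_baseline:
        return False, REASON_NO_EVALUATION
    return True, None


def compute_pfs(
    course: TreatmentCourse,
    adjudicated: AdjudicatedCourse,
    patient: Patient,
    cutoff_day: int,
) -> PfsResult:
    """Time from treatment start to progression or death from any cause,
    censored at min(cutoff, last follow-up)."""
    pd_day = adjudicated.first_pd_day
    if pd_day is not None and pd_day < course.start_day:
        raise ValueError(
            f"course {course.course_id}: progression precedes treatment start"
        )
    candidates = []  # (day, priority): progression outranks death on ties
    if pd_day is not None:
        candidates.append((pd_day, 0))
    if patient.death_day is not None:
        candidates.append((patient.death_day, 1))
    censor_day = min(cutoff_day, patient.last_followup_day)
    if candidates:
        event_day, prio = min(candidates)
        if event_day <= cutoff_day:
            return PfsResult(
                days=event_day - course.start_day, event=True, event_is_pd=prio == 0
            )
    return PfsResult(days=censor_day - course.start_day, event=False)


def _response_clock_end(
    course: TreatmentCourse, adjudicated: AdjudicatedCourse
) -> int:
    """Day the response observation clock ends: first progression or
    treatment stop, whichever comes first."""
    if adjudicated.first_pd_day is not None:
        return min(adjudicated.first_pd_day, course.stop_day)
    return course.stop_day


def compute_ocb(
    course: TreatmentCourse,
    adjudicated: AdjudicatedCourse,
    config: Optional[AnalysisConfig] = None,
) -> OcbStatus:
    """Objective clinical benefit: disease control sustained >= 24 weeks.

    Measurable disease: best response CR/PR/SD held for >= 168 days from
    treatment start. Non-measurable: CR or non-CR/non-PD held >= 168 days.
    Disease-free at start: no recurrence for >= 168 days. A course whose best
    response is SD (or non-CR/non-PD) but which stopped before 24 weeks while
    still in SD cannot be assessed and is NE.
    """
    config = config or AnalysisConfig()
    horizon = config.ocb_min_days
    start = course.start_day
    clock_end = _response_clock_end(course, adjudicated)
    sustained = clock_end - start

    if course.baseline_state is BaselineState.NED:
        if adjudicated.first_pd_day is not None:
            return (
                OcbStatus.YES
                if adjudicated.first_pd_day - start >= horizon
                else OcbStatus.NO
            )
        return OcbStatus.YES if sustained >= horizon else OcbStatus.NE

    best = adjudicated.best_response
    if best is ResponseCategory.PD:
        return OcbStatus.NO
    if best is ResponseCategory.NE:
        return OcbStatus.NE

    if course.baseline_state is BaselineState.MEASURABLE:
        controlled = best in (
            ResponseCategory.CR,
            ResponseCategory.PR,
            ResponseCategory.SD,
        )
    else:
        controlled = best in (
            ResponseCategory.CR,
            ResponseCategory.NON_CR_NON_PD,
        )
    if controlled and sustained >= horizon:
        return OcbStatus.YES
    stable_best = best in (ResponseCategory.SD, ResponseCategory.NON_CR_NON_PD)
    if (
        stable_best
        and adjudicated.first_pd_day is None
        and course.stop_day - start < horizon
    ):
        # stopped or changed treatment before 24 weeks while still in SD
        return OcbStatus.NE
    return OcbStatus.NO


def pfs_ratio(
    pgt_course: TreatmentCourse,
    pgt_pfs: PfsResult,
    pgt_adjudicated: AdjudicatedCourse,
    prior_course: Optional[TreatmentCourse],
    prior_pfs: Optional[PfsResult],
    patient: Patient,
    config: Optional[AnalysisConfig] = None,
) -> PfsRatioResult:
    """Intra-patient PFS ratio (index PFS over the most recent prior
    progressed treatment) with its five eligibility criteria.

    Criteria: (1) no progression within the first 4 weeks of the index
    treatment; (2) if the index treatment has not progressed at cutoff, its
    duration must be at least the comparator's; (3) the comparator ended in
    progression; (4) the comparator was given for relapsed/refractory
    disease; (5) both durations >= 4 weeks. Benefit requires ratio > 1.3 and
    an absolute gain >= 28 days.
    """
    config = config or AnalysisConfig()
    if prior_course is None or prior_pfs is None:
        return PfsRatioResult(eligible=False, reason="no comparator")
    min_days = config.pfs_ratio_min_gain
    first_pd = pgt_adjudicated.first_pd_day
    if first_pd is not None and first_pd - pgt_course.start_day < 28:
        return PfsRatioResult(eligible=False, reason="PD within 4wk of index treatment")
    if not (prior_pfs.event and prior_pfs.event_is_pd):
        return PfsRatioResult(eligible=False, reason="comparator did not end in PD")
    relapsed = (
        prior_course.n_progressions_before_start > 0
        or patient.enrollment_status is not EnrollmentStatus.DIAGNOSIS
    )
    if not relapsed:
        return PfsRatioResult(
            eligible=False, reason="comparator not given for relapsed/refractory disease"
        )
    if pgt_pfs.days < 28 or prior_pfs.days < 28:
        return PfsRatioResult(eligible=False, reason="duration<4wk")
    if not pgt_pfs.event:
        # index treatment not progressed at cutoff: the censored duration must
        # match or exceed the comparator's, and the ratio is computed
        # conservatively on the censored duration
        if pgt_pfs.days < prior_pfs.days:
            return PfsRatioResult(
                eligible=False, reason="censored index duration shorter than comparator"
            )
    ratio = pgt_pfs.days / prior_pfs.days
    benefit = (ratio > config.pfs_ratio_cut) and (
        pgt_pfs.days - prior_pfs.days >= min_days
    )
    return PfsRatioResult(
        eligible=True,
        ratio=ratio,
        benefit=benefit,
        pfs1_days=prior_pfs.days,
        pfs2_days=pgt_pfs.days,
        comparator_course_id=prior_course.course_id,
    )


def find_pfs_ratio_comparator(
    cohort: Cohort,
    pgt_course: TreatmentCourse,
    pfs_by_course: dict[str, PfsResult],
) -> Optional[TreatmentCourse]:
    """Most recent treatment before the index course on which the patient
    progressed."""
    candidates = [
        c
        for c in cohort.courses_for_patient(pgt_course.patient_id)
        if c.start_day < pgt_course.start_day
        and c.course_id in pfs_by_course
        and pfs_by_course[c.course_id].event
        and pfs_by_course[c.course_id].event_is_pd
    ]
    if not candidates:
        return None
    return max(candidates, key=lambda c: c.start_day)


def assign_os_groups(cohort: Cohort) -> tuple[dict[str, OsGroupAssignment], list[str]]:
    """Assign each patient to the category of the first treatment started
    after MTB discussion; the OS clock starts at that treatment (for patients
    whose group is PGT and who received several, at the first PGT).

    Patients with no new post-MTB treatment are excluded and listed
    separately.
    """
    groups: dict[str, OsGroupAssignment] = {}
    excluded: list[str] = []
    for patient in cohort.patients:
        post_mtb = [
            c
            for c in cohort.courses_for_patient(patient.patient_id)
            if not c.pre_mtb and c.start_day >= patient.mtb_day
        ]
        if not post_mtb:
            excluded.append(patient.patient_id)
            continue
        first = post_mtb[0]
        origin = first.start_day
        if first.category is CourseCategory.PGT:
            pgt_starts = [
                c.start_day for c in post_mtb if c.category is CourseCategory.PGT
            ]
            origin = min(pgt_starts)
        groups[patient.patient_id] = OsGroupAssignment(
            patient_id=patient.patient_id,
            group=first.category,
            origin_day=origin,
            first_course_id=first.course_id,
        )
    return groups, excluded


def favorable_factors(
    course: TreatmentCourse,
    recommendation,
    patient: Patient,
) -> Optional[int]:
    """Count of favorable factors for an index treatment: tier-1 evidence,
    a fusion/SV target, and no disease progression between enrollment and
    treatment start. Not defined for hematologic malignancies or non-index
    treatments."""
    if course.category is not CourseCategory.PGT:
        return None
    if patient.diagnosis_group is DiagnosisGroup.HM:
        return None
    score = 0
    if recommendation is not None and recommendation.tier is Tier.T1:
        score += 1
    if (
        recommendation is not None
        and recommendation.aberration_class is AberrationClass.FUSION_SV
    ):
        score += 1
    if course.n_progressions_before_start == 0:
        score += 1
    return score


def derive_endpoints(
    cohort: Cohort,
    config: Optional[AnalysisConfig] = None,
    adjudicated: Optional[dict[str, AdjudicatedCourse]] = None,
) -> tuple[list[EndpointRecord], AnalysisSets]:
    """Full endpoint derivation over a cohort.

    Adjudicates every course, applies the evaluability filter with a
    reason-coded audit trail, computes PFS/OCB for evaluable courses, PFS
    ratios for index (PGT) courses, OS groups per patient, and the
    favorable-factor score.
    """
    config = config or AnalysisConfig()
    if adjudicated is None:
        adjudicated = adjudicate_cohort(cohort, config)

    sets = AnalysisSets()
    records: list[EndpointRecord] = []

    # PFS for every course with enough data (used both for the PFS set and as
    # comparator durations in the PFS-ratio analysis).
    pfs_by_course: dict[str, PfsResult] = {}
    for course in cohort.courses:
        adj = adjudicated[course.course_id]
        patient = cohort.patient(course.patient_id)
        try:
            pfs_by_course[course.course_id] = compute_pfs(
                course, adj, patient, config.cutoff_day
            )
        except ValueError:
            continue

    sets.os_groups, os_excluded = assign_os_groups(cohort)
    sets.os_excluded = os_excluded

    for course in cohort.courses:
        adj = adjudicated[course.course_id]
        patient = cohort.patient(course.patient_id)
        ok, reason = is_evaluable(course, adj, config)
        rec = (
            cohort.recommendation(course.recommendation_id)
            if course.recommendation_id
            else None
        )
        ff = favorable_factors(course, rec, patient)

        if not ok:
            sets.exclusions[course.course_id] = reason
            records.append(
                EndpointRecord(
                    course_id=course.course_id,
                    evaluable=False,
                    exclusion_reason=reason,
                    best_response=ResponseCategory.NE,
                    objective_response=False,
                    ocb=OcbStatus.NE,
                    pfs_days=None,
                    pfs_event=None,
                    favorable_factors=ff,
                )
            )
            continue

        sets.pfs_set.append(course.course_id)
        pfs = pfs_by_course[course.course_id]
        ocb = compute_ocb(course, adj, config)
        if ocb is not OcbStatus.NE:
            sets.ocb_set.append(course.course_id)
        if course.baseline_state is not BaselineState.NED:
            sets.response_evaluable_set.append(course.course_id)
            if course.baseline_state is BaselineState.MEASURABLE:
                sets.response_measurable_set.append(course.course_id)

        ratio_res = PfsRatioResult(eligible=False, reason="not an index treatment")
        if course.category is CourseCategory.PGT:
            prior = find_pfs_ratio_comparator(cohort, course, pfs_by_course)
            ratio_res = pfs_ratio(
                course,
                pfs,
                adj,
                prior,
                pfs_by_course.get(prior.course_id) if prior else None,
                patient,
                config,
            )
            if ratio_res.eligible:
                sets.pfs_ratio_set.append(course.course_id)

        best = adj.best_response
        records.append(
            EndpointRecord(
                course_id=course.course_id,
                evaluable=True,
                exclusion_reason=None,
                best_response=best,
                objective_response=best
                in (ResponseCategory.CR, ResponseCategory.PR),
                ocb=ocb,
                pfs_days=pfs.days,
                pfs_event=pfs.event,
                pfs_ratio=ratio_res.ratio,
                pfs_ratio_benefit=ratio_res.benefit,
                pfs_ratio_reason=ratio_res.reason,
                favorable_factors=ff,
            )
        )

    return records, sets
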