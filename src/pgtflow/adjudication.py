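"""Per-assessment response classification and per-course best response.

Four modality rule sets are supported: percent-change bands over a target
lesion sum (solid-tumor and CNS imaging, and PET treated as a percent change
of its uptake-derived target quantity), a categorical scheme for evaluable
but non-measurable disease, and a marrow/circulating blast scheme for acute
leukemia.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .model import (
    AnalysisConfig,
    Assessment,
    BaselineState,
    Modality,
    NonmeasurableStatus,
    RESPONSE_ORDER,
    ResponseCategory,
    TreatmentCourse,
)


@dataclass(frozen=True)
class ResponseThresholds:
    """Percent-change bands as signed fractions.

    ``pr_cut`` (negative) is the largest change still qualifying as PR;
    ``pd_cut`` (positive) is the smallest change qualifying as PD. Both
    boundaries are inclusive; SD is the open interval between. A -100% change
    (total disappearance) is CR.
    """

    pr_cut: float
    pd_cut: float

    def __post_init__(self) -> None:
        if not (self.pr_cut < 0 < self.pd_cut):
            raise ValueError("require pr_cut < 0 < pd_cut")


#: Threshold sets keyed by (set name, modality). "paper" uses the published
#: waterfall bands (+25% PD for all imaging modalities); "recist11" swaps in
#: the +20% PD boundary for solid-tumor imaging.
THRESHOLD_SETS: dict[str, dict[Modality, ResponseThresholds]] = {
    "paper": {
        Modality.RANO: ResponseThresholds(pr_cut=-0.50, pd_cut=0.25),
        Modality.RECIST: ResponseThresholds(pr_cut=-0.30, pd_cut=0.25),
        Modality.PERCIST: ResponseThresholds(pr_cut=-0.30, pd_cut=0.25),
    },
    "recist11": {
        Modality.RANO: ResponseThresholds(pr_cut=-0.50, pd_cut=0.25),
        Modality.RECIST: ResponseThresholds(pr_cut=-0.30, pd_cut=0.20),
        Modality.PERCIST: ResponseThresholds(pr_cut=-0.30, pd_cut=0.20),
    },
}


def thresholds_for(modality: Modality, set_name: str = "paper") -> ResponseThresholds:
    try:
        return THRESHOLD_SETS[set_name][modality]
    except KeyError:
        raise KeyError(f"no thresholds for {modality} in set {set_name!r}") from None


def classify_target_change(
    baseline_sum: float,
    current_sum: float,
    thresholds: ResponseThresholds,
    new_lesions: bool = False,
) -> ResponseCategory:
    """Classify a target-lesion sum change against percent-change bands."""
    if baseline_sum <= 0:
        raise ValueError("baseline_sum must be positive")
    if current_sum < 0:
        raise ValueError("current_sum must be non-negative")
    if new_lesions:
        return ResponseCategory.PD
    change = (current_sum - baseline_sum) / baseline_sum
    if current_sum == 0:
        return ResponseCategory.CR
    if change >= thresholds.pd_cut:
        return ResponseCategory.PD
    if change <= thresholds.pr_cut:
        return ResponseCategory.PR
    return ResponseCategory.SD


def classify_nonmeasurable(
    status: NonmeasurableStatus, new_lesions: bool = False
) -> ResponseCategory:
    """Classify non-measurable disease; PR is never returned."""
    if status is None:
        raise ValueError("nonmeasurable status required")
    if new_lesions or status is NonmeasurableStatus.UNEQUIVOCAL_PROGRESSION:
        return ResponseCategory.PD
    if status is NonmeasurableStatus.DISAPPEARED:
        return ResponseCategory.CR
    return ResponseCategory.NON_CR_NON_PD


@dataclass(frozen=True)
class BlastState:
    """Leukemia disease state at one assessment."""

    marrow_pct: float
    circulating_abs: float = 0.0
    extramedullary: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.marrow_pct <= 100:
            raise ValueError("marrow_pct must lie in [0, 100]")
        if self.circulating_abs < 0:
            raise ValueError("circulating_abs must be non-negative")


def classify_leukemia(
    current: BlastState,
    baseline: BlastState,
    prior_best: Optional[ResponseCategory] = None,
    best_marrow: Optional[float] = None,
) -> ResponseCategory:
    """Classify a leukemia assessment from blast counts.

    CR: marrow blasts < 5% with no circulating blasts and no extramedullary
    disease. PD: circulating blasts rise by more than 25 in absolute number
    from baseline, or marrow blasts rise more than 25 points after a prior PR,
    or more than 5 points after a prior CR (rise measured from ``best_marrow``,
    the lowest marrow blast percentage observed up to the prior best). PR:
    marrow 5-25% inclusive, or a >50% relative and >=10-point absolute
    reduction from baseline, in either case with no circulating blasts or
    extramedullary disease. Anything else is SD.
    """
    if baseline is None:
        raise ValueError("baseline blast record required")
    in_remission_shape = current.circulating_abs == 0 and not current.extramedullary
    if in_remission_shape and current.marrow_pct < 5:
        return ResponseCategory.CR
    if prior_best in (ResponseCategory.CR, ResponseCategory.PR):
        if best_marrow is None:
            raise ValueError("best_marrow required when prior_best is CR or PR")
        rise = current.marrow_pct - best_marrow
        if prior_best is ResponseCategory.CR and rise > 5:
            return ResponseCategory.PD
        if prior_best is ResponseCategory.PR and rise > 25:
            return ResponseCategory.PD
    if current.circulating_abs - baseline.circulating_abs > 25:
        return ResponseCategory.PD
    if in_remission_shape:
        if 5 <= current.marrow_pct <= 25:
            return ResponseCategory.PR
        rel_ok = (
            baseline.marrow_pct > 0
            and (baseline.marrow_pct - current.marrow_pct) / baseline.marrow_pct > 0.5
        )
        abs_ok = baseline.marrow_pct - current.marrow_pct >= 10
        if rel_ok and abs_ok:
            return ResponseCategory.PR
    return ResponseCategory.SD


def _blast_state(a: Assessment) -> BlastState:
    if a.marrow_blast_pct is None:
        raise ValueError(f"assessment for {a.course_id} day {a.day}: no blast data")
    return BlastState(
        marrow_pct=a.marrow_blast_pct,
        circulating_abs=a.circulating_blast_abs or 0.0,
        extramedullary=bool(a.extramedullary),
    )


@dataclass
class AdjudicatedCourse:
    """Classified assessments plus per-course summary quantities."""

    course_id: str
    categories: list[tuple[int, ResponseCategory]]  # (day, category), day order
    best_response: ResponseCategory
    first_pd_day: Optional[int]
    best_change_pct: Optional[float]  # best (most negative) target-sum change
    has_post_baseline: bool


def _severity(cat: ResponseCategory) -> int:
    return RESPONSE_ORDER.index(cat)


def adjudicate_course(
    course: TreatmentCourse,
    assessments: Sequence[Assessment],
    config: Optional[AnalysisConfig] = None,
) -> AdjudicatedCourse:
    """Classify every post-baseline assessment and derive the best response.

    The baseline is the assessment at the course start day. The best response
    is the most favorable countable category over the course with ordering
    CR > PR > SD/non-CR-non-PD > PD; SD (and non-CR-non-PD) only counts when
    achieved at least ``config.sd_min_day`` days (default 42, i.e. 6 weeks)
    after the treatment start. A course with no countable category is NE.
    """
    config = config or AnalysisConfig()
    ordered = sorted(assessments, key=lambda a: a.day)
    baseline = next((a for a in ordered if a.day == course.start_day), None)
    post = [a for a in ordered if a.day > course.start_day]

    categories: list[tuple[int, ResponseCategory]] = []
    best_change: Optional[float] = None
    first_pd: Optional[int] = None

    if course.baseline_state is BaselineState.NED:
        # No disease to classify; only progression (new lesions / unequivocal
        # progression) is registrable.
        for a in post:
            if a.new_lesions or (
                a.nonmeasurable_status is NonmeasurableStatus.UNEQUIVOCAL_PROGRESSION
            ):
                categories.append((a.day, ResponseCategory.PD))
                if first_pd is None:
                    first_pd = a.day
        return AdjudicatedCourse(
            course_id=course.course_id,
            categories=categories,
            best_response=ResponseCategory.NE,
            first_pd_day=first_pd,
            best_change_pct=None,
            has_post_baseline=bool(post),
        )

    if course.modality is Modality.LEUKEMIA:
        if baseline is None:
            raise ValueError(f"course {course.course_id}: no baseline blast assessment")
        base_state = _blast_state(baseline)
        prior_best: Optional[ResponseCategory] = None
        nadir = base_state.marrow_pct
        for a in post:
            cur = _blast_state(a)
            cat = classify_leukemia(cur, base_state, prior_best, nadir)
            categories.append((a.day, cat))
            nadir = min(nadir, cur.marrow_pct)
            if cat in (ResponseCategory.CR, ResponseCategory.PR) and (
                prior_best is None or _severity(cat) < _severity(prior_best)
            ):
                prior_best = cat
    elif course.baseline_state is BaselineState.MEASURABLE:
        if baseline is None or baseline.target_sum is None:
            raise ValueError(
                f"course {course.course_id}: measurable baseline requires a "
                f"target_sum at the start day"
            )
        thr = thresholds_for(course.modality, config.thresholds)
        for a in post:
            if a.target_sum is None:
                raise ValueError(
                    f"assessment for {course.course_id} day {a.day}: no target_sum"
                )
            cat = classify_target_change(
                baseline.target_sum, a.target_sum, thr, a.new_lesions
            )
            categories.append((a.day, cat))
            if not a.new_lesions:
                change = 100.0 * (a.target_sum - baseline.target_sum) / baseline.target_sum
                if best_change is None or change < best_change:
                    best_change = change
    else:  # non-measurable evaluable disease
        for a in post:
            if a.nonmeasurable_status is None:
                raise ValueError(
                    f"assessment for {course.course_id} day {a.day}: "
                    f"no nonmeasurable_status"
                )
            cat = classify_nonmeasurable(a.nonmeasurable_status, a.new_lesions)
            categories.append((a.day, cat))

    for day, cat in categories:
        if cat is ResponseCategory.PD and first_pd is None:
            first_pd = day

    countable = [
        cat
        for day, cat in categories
        if cat in (ResponseCategory.CR, ResponseCategory.PR, ResponseCategory.PD)
        or day - course.start_day >= config.sd_min_day
    ]
    best = min(countable, key=_severity) if countable else ResponseCategory.NE

    return AdjudicatedCourse(
        course_id=course.course_id,
        categories=categories,
        best_response=best,
        first_pd_day=first_pd,
        best_change_pct=best_change,
        has_post_baseline=bool(post),
    )


def adjudicate_cohort(cohort, config: Optional[AnalysisConfig] = None):
    """Adjudicate every course; returns ``{course_id: AdjudicatedCourse}``."""
    config = config or AnalysisConfig()
    by_course: dict[str, list[Assessment]] = {c.course_id: [] for c in cohort.courses}
    for a in cohort.assessments:
        by_course[a.course_id].append(a)
    return {
        c.course_id: adjudicate_course(c, by_course[c.course_id], config)
        for c in cohort.courses
    }
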