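"""Aggregate outcome tables and figure-backing data.

All rates follow the round-half-away-from-zero integer-percent convention.
Non-CR/non-PD counts as SD whenever measurable and non-measurable courses are
pooled ("evaluable" scope).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .adjudication import AdjudicatedCourse
from .endpoints import AnalysisSets
from .model import (
    BaselineState,
    Cohort,
    CourseCategory,
    EndpointRecord,
    OcbStatus,
    ResponseCategory,
    round_pct,
)
from .stats import exact_binomial_ci, km_fit, logrank, chisq_prop


def _by_id(records: Sequence[EndpointRecord]) -> dict[str, EndpointRecord]:
    return {r.course_id: r for r in records}


def _scope_courses(
    cohort: Cohort,
    records: Sequence[EndpointRecord],
    scope: str,
    category: Optional[CourseCategory] = CourseCategory.PGT,
):
    """Evaluable courses in a response scope: 'measurable' restricts to
    measurable-disease courses; 'evaluable' adds non-measurable ones (courses
    disease-free at start are never response-scorable)."""
    if scope not in ("measurable", "evaluable"):
        raise ValueError("scope must be 'measurable' or 'evaluable'")
    recs = _by_id(records)
    out = []
    for course in cohort.courses:
        r = recs.get(course.course_id)
        if r is None or not r.evaluable:
            continue
        if category is not None and course.category is not category:
            continue
        if course.baseline_state is BaselineState.NED:
            continue
        if scope == "measurable" and course.baseline_state is not BaselineState.MEASURABLE:
            continue
        out.append((course, r))
    return out


def response_summary(
    cohort: Cohort,
    records: Sequence[EndpointRecord],
    scope: str = "evaluable",
    category: Optional[CourseCategory] = CourseCategory.PGT,
) -> dict:
    """Best-response category counts and rates over a response scope.

    In 'evaluable' scope non-CR/non-PD is pooled as SD. Returns counts, whole
    percents and the objective-response rate (CR+PR)."""
    pairs = _scope_courses(cohort, records, scope, category)
    if not pairs:
        raise ValueError(f"no courses in scope {scope!r}")
    counts = {c: 0 for c in ("CR", "PR", "SD", "PD")}
    for course, rec in pairs:
        cat = rec.best_response
        if cat is ResponseCategory.NON_CR_NON_PD:
            cat = ResponseCategory.SD
        if cat is ResponseCategory.NE:
            continue
        counts[cat.value] += 1
    n = sum(counts.values())
    if n == 0:
        raise ValueError("no adjudicated responses in scope")
    rates = {k: round_pct(100.0 * v / n) for k, v in counts.items()}
    orr = 100.0 * (counts["CR"] + counts["PR"]) / n
    return {
        "n": n,
        "counts": counts,
        "rates_pct": rates,
        "orr_pct": round_pct(orr),
        "orr_raw": orr,
    }


def ocb_summary(
    records: Sequence[EndpointRecord],
    cohort: Optional[Cohort] = None,
    category: Optional[CourseCategory] = CourseCategory.PGT,
) -> dict:
    """Objective-clinical-benefit rate over assessable courses (NE excluded)."""
    subset = list(records)
    if cohort is not None and category is not None:
        subset = [
            r for r in subset if cohort.course(r.course_id).category is category
        ]
    assessable = [r for r in subset if r.evaluable and r.ocb is not OcbStatus.NE]
    if not assessable:
        raise ValueError("no assessable courses")
    k = sum(1 for r in assessable if r.ocb is OcbStatus.YES)
    n = len(assessable)
    return {"n": n, "k": k, "rate_pct": round_pct(100.0 * k / n)}


def uptake_summary(cohort: Cohort) -> dict:
    """Treated-with-recommended-therapy rate among recommended patients."""
    recommended = {r.patient_id for r in cohort.recommendations}
    if not recommended:
        raise ValueError("no recommended patients")
    treated = {
        c.patient_id
        for c in cohort.courses
        if c.category is CourseCategory.PGT and c.patient_id in recommended
    }
    n, k = len(recommended), len(treated)
    return {"n": n, "k": k, "rate_pct": round_pct(100.0 * k / n)}


def pfs_ratio_summary(
    records: Sequence[EndpointRecord], level: float = 0.95
) -> dict:
    """Benefit rate among ratio-assessable courses with an exact CI."""
    assessable = [r for r in records if r.pfs_ratio is not None]
    if not assessable:
        raise ValueError("no ratio-assessable courses")
    k = sum(1 for r in assessable if r.pfs_ratio_benefit)
    n = len(assessable)
    lo, hi = exact_binomial_ci(k, n, level)
    return {
        "n": n,
        "k": k,
        "rate_pct": round_pct(100.0 * k / n),
        "ci_lower_pct": round_pct(100.0 * lo),
        "ci_upper_pct": round_pct(100.0 * hi),
        "ci_raw": (lo, hi),
    }


# ---------------------------------------------------------------------------
# stratified outcome table
# ---------------------------------------------------------------------------


@dataclass
class StratumSpec:
    """A named stratification: maps a course to a stratum label (or None to
    drop it)."""

    name: str
    assign: callable
    reference: Optional[str] = None  # label of the comparison reference


def _course_stratum_factories(cohort: Cohort):
    def by_tier(course, rec, patient):
        if rec is None:
            return None
        return {"T1": "tier1", "T2": "tier2"}.get(rec.tier.value, "tier3-5")

    def by_aberration(course, rec, patient):
        return rec.aberration_class.value if rec else None

    def by_disease_status(course, rec, patient):
        return "no_pd" if course.n_progressions_before_start == 0 else "pd"

    def by_group(course, rec, patient):
        return patient.diagnosis_group.value

    return {
        "tier": StratumSpec("tier", by_tier, reference="tier1"),
        "aberration": StratumSpec("aberration", by_aberration, reference="FUSION_SV"),
        "disease_status": StratumSpec("disease_status", by_disease_status,
                                      reference="no_pd"),
        "cancer_type": StratumSpec("cancer_type", by_group, reference="CNS"),
    }


def stratified_outcomes(
    cohort: Cohort,
    records: Sequence[EndpointRecord],
    sets: AnalysisSets,
    strata: str | StratumSpec,
    category: Optional[CourseCategory] = CourseCategory.PGT,
    horizon_days: int = 730,
) -> pd.DataFrame:
    """Per-stratum outcome table: n, survival at the horizon with Greenwood
    log(-log) CI, response and OCB rates, and a comparison p-value against the
    reference stratum (log-rank for survival, chi-squared for proportions)."""
    if isinstance(strata, str):
        factories = _course_stratum_factories(cohort)
        if strata == "favorable_factors":
            spec = StratumSpec(
                "favorable_factors",
                lambda course, rec, patient: None,
                reference="0",
            )
        elif strata in factories:
            spec = factories[strata]
        else:
            raise KeyError(f"unknown stratification {strata!r}")
    else:
        spec = strata

    recs_by_id = _by_id(records)
    rows: dict[str, dict] = {}
    for course in cohort.courses:
        r = recs_by_id.get(course.course_id)
        if r is None or not r.evaluable:
            continue
        if category is not None and course.category is not category:
            continue
        patient = cohort.patient(course.patient_id)
        rec = (
            cohort.recommendation(course.recommendation_id)
            if course.recommendation_id
            else None
        )
        if spec.name == "favorable_factors":
            label = None if r.favorable_factors is None else str(r.favorable_factors)
        else:
            label = spec.assign(course, rec, patient)
        if label is None:
            continue
        row = rows.setdefault(
            label,
            {"durations": [], "events": [], "resp": [], "ocb": []},
        )
        row["durations"].append(r.pfs_days)
        row["events"].append(bool(r.pfs_event))
        best = r.best_response
        if course.baseline_state is not BaselineState.NED and best is not ResponseCategory.NE:
            responded = best in (ResponseCategory.CR, ResponseCategory.PR)
            row["resp"].append(responded)
        if r.ocb is not OcbStatus.NE:
            row["ocb"].append(r.ocb is OcbStatus.YES)

    if not rows:
        raise ValueError("no strata with members")
    reference = spec.reference
    if reference is not None and reference not in rows:
        raise ValueError(f"reference stratum {reference!r} missing")

    out = []
    for label, row in sorted(rows.items()):
        curve = km_fit(row["durations"], row["events"])
        s, lo, hi = curve.survival_at_ci(horizon_days)
        entry = {
            "stratum": label,
            "n": len(row["durations"]),
            "pfs_at_horizon_pct": round_pct(100 * s),
            "pfs_ci_lower_pct": round_pct(100 * lo),
            "pfs_ci_upper_pct": round_pct(100 * hi),
            "response_pct": (
                round_pct(100 * np.mean(row["resp"])) if row["resp"] else None
            ),
            "ocb_pct": round_pct(100 * np.mean(row["ocb"])) if row["ocb"] else None,
            "pfs_logrank_p": None,
            "response_chisq_p": None,
            "ocb_chisq_p": None,
        }
        if reference is not None and label != reference:
            ref = rows[reference]
            entry["pfs_logrank_p"] = logrank(
                (row["durations"], row["events"]),
                (ref["durations"], ref["events"]),
            ).p_value
            for key, pcol in (("resp", "response_chisq_p"), ("ocb", "ocb_chisq_p")):
                a, b = row[key], ref[key]
                if a and b:
                    table = [
                        [sum(a), len(a) - sum(a)],
                        [sum(b), len(b) - sum(b)],
                    ]
                    try:
                        entry[pcol] = chisq_prop(table).p_value
                    except ValueError:
                        entry[pcol] = None
        out.append(entry)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# figure-backing exports
# ---------------------------------------------------------------------------


def export_figure_data(
    cohort: Cohort,
    adjudicated: dict[str, AdjudicatedCourse],
    records: Sequence[EndpointRecord],
    category: Optional[CourseCategory] = CourseCategory.PGT,
) -> dict[str, pd.DataFrame]:
    """Waterfall (best percent change, measurable courses), swimmer (course
    durations with response markers) and survival-curve data frames.

    Ordering is deterministic: waterfall descending by change then course id;
    swimmer by course id."""
    recs_by_id = _by_id(records)
    waterfall = []
    swimmer = []
    durations, events = [], []
    for course in cohort.courses:
        if category is not None and course.category is not category:
            continue
        r = recs_by_id.get(course.course_id)
        adj = adjudicated.get(course.course_id)
        if r is None or adj is None or not r.evaluable:
            continue
        if (
            course.baseline_state is BaselineState.MEASURABLE
            and adj.best_change_pct is not None
        ):
            waterfall.append(
                {
                    "course_id": course.course_id,
                    "best_change_pct": adj.best_change_pct,
                    "best_response": r.best_response.value,
                }
            )
        swimmer.append(
            {
                "course_id": course.course_id,
                "duration_days": course.duration,
                "best_response": r.best_response.value,
                "ocb": r.ocb.value,
                "pfs_days": r.pfs_days,
                "pfs_event": r.pfs_event,
            }
        )
        durations.append(r.pfs_days)
        events.append(bool(r.pfs_event))

    waterfall.sort(key=lambda d: (-d["best_change_pct"], d["course_id"]))
    swimmer.sort(key=lambda d: d["course_id"])

    wf_cols = ["course_id", "best_change_pct", "best_response"]
    sw_cols = [
        "course_id", "duration_days", "best_response", "ocb", "pfs_days", "pfs_event",
    ]
    km_cols = ["time", "at_risk", "events", "survival"]
    wf = pd.DataFrame(waterfall, columns=wf_cols)
    sw = pd.DataFrame(swimmer, columns=sw_cols)
    if durations and any(events):
        curve = km_fit(durations, events)
        km = pd.DataFrame(
            {
                "time": curve.event_times,
                "at_risk": curve.n_at_risk,
                "events": curve.n_events,
                "survival": curve.survival,
            }
        )
    else:
        km = pd.DataFrame(columns=km_cols)
    return {"waterfall": wf, "swimmer": sw, "km_curves": km}


def endpoints_frame(records: Sequence[EndpointRecord]) -> pd.DataFrame:
    """Tidy endpoints table (one row per course)."""
    rows = []
    for r in records:
        rows.append(
            {
                "course_id": r.course_id,
                "evaluable": r.evaluable,
                "exclusion_reason": r.exclusion_reason,
                "best_response": r.best_response.value,
                "objective_response": r.objective_response,
                "ocb": r.ocb.value,
                "pfs_days": r.pfs_days,
                "pfs_event": r.pfs_event,
                "pfs_ratio": r.pfs_ratio,
                "pfs_ratio_benefit": r.pfs_ratio_benefit,
                "pfs_ratio_reason": r.pfs_ratio_reason,
                "favorable_factors": r.favorable_factors,
            }
        )
    return pd.DataFrame(rows)
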