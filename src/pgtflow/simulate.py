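"""Synthetic cohort generator.

Emulates the statistical structure of the study tables: one row per patient,
per molecular-board recommendation, per treatment course and per serial
disease assessment. Event times are drawn from exponential (or Weibull)
hazards with a configurable log-hazard-ratio structure over four course-level
covariates (tier-1 evidence, fusion/SV target, no progression before start,
non-hematologic disease); response categories are drawn from configurable
probabilities and lesion-sum / blast trajectories are then constructed so
that the adjudication pipeline reproduces the drawn category exactly.

Reproducibility: each patient uses an independent generator seeded by
``(seed, patient_index)``, so enlarging the cohort never perturbs already
generated rows.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

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
    ResponseCategory,
    TherapyType,
    Tier,
    TreatmentCourse,
)

LN = math.log

#: Default log hazard ratios (protective direction) for the four course-level
#: covariates, in covariate order (tier1, fusion_sv, no_pd, non_hm).
DEFAULT_LOG_HRS = {
    "tier1": LN(0.43),
    "fusion_sv": LN(0.42),
    "no_pd": LN(0.50),
    "non_hm": LN(0.21),
}

COVARIATE_NAMES = ["tier1", "fusion_sv", "no_pd", "non_hm"]


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort. Defaults follow the published
    cohort composition (385 tumors: 146 CNS / 183 solid / 56 hematologic;
    recommendation rates 73% CNS vs 62% solid; 43% treatment uptake)."""

    seed: int
    n_patients: int = 385
    diagnosis_probs: dict = field(
        default_factory=lambda: {
            "CNS": 146 / 385,
            "SOLID": 183 / 385,
            "HM": 56 / 385,
        }
    )
    enrollment_probs: dict = field(
        default_factory=lambda: {
            "DIAGNOSIS": 160 / 384,
            "FIRST_RELAPSE": 184 / 384,
            "GE2_RELAPSE": 40 / 384,
        }
    )
    recommendation_probs: dict = field(
        default_factory=lambda: {"CNS": 0.73, "SOLID": 0.62, "HM": 0.64}
    )
    tier_probs: dict = field(
        default_factory=lambda: {
            "T1": 0.20,
            "T2": 0.33,
            "T3": 0.25,
            "T4": 0.18,
            "T5": 0.04,
        }
    )
    aberration_probs: dict = field(
        default_factory=lambda: {
            "FUSION_SV": 0.17,
            "SNV": 0.42,
            "HIGH_RNA_ONLY": 0.26,
            "CNV": 0.15,
        }
    )
    therapy_probs: dict = field(
        default_factory=lambda: {
            "TARGETED_MONO": 0.74,
            "TARGETED_DUAL": 0.12,
            "TARGETED_PLUS_CHEMO": 0.13,
            "CHEMO": 0.01,
        }
    )
    uptake_prob: float = 0.43
    response_probs: dict = field(
        default_factory=lambda: {"CR": 0.09, "PR": 0.21, "SD": 0.38, "PD": 0.32}
    )
    nonmeasurable_prob: float = 0.20
    ned_prob: float = 0.09
    no_pd_before_start_prob: float = 0.50
    prior_course_prob: float = 0.6  # chance a relapsed patient has a prior course
    log_hrs: dict = field(default_factory=lambda: dict(DEFAULT_LOG_HRS))
    baseline_hazard: float = 1 / 180.0  # events/day for the reference stratum
    weibull_shape: Optional[float] = None  # None = exponential
    censor_rate: float = 1 / 1500.0  # random censoring hazard per day
    death_after_pd_rate: float = 1 / 240.0
    cutoff_day: int = 1650

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        for name in (
            "diagnosis_probs",
            "enrollment_probs",
            "tier_probs",
            "aberration_probs",
            "therapy_probs",
            "response_probs",
        ):
            probs = getattr(self, name)
            vals = np.array(list(probs.values()), dtype=float)
            if np.any(vals < 0) or np.any(vals > 1):
                raise ValueError(f"{name}: probabilities must lie in [0, 1]")
            if not math.isclose(vals.sum(), 1.0, abs_tol=1e-9):
                raise ValueError(f"{name}: probabilities must sum to 1")
        for name in ("uptake_prob", "nonmeasurable_prob", "ned_prob",
                     "no_pd_before_start_prob", "prior_course_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        for p in self.recommendation_probs.values():
            if not 0 <= p <= 1:
                raise ValueError("recommendation_probs must lie in [0, 1]")
        if self.baseline_hazard <= 0 or self.censor_rate < 0:
            raise ValueError("hazard rates must be positive")
        if self.weibull_shape is not None and self.weibull_shape <= 0:
            raise ValueError("weibull_shape must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        unknown = set(d) - set(known)
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        cfg = cls(**known)
        cfg.validate()
        return cfg


@dataclass
class SimulatedCohort:
    cohort: Cohort
    truth: pd.DataFrame  # course_id, drawn category, pfs_days, event, covariates
    config: SimConfig


def _choice(rng: np.random.Generator, probs: dict):
    keys = list(probs)
    p = np.array([probs[k] for k in keys], dtype=float)
    return keys[int(rng.choice(len(keys), p=p / p.sum()))]


def _event_days(rng: np.random.Generator, rate: float, shape: Optional[float]) -> int:
    """Days to event, minimum 1. Weibull uses ``rate`` as 1/scale."""
    if shape is None:
        raw = rng.exponential(1.0 / rate)
    else:
        raw = (1.0 / rate) * rng.weibull(shape)
    return max(1, int(math.ceil(raw)))


# trajectory templates: fractional change of the target sum realizing each
# category under both the -30% (solid/PET) and -50% (CNS) PR cuts
_MEASURABLE_SUM = {"CR": 0.0, "PR": 0.40, "SD": 0.90, "PD": 1.60}
_BASELINE_SUM = 50.0


def _response_assessments(
    rng: np.random.Generator,
    course_id: str,
    start: int,
    modality: Modality,
    baseline_state: BaselineState,
    category: ResponseCategory,
    obs_end: int,
    event: bool,
    event_days: int,
) -> list[Assessment]:
    """Construct a trajectory whose adjudicated best response is exactly
    ``category``. Interim response assessments land on day start+56 (CR/PR)
    or start+49 (SD, past the 6-week minimum); a progression event appears at
    ``start + event_days``."""
    out: list[Assessment] = []

    def add(day, **kw):
        out.append(Assessment(course_id=course_id, day=day, **kw))

    if modality is Modality.LEUKEMIA:
        add(start, marrow_blast_pct=80.0, circulating_blast_abs=0.0,
            extramedullary=False)

        def blast(day, marrow, circ=0.0):
            add(day, marrow_blast_pct=marrow, circulating_blast_abs=circ,
                extramedullary=False)

        if category is ResponseCategory.CR:
            blast(start + 56, 3.0)
        elif category is ResponseCategory.PR:
            blast(start + 56, 15.0)
        elif category is ResponseCategory.SD:
            blast(start + 49, 70.0)
        if event:
            # progression via a >25 absolute rise in circulating blasts, which
            # is PD regardless of any earlier CR/PR
            blast(start + event_days, 90.0, circ=30.0)
        return out

    if baseline_state is BaselineState.NED:
        add(start, new_lesions=False)
        if event:
            add(start + event_days, new_lesions=True)
        elif obs_end > 30:
            add(start + 30, new_lesions=False)
        return out

    if baseline_state is BaselineState.NONMEASURABLE_EVALUABLE:
        add(start, nonmeasurable_status=NonmeasurableStatus.PERSISTS)
        if category is ResponseCategory.CR:
            add(start + 56, nonmeasurable_status=NonmeasurableStatus.DISAPPEARED)
        elif category is ResponseCategory.NON_CR_NON_PD:
            add(start + 49, nonmeasurable_status=NonmeasurableStatus.PERSISTS)
        if event:
            add(
                start + event_days,
                nonmeasurable_status=NonmeasurableStatus.UNEQUIVOCAL_PROGRESSION,
            )
        return out

    # measurable imaging disease
    add(start, target_sum=_BASELINE_SUM)
    if category in (ResponseCategory.CR, ResponseCategory.PR):
        frac = _MEASURABLE_SUM[category.value]
        add(start + 56, target_sum=round(_BASELINE_SUM * frac, 1))
    elif category is ResponseCategory.SD:
        add(start + 49, target_sum=round(_BASELINE_SUM * _MEASURABLE_SUM["SD"], 1))
    if event:
        add(start + event_days, target_sum=round(_BASELINE_SUM * 1.6, 1))
    return out


def _realizable(
    probs: dict,
    baseline_state: BaselineState,
    event: bool,
    event_days: int,
    obs_end: int,
) -> dict:
    """Restrict the drawn-category distribution to categories the course
    timeline can realize, renormalizing the probabilities."""
    allowed: dict[str, float] = {}
    can_resp = (event and event_days > 56) or (not event and obs_end >= 56)
    can_sd = (event and event_days > 49) or (not event and obs_end >= 49)
    if baseline_state is BaselineState.NONMEASURABLE_EVALUABLE:
        base = {
            "CR": probs["CR"],
            "NON_CR_NON_PD": probs["SD"] + probs["PR"],
            "PD": probs["PD"],
        }
    else:
        base = dict(probs)
    for cat, p in base.items():
        if cat == "PD":
            if event:
                allowed[cat] = p
        elif cat in ("SD", "NON_CR_NON_PD"):
            if can_sd:
                allowed[cat] = p
        else:
            if can_resp:
                allowed[cat] = p
    if not allowed:
        allowed = {"PD": 1.0} if event else {"NE": 1.0}
    total = sum(allowed.values())
    return {k: v / total for k, v in allowed.items()}


def simulate(config: SimConfig) -> SimulatedCohort:
    """Generate a referentially consistent four-table cohort plus a truth
    table (drawn response category and survival time per course)."""
    config.validate()
    patients: list[Patient] = []
    recommendations: list[Recommendation] = []
    courses = []
    assessments: list[Assessment] = []
    truth_rows: list[dict] = []

    beta = np.array([config.log_hrs.get(k, 0.0) for k in COVARIATE_NAMES])

    for i in range(config.n_patients):
        rng = np.random.default_rng([config.seed, i])
        pid = f"P{i + 1:05d}"
        group = DiagnosisGroup(_choice(rng, config.diagnosis_probs))
        status = EnrollmentStatus(_choice(rng, config.enrollment_probs))
        enrollment = 0
        mtb = enrollment + int(rng.integers(20, 70))

        has_rec = rng.random() < config.recommendation_probs[group.value]
        rec: Optional[Recommendation] = None
        if has_rec:
            rec = Recommendation(
                recommendation_id=f"R{i + 1:05d}",
                patient_id=pid,
                tier=Tier(_choice(rng, config.tier_probs)),
                target_gene=f"GENE{int(rng.integers(1, 200)):03d}",
                aberration_class=AberrationClass(_choice(rng, config.aberration_probs)),
                therapy_type=TherapyType(_choice(rng, config.therapy_probs)),
            )
            recommendations.append(rec)

        treated = has_rec and rng.random() < config.uptake_prob
        progression_days: list[int] = []
        death_day: Optional[int] = None
        last_day = config.cutoff_day

        # optional prior (pre-MTB) treatment ending in progression, providing
        # a PFS-ratio comparator for relapsed patients
        prior_stop = None
        if (
            status is not EnrollmentStatus.DIAGNOSIS
            and rng.random() < config.prior_course_prob
        ):
            p_start = enrollment + 1
            p_pfs = 28 + int(rng.integers(14, 200))
            p_stop = p_start + p_pfs
            if p_stop < mtb + 200:
                cid = f"C{i + 1:05d}X"
                courses.append(
                    TreatmentCourse(
                        course_id=cid,
                        patient_id=pid,
                        category=CourseCategory.SOC,
                        recommendation_id=None,
                        start_day=p_start,
                        stop_day=p_stop,
                        baseline_state=BaselineState.MEASURABLE,
                        n_progressions_before_start=1,
                        modality=Modality.RECIST,
                        pre_mtb=True,
                    )
                )
                assessments.append(
                    Assessment(course_id=cid, day=p_start, target_sum=_BASELINE_SUM)
                )
                assessments.append(
                    Assessment(
                        course_id=cid,
                        day=p_stop,
                        target_sum=round(_BASELINE_SUM * 1.6, 1),
                    )
                )
                progression_days.append(p_stop)
                prior_stop = p_stop

        # every patient receives one post-MTB course: PGT if treated,
        # otherwise SOC/UGT/OTHER
        if treated:
            category = CourseCategory.PGT
        else:
            category = CourseCategory(
                _choice(rng, {"SOC": 0.55, "UGT": 0.35, "OTHER": 0.10})
            )
        earliest = max(mtb, (prior_stop or 0)) + 1
        start = earliest + int(rng.integers(3, 60))
        no_pd_flag = rng.random() < config.no_pd_before_start_prob
        n_prog = len([d for d in progression_days if d < start])
        if not no_pd_flag and n_prog == 0:
            progression_days.append(start - 1)
            progression_days.sort()
            n_prog = 1

        if group is DiagnosisGroup.HM:
            modality = Modality.LEUKEMIA
            baseline_state = BaselineState.MEASURABLE
        else:
            u = rng.random()
            if u < config.ned_prob:
                baseline_state = BaselineState.NED
            elif u < config.ned_prob + config.nonmeasurable_prob:
                baseline_state = BaselineState.NONMEASURABLE_EVALUABLE
            else:
                baseline_state = BaselineState.MEASURABLE
            if group is DiagnosisGroup.CNS:
                modality = Modality.RANO
            else:
                modality = (
                    Modality.PERCIST if rng.random() < 0.2 else Modality.RECIST
                )

        x = np.array(
            [
                1.0 if (rec is not None and rec.tier is Tier.T1 and treated) else 0.0,
                1.0
                if (
                    rec is not None
                    and rec.aberration_class is AberrationClass.FUSION_SV
                    and treated
                )
                else 0.0,
                1.0 if n_prog == 0 else 0.0,
                1.0 if group is not DiagnosisGroup.HM else 0.0,
            ]
        )
        rate = config.baseline_hazard * math.exp(float(beta @ x))
        # all simulated courses clear the 4-week evaluability bar: the
        # exponential clock starts at day 28 (memoryless, so proportional
        # hazards are preserved)
        t_days = 28 + _event_days(rng, rate, config.weibull_shape)
        c_days = 28 + _event_days(rng, config.censor_rate, None)
        admin = config.cutoff_day - start
        obs_end = min(c_days, admin)
        event = t_days <= obs_end
        end_days = t_days if event else obs_end

        if baseline_state is BaselineState.NED:
            # no disease to classify at start; adjudication yields NE
            drawn = ResponseCategory.NE
        else:
            cat_probs = _realizable(
                config.response_probs, baseline_state, event, t_days, obs_end
            )
            drawn = ResponseCategory(_choice(rng, cat_probs))

        cid = f"C{i + 1:05d}A"
        stop = start + end_days
        course = TreatmentCourse(
            course_id=cid,
            patient_id=pid,
            category=category,
            recommendation_id=rec.recommendation_id if treated else None,
            start_day=start,
            stop_day=stop,
            baseline_state=baseline_state,
            n_progressions_before_start=n_prog,
            modality=modality,
            pre_mtb=False,
        )
        courses.append(course)
        assessments.extend(
            _response_assessments(
                rng, cid, start, modality, baseline_state, drawn,
                obs_end, event, t_days,
            )
        )
        if event:
            progression_days.append(start + t_days)
            # post-progression survival
            extra = _event_days(rng, config.death_after_pd_rate, None)
            death = start + t_days + extra
            if death <= config.cutoff_day:
                death_day = death
                last_day = death
            else:
                last_day = config.cutoff_day
        else:
            last_day = config.cutoff_day

        truth_rows.append(
            {
                "course_id": cid,
                "patient_id": pid,
                "category": category.value,
                "drawn_response": drawn.value,
                "pfs_days": end_days,
                "event": event,
                "tier1": x[0],
                "fusion_sv": x[1],
                "no_pd": x[2],
                "non_hm": x[3],
            }
        )

        progression_days = sorted(set(progression_days))
        if death_day is not None:
            progression_days = [d for d in progression_days if d <= death_day]
        patients.append(
            Patient(
                patient_id=pid,
                diagnosis_group=group,
                enrollment_day=enrollment,
                enrollment_status=status,
                mtb_day=mtb,
                death_day=death_day,
                last_followup_day=last_day,
                progression_days=progression_days,
            )
        )

    cohort = Cohort(patients, recommendations, courses, assessments)
    cohort.validate()
    truth = pd.DataFrame(truth_rows)
    return SimulatedCohort(cohort=cohort, truth=truth, config=config)


def provenance(config: SimConfig) -> dict:
    from . import __version__

    return {
        "generator": "pgtflow.simulate",
        "version": __version__,
        "config": asdict(config),
    }


def write_provenance(config: SimConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(provenance(config), fh, indent=2, sort_keys=True)
        fh.write("\n")
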