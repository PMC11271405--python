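import pytest
from hypothesis import given, strategies as st

from pgtflow.adjudication import AdjudicatedCourse
from pgtflow.endpoints import (
    AnalysisSets,
    PfsResult,
    assign_os_groups,
    compute_ocb,
    compute_pfs,
    derive_endpoints,
    favorable_factors,
    is_evaluable,
    pfs_ratio,
)
from pgtflow.model import (
    AberrationClass,
    AnalysisConfig,
    BaselineState,
    Cohort,
    CourseCategory,
    DiagnosisGroup,
    EnrollmentStatus,
    Modality,
    OcbStatus,
    Patient,
    Recommendation,
    ResponseCategory,
    TherapyType,
    Tier,
    TreatmentCourse,
)


def _course(**kw):
    base = dict(
        course_id="C1",
        patient_id="P1",
        category=CourseCategory.PGT,
        recommendation_id="R1",
        start_day=100,
        stop_day=300,
        baseline_state=BaselineState.MEASURABLE,
        n_progressions_before_start=0,
        modality=Modality.RECIST,
    )
    base.update(kw)
    return TreatmentCourse(**base)


def _adj(course_id="C1", best="SD", first_pd=None, has_post=True):
    return AdjudicatedCourse(
        course_id=course_id,
        categories=[],
        best_response=ResponseCategory(best),
        first_pd_day=first_pd,
        best_change_pct=None,
        has_post_baseline=has_post,
    )


def _patient(**kw):
    base = dict(
        patient_id="P1",
        diagnosis_group=DiagnosisGroup.SOLID,
        enrollment_day=0,
        enrollment_status=EnrollmentStatus.FIRST_RELAPSE,
        mtb_day=50,
        death_day=None,
        last_followup_day=900,
        progression_days=[],
    )
    base.update(kw)
    return Patient(**base)


class TestEvaluability:
    def test_short_duration(self):
        ok, reason = is_evaluable(_course(stop_day=121), _adj())
        assert not ok and reason == "duration<4wk"

    def test_early_pd(self):
        ok, reason = is_evaluable(_course(), _adj(best="PD", first_pd=120))
        assert not ok and reason == "early PD"

    def test_pd_at_day_28_allowed(self):
        ok, _ = is_evaluable(_course(), _adj(best="PD", first_pd=128))
        assert ok

    def test_no_evaluation(self):
        ok, reason = is_evaluable(_course(), _adj(has_post=False))
        assert not ok and reason == "no evaluation"

    def test_all_criteria_met(self):
        ok, reason = is_evaluable(_course(stop_day=160), _adj(best="SD"))
        assert ok and reason is None


class TestComputePfs:
    def test_pd_before_death(self):
        pfs = compute_pfs(
            _course(), _adj(first_pd=250), _patient(death_day=400, last_followup_day=400), 800
        )
        assert (pfs.days, pfs.event, pfs.event_is_pd) == (150, True, True)

    def test_censored_at_cutoff(self):
        pfs = compute_pfs(_course(), _adj(), _patient(last_followup_day=900), 800)
        assert (pfs.days, pfs.event) == (700, False)

    def test_death_without_pd(self):
        pfs = compute_pfs(
            _course(), _adj(), _patient(death_day=300, last_followup_day=300), 800
        )
        assert (pfs.days, pfs.event, pfs.event_is_pd) == (200, True, False)

    def test_censored_at_followup_before_cutoff(self):
        pfs = compute_pfs(_course(), _adj(), _patient(last_followup_day=600), 800)
        assert (pfs.days, pfs.event) == (500, False)

    def test_pd_before_start_errors(self):
        with pytest.raises(ValueError, match="precedes"):
            compute_pfs(_course(), _adj(first_pd=50), _patient(), 800)


class TestComputeOcb:
    def test_pr_sustained_past_168(self):
        # PR at day 60, progression at day 200 after start -> sustained 200d
        course = _course(stop_day=360)
        assert compute_ocb(course, _adj(best="PR", first_pd=300)) is OcbStatus.YES

    def test_pr_lost_early(self):
        course = _course(stop_day=200)
        assert compute_ocb(course, _adj(best="PR", first_pd=200)) is OcbStatus.NO

    def test_sd_stopped_early_is_ne(self):
        course = _course(stop_day=200)  # 100 days on treatment, still SD
        assert compute_ocb(course, _adj(best="SD")) is OcbStatus.NE

    def test_sd_held_24_weeks(self):
        course = _course(stop_day=300)
        assert compute_ocb(course, _adj(best="SD", first_pd=290)) is OcbStatus.YES

    def test_nonmeasurable_ncnpd_held(self):
        course = _course(
            baseline_state=BaselineState.NONMEASURABLE_EVALUABLE, stop_day=300
        )
        assert compute_ocb(course, _adj(best="NON_CR_NON_PD")) is OcbStatus.YES

    def test_nonmeasurable_sd_category_not_counted(self):
        # SD is not a non-measurable category; only CR/non-CR-non-PD control
        course = _course(
            baseline_state=BaselineState.NONMEASURABLE_EVALUABLE, stop_day=300
        )
        assert compute_ocb(course, _adj(best="PD")) is OcbStatus.NO

    def test_ned_relapse_before_24_weeks(self):
        course = _course(baseline_state=BaselineState.NED, stop_day=300)
        assert compute_ocb(course, _adj(best="NE", first_pd=190)) is OcbStatus.NO

    def test_ned_disease_free_24_weeks(self):
        course = _course(baseline_state=BaselineState.NED, stop_day=300)
        assert compute_ocb(course, _adj(best="NE")) is OcbStatus.YES

    def test_pd_is_no(self):
        assert compute_ocb(_course(), _adj(best="PD", first_pd=160)) is OcbStatus.NO


class TestPfsRatio:
    def _run(self, pfs1, pfs2, event2=True, prior_relapsed=True, **kw):
        pgt = _course()
        prior = _course(
            course_id="C0",
            category=CourseCategory.SOC,
            recommendation_id=None,
            start_day=0,
            stop_day=pfs1,
            pre_mtb=True,
            n_progressions_before_start=1 if prior_relapsed else 0,
        )
        patient = _patient(
            enrollment_status=EnrollmentStatus.FIRST_RELAPSE
            if prior_relapsed
            else EnrollmentStatus.DIAGNOSIS
        )
        return pfs_ratio(
            pgt,
            PfsResult(days=pfs2, event=event2, event_is_pd=event2),
            _adj(first_pd=100 + pfs2 if event2 else None),
            prior,
            PfsResult(days=pfs1, event=True, event_is_pd=True),
            patient,
            **kw,
        )

    def test_clear_benefit(self):
        res = self._run(100, 200)
        assert res.eligible and res.ratio == 2.0 and res.benefit

    def test_ratio_below_cut(self):
        res = self._run(100, 125)
        assert res.eligible and res.ratio == 1.25 and not res.benefit

    def test_gain_below_4_weeks(self):
        # ratio 1.54 > 1.3 but absolute gain 21 days < 28
        res = self._run(39, 60)
        assert res.eligible and not res.benefit

    def test_censored_shorter_than_comparator_ineligible(self):
        res = self._run(300, 150, event2=False)
        assert not res.eligible and "censored" in res.reason

    def test_censored_longer_eligible_conservative(self):
        res = self._run(100, 400, event2=False)
        assert res.eligible and res.ratio == 4.0 and res.benefit

    def test_no_comparator(self):
        pgt = _course()
        res = pfs_ratio(
            pgt, PfsResult(200, True, True), _adj(), None, None, _patient()
        )
        assert not res.eligible and res.reason == "no comparator"

    def test_prior_not_relapsed_ineligible(self):
        res = self._run(100, 200, prior_relapsed=False)
        assert not res.eligible and "relapsed" in res.reason

    def test_short_durations_ineligible(self):
        res = self._run(20, 200)
        assert not res.eligible and res.reason == "duration<4wk"

    @given(scale=st.floats(1.0, 5.0))
    def test_benefit_invariant_under_rescaling(self, scale):
        # rescaling both durations by a common factor > 1 keeps the ratio and
        # can only grow the absolute gain, so benefit is preserved
        base = self._run(100, 200)
        scaled = self._run(int(100 * scale), int(200 * scale))
        assert base.eligible and scaled.eligible
        assert scaled.benefit == base.benefit


class TestOsGroups:
    def _cohort(self, courses):
        patient = _patient()
        recs = [
            Recommendation(
                recommendation_id="R1",
                patient_id="P1",
                tier=Tier.T1,
                target_gene="G",
                aberration_class=AberrationClass.SNV,
                therapy_type=TherapyType.TARGETED_MONO,
            )
        ]
        return Cohort([patient], recs, courses, [])

    def test_first_post_mtb_soc_wins(self):
        cohort = self._cohort(
            [
                _course(course_id="C1", category=CourseCategory.SOC,
                        recommendation_id=None, start_day=60, stop_day=100),
                _course(course_id="C2", start_day=150, stop_day=400),
            ]
        )
        groups, excluded = assign_os_groups(cohort)
        assert groups["P1"].group is CourseCategory.SOC
        assert groups["P1"].origin_day == 60
        assert excluded == []

    def test_no_post_mtb_course_excluded(self):
        cohort = self._cohort(
            [
                _course(course_id="C1", category=CourseCategory.SOC,
                        recommendation_id=None, start_day=5, stop_day=40,
                        pre_mtb=True),
            ]
        )
        groups, excluded = assign_os_groups(cohort)
        assert groups == {} and excluded == ["P1"]

    def test_multi_pgt_origin_is_first_pgt(self):
        cohort = self._cohort(
            [
                _course(course_id="C1", start_day=100, stop_day=200),
                _course(course_id="C2", start_day=300, stop_day=400),
            ]
        )
        groups, _ = assign_os_groups(cohort)
        assert groups["P1"].group is CourseCategory.PGT
        assert groups["P1"].origin_day == 100

    def test_partition(self, printed_cohort):
        groups, excluded = assign_os_groups(printed_cohort)
        assert set(groups) & set(excluded) == set()
        assert len(groups) + len(excluded) == len(printed_cohort.patients)


class TestFavorableFactors:
    def _rec(self, tier=Tier.T1, ab=AberrationClass.FUSION_SV):
        return Recommendation(
            recommendation_id="R1",
            patient_id="P1",
            tier=tier,
            target_gene="G",
            aberration_class=ab,
            therapy_type=TherapyType.TARGETED_MONO,
        )

    def test_all_three(self):
        assert favorable_factors(_course(), self._rec(), _patient()) == 3

    def test_none_present(self):
        course = _course(n_progressions_before_start=1)
        rec = self._rec(tier=Tier.T3, ab=AberrationClass.SNV)
        assert favorable_factors(course, rec, _patient()) == 0

    def test_hm_patient_is_na(self):
        patient = _patient(diagnosis_group=DiagnosisGroup.HM)
        assert favorable_factors(_course(), self._rec(), patient) is None

    def test_non_index_course_is_na(self):
        course = _course(category=CourseCategory.SOC, recommendation_id=None)
        assert favorable_factors(course, None, _patient()) is None


class TestFilterConservation:
    def test_printed_counts_reconciliation(self, printed_cohort, printed_endpoints):
        records, sets = printed_endpoints
        pgt_ids = {
            c.course_id
            for c in printed_cohort.courses
            if c.category is CourseCategory.PGT
        }
        pgt_pfs = [cid for cid in sets.pfs_set if cid in pgt_ids]
        pgt_excl = {c: r for c, r in sets.exclusions.items() if c in pgt_ids}
        assert len(pgt_pfs) + len(pgt_excl) == len(pgt_ids) == 117
        assert len(pgt_pfs) == 99
        reasons = sorted(pgt_excl.values())
        assert reasons.count("duration<4wk") == 14
        assert reasons.count("early PD") == 4

    def test_conservation_on_simulated(self):
        from pgtflow.simulate import SimConfig, simulate

        sim = simulate(SimConfig(seed=7, n_patients=120))
        records, sets = derive_endpoints(sim.cohort)
        assert len(sets.pfs_set) + len(sets.exclusions) == len(sim.cohort.courses)

    def test_analysis_set_nesting(self, printed_endpoints):
        _, sets = printed_endpoints
        assert set(sets.pfs_ratio_set) <= set(sets.pfs_set)
        assert set(sets.response_measurable_set) <= set(sets.response_evaluable_set)


def test_derive_endpoints_pfs_floor(printed_cohort, printed_endpoints):
    records, sets = printed_endpoints
    for r in records:
        if r.evaluable:
            assert r.pfs_days >= 28
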