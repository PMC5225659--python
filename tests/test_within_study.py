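"""Within-study risk: identities, variance structure, published-table entry
point, and the trend diagnostic."""

import itertools

import numpy as np
import pytest

import lexiscope as lx
from lexiscope import Status, SubjectRecord

from conftest import BASE_SEED, build_cohort, censored_exponential_stratum, make_records


def brute_force_event_fraction(cohort, t):
    """Independent counter: events at or before t ^ t_i, over the sample size."""
    n = cohort.n
    count = 0
    for stratum, t_i in zip(cohort.strata, cohort.t):
        for rec in stratum:
            if rec.status is Status.EVENT and rec.followup <= min(t, t_i):
                count += 1
    return count / n


def _stratum(followups, statuses):
    return make_records(followups, statuses)


class TestStratifiedSurvival:
    def test_weighted_average_arithmetic(self):
        # S_1(1) = 0.9 and S_2(1) = 0.7 with equal stratum sizes -> 0.8
        s1 = _stratum([1.0] + [2.0] * 9, ["event"] + ["admin"] * 9)
        s2 = _stratum([1.0] * 3 + [2.0] * 7, ["event"] * 3 + ["admin"] * 7)
        cohort = build_cohort([s1, s2], t=(2.0, 2.0))
        curve = lx.stratified_survival(cohort)
        assert curve(1.0) == pytest.approx(0.8)

    def test_identical_strata_equal_stratum_km(self):
        s = _stratum([0.5, 1.2, 2.0, 2.0], ["event", "event", "admin", "admin"])
        cohort = build_cohort([list(s), list(s)], t=(2.0, 2.0))
        curve = lx.stratified_survival(cohort)
        stratum_km = lx.km(lx.risk_table(s, domain_end=2.0))
        for t in (0.5, 1.2, 1.9):
            assert curve(t) == pytest.approx(stratum_km(t), abs=1e-14)

    def test_evaluation_beyond_t_k_rejected(self, rng):
        strata = [
            censored_exponential_stratum(rng, 50, 0.5, t_end) for t_end in (2.0, 1.0)
        ]
        cohort = build_cohort(strata, t=(2.0, 1.0))
        with pytest.raises(ValueError, match="only defined up to"):
            lx.stratified_survival(cohort, t=1.5)

    def test_agrees_with_within_study_curve_below_t_k(self, rng):
        strata = [
            censored_exponential_stratum(rng, 300, 0.5, t_end, ltfu_rate=0.1)
            for t_end in (2.0, 1.0)
        ]
        cohort = build_cohort(strata, t=(2.0, 1.0))
        s_s = lx.stratified_survival(cohort)
        ci_w = lx.within_study_curve(cohort)
        for t in np.linspace(0, 1.0, 11):
            assert 1.0 - s_s(t) == pytest.approx(ci_w(t), abs=1e-14)


class TestWithinStudyCurve:
    def test_single_stratum_is_one_minus_km(self, rng):
        s = censored_exponential_stratum(rng, 200, 0.5, 2.0, ltfu_rate=0.1)
        cohort = build_cohort([s], t=(2.0,))
        ci_w = lx.within_study_curve(cohort)
        surv = lx.km(lx.risk_table(s, domain_end=2.0))
        for t in np.linspace(0, 2, 9):
            assert ci_w(t) == pytest.approx(1.0 - surv(t), abs=1e-14)

    def test_binomial_identity_exhaustive_small_cohorts(self):
        # with no loss to follow-up the estimator is the event count in the
        # truncated Lexis region over n, exactly, for every t
        t_ends = (2.0, 1.0)
        followup_grid = (0.5, 1.0, 1.5, 2.0)
        n_checked = 0
        for statuses in itertools.product(["event", "admin"], repeat=4):
            for fus in itertools.product(followup_grid, repeat=4):
                strata = []
                for idx, t_i in enumerate(t_ends):
                    recs = []
                    for fu, st in zip(fus[idx * 2 : idx * 2 + 2], statuses[idx * 2 : idx * 2 + 2]):
                        fu = min(fu, t_i)
                        st_eff = Status(st)
                        if st_eff is Status.ADMIN_CENSORED:
                            fu = t_i  # admin censoring only at end of follow-up
                        recs.append(
                            SubjectRecord(
                                0.0, fu, st_eff, 1 if st_eff is Status.EVENT else None
                            )
                        )
                    strata.append(recs)
                cohort = build_cohort(strata, t=t_ends)
                curve = lx.within_study_curve(cohort)
                for t in (0.25, 0.5, 1.0, 1.5, 2.0):
                    assert curve(t) == pytest.approx(
                        brute_force_event_fraction(cohort, t), abs=1e-12
                    )
                n_checked += 1
        assert n_checked == 16 * 256

    def test_matches_true_within_study_incidence(self):
        # staggered-entry benchmark: CI_w(2) targets P(T <= 2 ^ U), U in {2, 1}
        cohort = lx.two_stratum_benchmark(20_000, seed=BASE_SEED)
        curve = lx.within_study_curve(cohort)
        truth = 0.5 * (1 - np.exp(-0.5)) + 0.5 * (1 - np.exp(-0.5))
        se = np.sqrt(curve.variance_at(2.0))
        assert abs(curve(2.0) - truth) < 3 * se


class TestWithinStudyRisk:
    def test_single_stratum_variance_is_greenwood(self, rng):
        s = censored_exponential_stratum(rng, 300, 0.5, 2.0, ltfu_rate=0.2)
        cohort = build_cohort([s], t=(2.0,))
        summary = lx.within_study_risk(cohort)
        surv = lx.km(lx.risk_table(s, domain_end=2.0))
        # k = 1: the between-stratum term vanishes identically
        assert summary.variance == pytest.approx(surv.variance_at(2.0), rel=1e-12)
        assert summary.estimate == pytest.approx(1.0 - surv(2.0), abs=1e-14)

    def test_estimate_is_weighted_average_of_per_stratum(self, rng):
        strata = [
            censored_exponential_stratum(rng, n, 0.4, t_end, ltfu_rate=0.1)
            for n, t_end in ((200, 2.0), (300, 1.0))
        ]
        cohort = build_cohort(strata, t=(2.0, 1.0))
        summary = lx.within_study_risk(cohort)
        manual = sum(
            w * s.incidence for w, s in zip(summary.weights, summary.per_stratum)
        )
        assert summary.estimate == pytest.approx(manual, abs=1e-15)
        assert summary.weights == (0.4, 0.6)
        assert 0.0 <= summary.ci_lower <= summary.estimate <= summary.ci_upper <= 1.0

    def test_empty_stratum_rejected(self):
        cohort = build_cohort([_stratum([1.0], ["event"]), []], t=(2.0, 1.0))
        with pytest.raises(ValueError, match="empty"):
            lx.within_study_risk(cohort)


class TestFromEndOfFollowup:
    def test_published_table_averages(self):
        fixture = lx.load_nordic_incidence_table()
        expected = {
            ("TS", "Denmark"): 27.1,
            ("TS", "Finland"): 8.3,
            ("HKD", "Denmark"): 139.0,
            ("HKD", "Finland"): 128.8,
        }
        for (disorder, country), value in expected.items():
            summary = lx.from_end_of_followup(fixture.probabilities(disorder, country))
            assert lx.per_ten_thousand(summary.estimate) == value
            assert summary.variance is None and not summary.variance_complete

    def test_single_stratum_passthrough(self):
        assert lx.from_end_of_followup([0.37], weights=[1.0]).estimate == 0.37

    def test_weight_validation(self):
        with pytest.raises(ValueError, match="sum to 1"):
            lx.from_end_of_followup([0.1, 0.2], weights=[0.5, 0.6])
        with pytest.raises(ValueError, match="equal length"):
            lx.from_end_of_followup([0.1, 0.2], weights=[1.0])

    def test_monotone_in_each_component(self):
        base = [0.1, 0.2, 0.3]
        ref = lx.from_end_of_followup(base).estimate
        for i in range(3):
            bumped = list(base)
            bumped[i] += 0.05
            assert lx.from_end_of_followup(bumped).estimate > ref


class TestCompetingRisks:
    def _two_cause_cohort(self, seed, competing):
        sc = lx.Scenario(
            design=lx.StudyDesign(0.0, 2.0, 3.0, 2),
            n_per_stratum=(800, 800),
            event_laws=(lx.Exponential(0.3), lx.Exponential(0.5)),
            ltfu_rate=0.05,
            competing_rate=0.2 if competing else 0.0,
            seed=seed,
        )
        records, _ = lx.simulate_cohort(sc)
        return lx.truncate_triangles(lx.stratify(records, sc.design))

    def test_reduces_to_km_form_without_competing_events(self):
        cohort = self._two_cause_cohort(BASE_SEED, competing=False)
        km_summary = lx.within_study_risk(cohort)
        aj_summary = lx.within_study_risk_cr(cohort, cause=1)
        assert aj_summary.estimate == pytest.approx(km_summary.estimate, abs=1e-12)
        assert aj_summary.variance == pytest.approx(km_summary.variance, rel=1e-9)

    def test_single_stratum_variance_is_aj_variance(self):
        cohort = self._two_cause_cohort(BASE_SEED, competing=True)
        single = build_cohort([list(cohort.strata[0])], t=(cohort.t[0],))
        summary = lx.within_study_risk_cr(single, cause=1)
        curve = lx.aj(lx.risk_table(single.strata[0], domain_end=single.t[0]), 1)
        assert summary.variance == pytest.approx(
            curve.variance_at(single.t[0]), rel=1e-12
        )


class TestTrendDiagnostic:
    def test_identical_strata_zero_standardized_difference(self):
        s = _stratum([0.5, 1.0, 2.0], ["event", "event", "admin"])
        cohort = build_cohort([list(s), list(s)], t=(2.0, 2.0))
        _table, summary = lx.trend_diagnostic(cohort, grid=[0.75, 1.5])
        assert summary["max_standardized_difference"] == 0.0
        assert not summary["flag"]

    def test_null_flag_rate_near_nominal(self):
        # iid strata: the pointwise 5%-level comparison flags ~5% of the time
        rng = np.random.default_rng(BASE_SEED)
        reps, flags = 300, 0
        for _ in range(reps):
            strata = [
                censored_exponential_stratum(rng, 400, 0.4, t_end)
                for t_end in (2.0, 1.0)
            ]
            cohort = build_cohort(strata, t=(2.0, 1.0))
            _table, summary = lx.trend_diagnostic(cohort, grid=[1.0])
            flags += summary["flag"]
        rate = flags / reps
        # binomial(300, 0.05): 3 SE is about 0.038
        assert rate < 0.05 + 0.04

    def test_hazard_ratio_two_is_detected(self):
        cohort = lx.two_stratum_benchmark(5_000, seed=BASE_SEED)
        _table, summary = lx.trend_diagnostic(cohort, grid=[0.5, 1.0])
        assert summary["flag"]

    def test_requires_two_strata(self, rng):
        s = censored_exponential_stratum(rng, 50, 0.5, 2.0)
        cohort = build_cohort([s], t=(2.0,))
        with pytest.raises(ValueError, match="at least two strata"):
            lx.trend_diagnostic(cohort)
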