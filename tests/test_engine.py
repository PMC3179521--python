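"""Discrete-event engine: event-time sampling, copula, person/cohort simulation."""
import copy
import math

import numpy as np
import pytest
from scipy import stats

from oasim.engine import (EngineConfig, Person, correlated_uniform_pair,
                          draw_person_uniforms, replacement_distribution,
                          sample_event_time, simulate_cohort, simulate_pair,
                          STATE_POST_PRIMARY)
from oasim.outcomes import dalys_averted
from oasim.weibull import WeibullComponent, WeibullMixture


class TestSampleEventTime:
    def test_exponential_quantile(self):
        u = 1.0 - math.exp(-1.0)
        assert sample_event_time(0.2, u) == pytest.approx(5.0, abs=1e-12)

    def test_zero_hazard_never_fires(self):
        assert sample_event_time(0.0, 0.5) == math.inf

    def test_piecewise_hazard_closed_form(self):
        # 0.1/y for 5 years then 0.3/y; u = 0.5 -> cumulative hazard ln 2.
        t = sample_event_time([(0.0, 0.1), (5.0, 0.3)], 0.5)
        expected = 5.0 + (math.log(2.0) - 0.5) / 0.3
        assert t == pytest.approx(expected, abs=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            sample_event_time(0.2, 0.0)
        with pytest.raises(ValueError):
            sample_event_time(-0.1, 0.5)
        with pytest.raises(ValueError):
            sample_event_time([(1.0, 0.1)], 0.5)


class TestCopula:
    def test_independent_at_rho_zero(self):
        u1, u2 = correlated_uniform_pair(0.0, np.random.default_rng(0), 100_000)
        rho, _ = stats.spearmanr(u1, u2)
        assert abs(rho) < 0.02

    def test_extreme_positive_correlation(self):
        u1, u2 = correlated_uniform_pair(0.99, np.random.default_rng(1), 100_000)
        rho, _ = stats.spearmanr(u1, u2)
        assert rho > 0.95
        # matches the Gaussian-copula rank-correlation formula
        assert rho == pytest.approx(6.0 / math.pi * math.asin(0.99 / 2.0), abs=0.01)

    def test_extreme_negative_correlation(self):
        u1, u2 = correlated_uniform_pair(-0.99, np.random.default_rng(2), 100_000)
        rho, _ = stats.spearmanr(u1, u2)
        assert rho < -0.95

    def test_margins_uniform(self):
        u1, _ = correlated_uniform_pair(0.7, np.random.default_rng(3), 50_000)
        assert stats.kstest(u1, "uniform").pvalue > 0.01

    def test_out_of_bounds_rho_rejected(self):
        with pytest.raises(ValueError):
            correlated_uniform_pair(0.999, np.random.default_rng(0))


def _person(pid=0, sex="male", age=62.0, site="hip", grades=(4, 0), bg=0.1):
    return Person(pid=pid, sex=sex, age=age, site=site, grades=grades, bg_rate=bg)


class TestSimulatePerson:
    def test_entry_criterion_enforced(self):
        with pytest.raises(ValueError, match="entry"):
            _person(grades=(1, 0))

    def test_comparator_never_operates(self, fixture_ps):
        rng = np.random.default_rng(0)
        for _ in range(50):
            d = draw_person_uniforms(rng)
            _, comp = simulate_pair(_person(), fixture_ps, EngineConfig(), d)
            assert comp.operations == []
            states = {s for t, s in comp.joint_segments[0]}
            assert states <= {2, 3, 4}      # untreated progression only

    def test_certain_surgical_death_ends_life(self, fixture_ps):
        ps = copy.deepcopy(fixture_ps)
        ps.surgical_death_prob = 1.0
        d = draw_person_uniforms(np.random.default_rng(1))
        h_int, h_comp = simulate_pair(_person(), ps, EngineConfig(), d)
        assert len(h_int.operations) == 1
        assert h_int.operations[0].fatal
        assert h_int.death_cause == "surgical"
        assert h_int.death_time == h_int.operations[0].time
        if h_comp.death_time > h_int.death_time:
            assert dalys_averted(h_int, h_comp, ps, 0.0) < 0.0

    def test_event_times_monotone_no_post_death_events(self, small_hip_pairs):
        for h_int, h_comp in small_hip_pairs[:100]:
            for h in (h_int, h_comp):
                for j in (0, 1):
                    times = [t for t, _ in h.joint_segments[j]]
                    assert times == sorted(times)
                    assert all(t <= h.death_time for t in times)
                assert all(op.time <= h.death_time for op in h.operations)

    def test_single_operation_when_implants_never_fail(self, fixture_ps):
        ps = copy.deepcopy(fixture_ps)
        ps.surgical_death_prob = 0.0
        forever = WeibullMixture(WeibullComponent(1.0, 1e8),
                                 WeibullComponent(1.0, 1e9), 0.5)
        ps.implant_failure = {"hip": forever, "knee": forever}
        rng = np.random.default_rng(2)
        for pid in range(200):
            d = draw_person_uniforms(rng)
            h, _ = simulate_pair(_person(pid=pid, grades=(4, 4)), ps,
                                 EngineConfig(), d)
            per_joint = [sum(op.joint == j for op in h.operations) for j in (0, 1)]
            assert max(per_joint) <= 1
            assert all(op.kind == "primary" for op in h.operations)


class TestSimulateCohort:
    def test_same_seed_identical_histories(self, fixture_ps, small_hip_cohort):
        a = simulate_cohort(small_hip_cohort[:40], fixture_ps, EngineConfig(seed=3))
        b = simulate_cohort(small_hip_cohort[:40], fixture_ps, EngineConfig(seed=3))
        assert a == b

    def test_operated_fraction_nondegenerate(self, small_hip_pairs):
        frac = np.mean([len(h.operations) > 0 for h, _ in small_hip_pairs])
        assert 0.0 < frac < 1.0

    def test_unilateral_restriction_blocks_second_joint(self, fixture_ps,
                                                        small_hip_cohort):
        pairs = simulate_cohort(small_hip_cohort[:80], fixture_ps,
                                EngineConfig(seed=4, unilateral_restriction=True))
        for h, c in pairs:
            for hist in (h, c):
                assert [s for _, s in hist.joint_segments[1]] == [0]
            assert all(op.joint == 0 for op in h.operations)

    def test_positive_correlation_raises_bilateral_replacements(self, fixture_ps,
                                                                fixture_spec):
        from oasim.synth import generate_cohort
        cohort = generate_cohort(fixture_spec, fixture_ps, "hip", 0.01,
                                 np.random.default_rng(21))

        def bilateral_fraction(rho):
            pairs = simulate_cohort(
                cohort, fixture_ps, EngineConfig(seed=9, joint_correlation=rho))
            ops = [{op.joint for op in h.operations if not op.fatal}
                   for h, _ in pairs]
            operated = [js for js in ops if js]
            return np.mean([js == {0, 1} for js in operated])

        assert bilateral_fraction(0.99) > bilateral_fraction(0.0)


class TestReplacementDistribution:
    def test_single_stratum_gets_all_mass(self, fixture_ps):
        rng = np.random.default_rng(5)
        persons = [_person(pid=i, age=61.0) for i in range(60)]
        pairs = simulate_cohort(persons, fixture_ps, EngineConfig(seed=6))
        dist = replacement_distribution([h for h, _ in pairs])
        assert dist["proportion"].sum() == pytest.approx(1.0)
        assert set(dist["sex"]) == {"male"}

    def test_comparator_table_empty(self, small_hip_pairs):
        dist = replacement_distribution([c for _, c in small_hip_pairs])
        assert dist.empty

    def test_proportions_match_brute_force_recount(self, small_hip_pairs):
        from oasim.params import age_band_start
        dist = replacement_distribution([h for h, _ in small_hip_pairs])
        # independent tally straight off the event logs
        counts = {}
        for h, _ in small_hip_pairs:
            for op in h.operations:
                key = (h.sex, age_band_start(op.age))
                counts[key] = counts.get(key, 0) + 1
        total = sum(counts.values())
        for _, row in dist.iterrows():
            key = (row["sex"], row["age_lo"])
            assert row["count"] == counts[key]
            assert row["proportion"] == pytest.approx(counts[key] / total)
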