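"""Outcome accounting: discounting, combined disability, DALYs, costs, ICERs."""
import copy
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oasim.engine import LifeHistory, OpRecord
from oasim.outcomes import (PairedOutcomeData, ScenarioFlags, combined_dw,
                            dalys_averted, discount, discount_integral, icer,
                            per_person, scenario_costs)


def _history(arm, segments0, death, sex="male", bg=0.0, ops=(), site="hip",
             age=62.0):
    return LifeHistory(pid=0, arm=arm, sex=sex, site=site, entry_age=age,
                       bg_rate=bg, death_time=death, death_cause="background",
                       joint_segments=(list(segments0), [(0.0, 0)]),
                       operations=list(ops))


class TestDiscount:
    def test_one_period_closed_form(self):
        assert discount(103.0, 1.0, 0.03) == pytest.approx(100.0)

    def test_identity_at_time_zero(self):
        assert discount(57.3, 0.0, 0.08) == 57.3

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            discount(1.0, -0.5, 0.03)

    def test_constant_flow_annuity(self):
        expected = (1.0 - 1.03 ** -10) / math.log(1.03)
        assert discount_integral(0.0, 10.0, 0.03) == pytest.approx(expected, abs=1e-12)

    def test_zero_rate_is_duration(self):
        assert discount_integral(2.0, 7.5, 0.0) == 5.5


class TestCombinedDw:
    @pytest.mark.parametrize("bg, dw1, dw2, expected", [
        (0.0, 0.3, 0.0, 0.3),
        (0.1, 0.2, 0.25, 0.46),
        (0.0, 0.0, 0.0, 0.0),
    ])
    def test_values(self, bg, dw1, dw2, expected):
        assert combined_dw(bg, dw1, dw2) == pytest.approx(expected, abs=1e-12)

    @given(bg=st.floats(0, 1), dw1=st.floats(0, 1), dw2=st.floats(0, 1))
    @settings(max_examples=200, deadline=None)
    def test_bounds_and_symmetry(self, bg, dw1, dw2):
        v = combined_dw(bg, dw1, dw2)
        assert max(bg, dw1, dw2) - 1e-12 <= v <= min(1.0, bg + dw1 + dw2) + 1e-12
        assert v == pytest.approx(combined_dw(bg, dw2, dw1), abs=1e-12)


class TestDalysAverted:
    def test_identical_histories_give_zero(self, fixture_ps):
        h = _history("intervention", [(0.0, 4)], 12.0)
        c = _history("comparator", [(0.0, 4)], 12.0)
        assert dalys_averted(h, c, fixture_ps, 0.03) == 0.0

    def test_hand_integral_same_lifespan(self, fixture_ps):
        # comparator dw 0.30 (severe symptomatic), intervention dw 0.10
        # (grade 3-4 asymptomatic) for 10 years, undiscounted -> 2.0 averted.
        h = _history("intervention", [(0.0, 3)], 10.0)
        c = _history("comparator", [(0.0, 4)], 10.0)
        assert dalys_averted(h, c, fixture_ps, 0.0) == pytest.approx(2.0, abs=1e-12)

    def test_surgical_death_counts_full_lost_years(self, fixture_ps):
        # death at t=0 vs 10 comparator years at dw 0.30, undiscounted:
        # averted = -10 * (1 - 0.30).
        h = _history("intervention", [(0.0, 4)], 0.0)
        h.death_cause = "surgical"
        c = _history("comparator", [(0.0, 4)], 10.0)
        assert dalys_averted(h, c, fixture_ps, 0.0) == pytest.approx(-7.0, abs=1e-12)

    def test_antisymmetric_under_arm_swap(self, fixture_ps, small_hip_pairs):
        for h, c in small_hip_pairs[:50]:
            a = dalys_averted(h, c, fixture_ps, 0.03)
            b = dalys_averted(c, h, fixture_ps, 0.03)
            assert a == pytest.approx(-b, abs=1e-9)

    def test_mismatched_person_rejected(self, fixture_ps):
        h = _history("intervention", [(0.0, 4)], 10.0)
        c = _history("comparator", [(0.0, 4)], 10.0)
        c.pid = 1
        with pytest.raises(ValueError, match="different persons"):
            dalys_averted(h, c, fixture_ps, 0.03)


class TestScenarioCosts:
    def test_single_uncomplicated_primary_hip(self, fixture_ps):
        op = OpRecord(time=0.0, joint=0, kind="primary", cscc=False,
                      fatal=False, age=62.0)
        h = _history("intervention", [(0.0, 4), (0.0, 5)], 10.0, ops=[op])
        c = _history("comparator", [(0.0, 4)], 10.0)
        flags = ScenarioFlags(include_cost_offset=False)
        got = scenario_costs(h, c, fixture_ps, flags, 0.0)
        assert got == pytest.approx(13_648 + 2_254 + 839, abs=1e-9)
        with_time = scenario_costs(
            h, c, fixture_ps, ScenarioFlags(False, include_time_cost=True), 0.0)
        assert with_time == pytest.approx(13_648 + 2_254 + 839 + 168 + 2_227,
                                          abs=1e-9)

    def test_no_operations_costs_nothing(self, fixture_ps):
        h = _history("intervention", [(0.0, 0)], 10.0)
        h.joint_segments = ([(0.0, 0)], [(0.0, 0)])
        c = _history("comparator", [(0.0, 0)], 10.0)
        c.joint_segments = ([(0.0, 0)], [(0.0, 0)])
        for flags in (ScenarioFlags(True, True, True), ScenarioFlags(False, False, False)):
            assert scenario_costs(h, c, fixture_ps, flags, 0.03) == 0.0

    def test_unit_cost_scaling_scales_increment(self, fixture_ps, small_hip_pairs):
        scaled = copy.deepcopy(fixture_ps)
        k = 2.5
        c = scaled.costs
        c.government = {q: v * k for q, v in c.government.items()}
        c.other_surgery *= k
        c.out_of_pocket = {q: v * k for q, v in c.out_of_pocket.items()}
        c.time_pre_visit = {q: v * k for q, v in c.time_pre_visit.items()}
        c.time_recuperation = {q: v * k for q, v in c.time_recuperation.items()}
        c.oa_annual_expenditure *= k
        c.unrelated_annual_expenditure = {
            q: v * k for q, v in c.unrelated_annual_expenditure.items()}
        flags = ScenarioFlags(True, True, True)
        for h, comp in small_hip_pairs[:30]:
            base = scenario_costs(h, comp, fixture_ps, flags, 0.03)
            assert scenario_costs(h, comp, scaled, flags, 0.03) == \
                pytest.approx(k * base, rel=1e-12, abs=1e-9)

    def test_discounting_shrinks_positive_flows(self, fixture_ps, small_hip_pairs):
        flags = ScenarioFlags(include_cost_offset=False, include_time_cost=True)
        for h, c in small_hip_pairs[:30]:
            undisc = scenario_costs(h, c, fixture_ps, flags, 0.0)
            disc = scenario_costs(h, c, fixture_ps, flags, 0.03)
            assert disc <= undisc + 1e-9


class TestReporting:
    @pytest.mark.parametrize("total, n, kind, expected", [
        (420e6, 68_908, "cost", 6_100),
        (1.2e9, 68_908, "cost", 17_000),
        (115_000, 68_908, "daly", 1.7),
        (113_000, 100_657, "daly", 1.1),
        (0.0, 100, "cost", 0.0),
    ])
    def test_per_person_rounding(self, total, n, kind, expected):
        assert per_person(total, n, kind) == expected

    def test_per_person_rejects_empty_cohort(self):
        with pytest.raises(ValueError):
            per_person(100.0, 0)

    def test_icer_values_and_flags(self):
        assert icer(50_000.0, 1.0).value == 50_000.0
        assert icer(3.6e8, 1.0e5).value == pytest.approx(3_600.0)
        dom = icer(-10.0, 2.0)
        assert dom.dominant and not dom.undefined
        und = icer(5.0, 0.0)
        assert und.undefined and math.isnan(und.value)


class TestPairedOutcomeData:
    def test_totals_match_per_person_route(self, fixture_ps, small_hip_pairs):
        data = PairedOutcomeData(small_hip_pairs, fixture_ps, 0.03)
        slow_daly = sum(dalys_averted(h, c, fixture_ps, 0.03)
                        for h, c in small_hip_pairs)
        assert data.total_dalys_averted(fixture_ps) == \
            pytest.approx(slow_daly, rel=1e-10)
        for flags in (ScenarioFlags(True, False, False),
                      ScenarioFlags(False, True, True)):
            slow_cost = sum(scenario_costs(h, c, fixture_ps, flags, 0.03)
                            for h, c in small_hip_pairs)
            assert data.total_cost(fixture_ps, flags) == \
                pytest.approx(slow_cost, rel=1e-10)
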