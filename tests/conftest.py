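"""Shared fixtures: the default parameter set and small simulated cohorts."""
import copy
from dataclasses import replace

import numpy as np
import pytest

from oasim import default_fixture, generate_cohort
from oasim.engine import EngineConfig, simulate_cohort


@pytest.fixture(scope="session")
def fixture_ps():
    ps, _ = default_fixture()
    return ps


@pytest.fixture(scope="session")
def fixture_spec():
    _, spec = default_fixture()
    return spec


@pytest.fixture(scope="session")
def small_hip_cohort(fixture_ps, fixture_spec):
    """~345 hip persons (0.5% scale), deterministic."""
    return generate_cohort(fixture_spec, fixture_ps, "hip", 0.005,
                           np.random.default_rng(11))


@pytest.fixture(scope="session")
def small_hip_pairs(fixture_ps, small_hip_cohort):
    """Paired (intervention, comparator) histories for the small cohort."""
    return simulate_cohort(small_hip_cohort, fixture_ps, EngineConfig(seed=5))


def null_parameter_set(ps):
    """A copy of ``ps`` in which the intervention can change nothing:
    effects 0, all costs 0, no surgical mortality, no OA mortality excess,
    and a failed implant as disabling as untreated severe OA."""
    out = copy.deepcopy(ps)
    out.oa_mortality_rr = 1.0
    out.surgical_death_prob = 0.0
    for site in out.dw_failed_implant:
        out.dw_failed_implant[site] = out.dw_by_grade["g34_symptomatic"]
    for key, spec in out.effects.items():
        out.effects[key] = replace(spec, value=0.0)
    c = out.costs
    c.government = {k: 0.0 for k in c.government}
    c.other_surgery = 0.0
    c.out_of_pocket = {k: 0.0 for k in c.out_of_pocket}
    c.time_pre_visit = {k: 0.0 for k in c.time_pre_visit}
    c.time_recuperation = {k: 0.0 for k in c.time_recuperation}
    c.oa_annual_expenditure = 0.0
    c.unrelated_annual_expenditure = {k: 0.0 for k in c.unrelated_annual_expenditure}
    out.cost_uncertainty = {}
    return out
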