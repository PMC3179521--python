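"""Parameter model: validation, round-trip I/O, distribution sampling."""
import copy
import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from oasim.params import (DistributionSpec, ParameterError, beta_from_moments,
                          from_dict, load_parameters, sample_second_order,
                          save_parameters, to_dict)


class TestLoadValidate:
    def test_fixture_file_round_trip(self, fixture_ps, tmp_path):
        path = tmp_path / "params.yaml"
        save_parameters(fixture_ps, path)
        again = load_parameters(path)
        assert to_dict(again) == to_dict(fixture_ps)

    def test_table_costs_present(self, fixture_ps):
        assert fixture_ps.costs.government["hip.primary.nocscc"] == 13_648
        assert fixture_ps.discount_rate == 0.03

    def test_out_of_range_probability_rejected(self, fixture_ps, tmp_path):
        d = to_dict(fixture_ps)
        d["surgical_death_prob"] = 1.5
        with pytest.raises(ParameterError, match="surgical_death_prob"):
            from_dict(d)

    def test_unknown_key_rejected(self, fixture_ps):
        d = to_dict(fixture_ps)
        d["not_a_parameter"] = 1
        with pytest.raises(ParameterError, match="not_a_parameter"):
            from_dict(d)

    def test_missing_key_rejected(self, fixture_ps):
        d = to_dict(fixture_ps)
        del d["discount_rate"]
        with pytest.raises(ParameterError, match="discount_rate"):
            from_dict(d)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_parameters(tmp_path / "absent.yaml")


class TestBetaFromMoments:
    def test_uniform_moments_give_unit_shapes(self):
        a, b = beta_from_moments(0.5, math.sqrt(1.0 / 12.0))
        assert a == pytest.approx(1.0, abs=1e-9)
        assert b == pytest.approx(1.0, abs=1e-9)

    def test_round_trip_against_density_integration(self):
        # Moments of the returned density recovered by numerical integration.
        a, b = beta_from_moments(0.5202, 0.0697)
        mean, _ = integrate.quad(lambda x: x * stats.beta.pdf(x, a, b), 0, 1)
        ex2, _ = integrate.quad(lambda x: x * x * stats.beta.pdf(x, a, b), 0, 1)
        assert mean == pytest.approx(0.5202, abs=1e-9)
        assert math.sqrt(ex2 - mean * mean) == pytest.approx(0.0697, abs=1e-9)

    def test_infeasible_variance_rejected(self):
        with pytest.raises(ValueError):
            beta_from_moments(0.5, 0.6)
        with pytest.raises(ValueError):
            beta_from_moments(1.2, 0.1)

    @given(mean=st.floats(0.05, 0.95), frac=st.floats(0.05, 0.95))
    @settings(max_examples=50, deadline=None)
    def test_moment_inversion_property(self, mean, frac):
        sd = frac * math.sqrt(mean * (1 - mean))
        a, b = beta_from_moments(mean, sd)
        assert a > 0 and b > 0
        assert a / (a + b) == pytest.approx(mean, rel=1e-12)
        var = a * b / ((a + b) ** 2 * (a + b + 1))
        assert math.sqrt(var) == pytest.approx(sd, rel=1e-9)


class TestDistributionSpec:
    @pytest.mark.parametrize("spec", [
        DistributionSpec("normal", (0.52, 0.07)),
        DistributionSpec("beta", (2.0, 5.0)),
        DistributionSpec("gamma", (13648.0, 1.0)),
        DistributionSpec("triangular", (0.8, 1.0, 1.2)),
    ])
    def test_sample_moments_match_analytic(self, spec):
        rng = np.random.default_rng(7)
        x = np.array([spec.sample(rng) for _ in range(10_000)])
        se_mean = spec.sd() / 100.0
        assert abs(x.mean() - spec.mean()) < 3 * se_mean
        # sd of the sample sd is ~ sd / sqrt(2n) for near-normal cases
        assert abs(x.std(ddof=1) - spec.sd()) < 5 * spec.sd() / math.sqrt(2e4)

    def test_point_is_degenerate(self):
        rng = np.random.default_rng(0)
        assert DistributionSpec("point", (3.14,)).sample(rng) == 3.14

    def test_support_bounds_respected(self):
        spec = DistributionSpec("normal", (0.0, 1.0), lower=-0.5, upper=0.5)
        rng = np.random.default_rng(1)
        draws = [spec.sample(rng) for _ in range(500)]
        assert all(-0.5 <= v <= 0.5 for v in draws)

    def test_invalid_families_rejected(self):
        with pytest.raises(ParameterError):
            DistributionSpec("cauchy", (0.0, 1.0))
        with pytest.raises(ParameterError):
            DistributionSpec("beta", (-1.0, 2.0))
        with pytest.raises(ParameterError):
            DistributionSpec("triangular", (1.0, 0.5, 2.0))


class TestSecondOrderSampling:
    def test_point_specs_reproduce_input(self, fixture_ps):
        ps = copy.deepcopy(fixture_ps)
        ps.cost_uncertainty = {k: DistributionSpec("point", (1234.5,))
                               for k in ("other_surgery",)}
        for key, spec in ps.effects.items():
            ps.effects[key] = replace(spec, dist=DistributionSpec(
                "point", (spec.mean,)), regression=None)
        drawn = sample_second_order(ps, np.random.default_rng(3))
        assert drawn.costs.other_surgery == 1234.5
        for key in ps.effects:
            assert drawn.effects[key].current == ps.effects[key].mean

    def test_reproducible_given_seed(self, fixture_ps):
        a = sample_second_order(fixture_ps, np.random.default_rng(42))
        b = sample_second_order(fixture_ps, np.random.default_rng(42))
        assert to_dict(a) == to_dict(b)

    def test_first_order_fields_unchanged(self, fixture_ps):
        drawn = sample_second_order(fixture_ps, np.random.default_rng(9))
        assert drawn.mortality_hazard == fixture_ps.mortality_hazard
        assert drawn.grade_progression == fixture_ps.grade_progression
        assert drawn.implant_failure == fixture_ps.implant_failure
        assert drawn.surgical_uptake_rate == fixture_ps.surgical_uptake_rate

    def test_knee_effect_long_run_mean(self, fixture_ps):
        rng = np.random.default_rng(5)
        vals = np.array([
            sample_second_order(fixture_ps, rng).effects["knee.primary.male"].current
            for _ in range(2_000)])
        spec = fixture_ps.effects["knee.primary.male"]
        assert abs(vals.mean() - spec.mean) < 3 * spec.sd / math.sqrt(vals.size)

    def test_triangular_cost_draws_within_20pc(self, fixture_ps):
        rng = np.random.default_rng(6)
        base = fixture_ps.costs.out_of_pocket["hip"]
        for _ in range(200):
            v = sample_second_order(fixture_ps, rng).costs.out_of_pocket["hip"]
            assert 0.8 * base <= v <= 1.2 * base
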