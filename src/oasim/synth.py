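"""Synthetic fixtures standing in for the study's unavailable inputs.

The printed effect-size table (per site/operation/sex) and the unit-cost
table are embedded verbatim and tagged with their table of origin.  Every
other input — life-table hazards, OA grade-progression and surgical-uptake
rates, implant-failure mixtures, disability weights, background disability
and expenditure rates, cohort age structure — is an invented but plausible
stand-in, tagged ``fixture-invented`` in the parameter provenance map so the
two classes are machine-distinguishable.  Passing tests therefore validate
model mechanics, not the original epidemiological inputs.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .effects import InstrumentScorePair, RegressionEffectSpec
from .engine import Person
from .params import (AGE_BAND_STARTS, COST_CLASSES, CostTable, DistributionSpec,
                     EffectSpec, GRADE_NAMES, ParameterSet, SEXES, SITES,
                     beta_from_moments)
from .weibull import RevisionObservations, WeibullComponent, WeibullMixture, mixture_cdf

__all__ = [
    "EFFECT_TABLE", "COHORT_SIZES", "FixtureSpec",
    "default_fixture", "generate_cohort", "synthetic_revision_curve",
    "generate_study_table", "default_revision_times",
]

# Printed effect sizes on the disability weight: (site, operation, sex) ->
# (mean, sd, 95% CI low, 95% CI high).   [provenance: published effect table]
EFFECT_TABLE = {
    ("hip", "primary", "male"): (0.3358, 0.0454, 0.2548, 0.4319),
    ("hip", "primary", "female"): (0.3479, 0.0376, 0.2793, 0.4260),
    ("hip", "revision", "male"): (0.5339, 0.0830, 0.3883, 0.7115),
    ("hip", "revision", "female"): (0.5527, 0.0709, 0.4256, 0.7018),
    ("knee", "primary", "male"): (0.5202, 0.0697, 0.3888, 0.6606),
    ("knee", "primary", "female"): (0.5205, 0.0687, 0.3891, 0.6580),
    ("knee", "revision", "male"): (0.6610, 0.0492, 0.5642, 0.7573),
    ("knee", "revision", "female"): (0.6698, 0.0474, 0.5772, 0.7621),
}

# Printed unit costs per surgery, AUD 2003.   [provenance: published cost table]
_GOVERNMENT = {
    "hip.primary.nocscc": 13_648, "hip.primary.cscc": 16_744,
    "hip.revision.nocscc": 16_744, "hip.revision.cscc": 30_648,
    "knee.primary.nocscc": 13_640, "knee.primary.cscc": 19_620,
    "knee.revision.nocscc": 19_620, "knee.revision.cscc": 35_912,
}
_OTHER_SURGERY = 2_254
_OUT_OF_POCKET = {"hip": 839, "knee": 1_019}
_TIME_PRE_VISIT = {"hip": 168, "knee": 171}
_TIME_RECUPERATION = {
    "hip.male.primary.nocscc": 2_227, "hip.male.primary.cscc": 3_781,
    "hip.male.revision.nocscc": 3_781, "hip.male.revision.cscc": 5_629,
    "hip.female.primary.nocscc": 1_576, "hip.female.primary.cscc": 2_677,
    "hip.female.revision.nocscc": 2_677, "hip.female.revision.cscc": 3_985,
    "knee.male.primary.nocscc": 2_096, "knee.male.primary.cscc": 4_197,
    "knee.male.revision.nocscc": 4_197, "knee.male.revision.cscc": 6_246,
    "knee.female.primary.nocscc": 1_484, "knee.female.primary.cscc": 2_970,
    "knee.female.revision.nocscc": 2_970, "knee.female.revision.cscc": 4_422,
}

# Cohort entering the analysis, by site and sex.   [provenance: stated]
COHORT_SIZES = {
    "hip": {"male": 30_347, "female": 38_561},
    "knee": {"male": 42_930, "female": 57_727},
}


@dataclass(frozen=True)
class FixtureSpec:
    """Cohort-construction settings; all distributional details invented."""

    seed: int = 0
    cohort_sizes: dict = field(default_factory=lambda: {
        s: dict(d) for s, d in COHORT_SIZES.items()})
    bilateral_proportion: float = 0.5
    # Age-band weights concentrated 60-79 (invented).
    age_weights: dict = field(default_factory=lambda: {
        40: 0.03, 45: 0.05, 50: 0.07, 55: 0.09, 60: 0.13, 65: 0.15,
        70: 0.16, 75: 0.14, 80: 0.10, 85: 0.05, 90: 0.02, 95: 0.01})
    # Entry grade of the index joint (must satisfy the entry criterion).
    index_grade_weights: dict = field(default_factory=lambda: {
        2: 0.45, 3: 0.25, 4: 0.30})
    # Entry grade of the second joint when bilateral.
    second_grade_weights: dict = field(default_factory=lambda: {
        1: 0.2, 2: 0.4, 3: 0.2, 4: 0.2})


def _hip_regression(mean: float, sd: float, pre: float = 0.35,
                    se_pre: float = 0.02) -> RegressionEffectSpec:
    """Synthetic two-coefficient regression (intercept = pre-surgery EQ-5D
    score, slope = post-surgery gain) calibrated by the delta method so the
    sampled effect has approximately the requested mean and sd.

    Stand-in for the unavailable published coefficient set; labelled
    synthetic through the parameter provenance map.
    """
    gain = mean * (1.0 - pre)
    d_pre = gain / (1.0 - pre) ** 2          # d effect / d intercept
    var_gain = sd * sd - (d_pre * se_pre) ** 2
    if var_gain <= 0:
        raise ValueError("pre-score SE too large for the requested effect sd")
    se_gain = math.sqrt(var_gain) * (1.0 - pre)
    return RegressionEffectSpec(
        coef_mean=(pre, gain), coef_se=(se_pre, se_gain),
        x_pre=(1.0, 0.0), x_post=(1.0, 1.0),
    )


def _effect_spec(site: str, op: str, sex: str) -> EffectSpec:
    mean, sd, lo, hi = EFFECT_TABLE[(site, op, sex)]
    if site == "hip" and op == "primary":
        return EffectSpec(site, op, sex, mean, sd, lo, hi,
                          regression=_hip_regression(mean, sd))
    a, b = beta_from_moments(mean, sd)
    return EffectSpec(site, op, sex, mean, sd, lo, hi,
                      dist=DistributionSpec("beta", (a, b)))


def _band_mid(age_lo: int) -> float:
    return age_lo + 2.5


def default_fixture() -> tuple:
    """The default parameter set and cohort spec: printed tables verbatim,
    invented epidemiology; fully deterministic."""
    mortality, pyld, unrelated = {}, {}, {}
    for sex in SEXES:
        sex_mult = 1.0 if sex == "male" else 0.65
        for a in AGE_BAND_STARTS:
            mid = _band_mid(a)
            mortality[f"{sex}.{a}"] = sex_mult * 0.0018 * math.exp(0.085 * (mid - 42.5))
            pyld[f"{sex}.{a}"] = min(0.30, 0.04 + 0.0035 * (mid - 42.5))
            unrelated[f"{sex}.{a}"] = 1_500.0 + 110.0 * (mid - 42.5)

    effects = {f"{s}.{o}.{x}": _effect_spec(s, o, x)
               for (s, o, x) in EFFECT_TABLE}

    costs = CostTable(
        government={k: float(v) for k, v in _GOVERNMENT.items()},
        other_surgery=float(_OTHER_SURGERY),
        out_of_pocket={k: float(v) for k, v in _OUT_OF_POCKET.items()},
        time_pre_visit={k: float(v) for k, v in _TIME_PRE_VISIT.items()},
        time_recuperation={k: float(v) for k, v in _TIME_RECUPERATION.items()},
        oa_annual_expenditure=600.0,
        unrelated_annual_expenditure=unrelated,
    )

    # Second-order cost uncertainty: gamma(shape = unit cost, scale = 1) for
    # surgery costs; triangular +/-20% for out-of-pocket and time unit costs.
    cost_unc = {}
    for k, v in costs.government.items():
        cost_unc[f"government.{k}"] = DistributionSpec("gamma", (v, 1.0))
    cost_unc["other_surgery"] = DistributionSpec("gamma", (costs.other_surgery, 1.0))
    for table, name in ((costs.out_of_pocket, "out_of_pocket"),
                        (costs.time_pre_visit, "time_pre_visit"),
                        (costs.time_recuperation, "time_recuperation")):
        for k, v in table.items():
            cost_unc[f"{name}.{k}"] = DistributionSpec(
                "triangular", (0.8 * v, v, 1.2 * v))

    ps = ParameterSet(
        mortality_hazard=mortality,
        oa_mortality_rr=1.1,
        grade_progression={
            "hip": {"incidence": 0.03, "radiological_to_symptomatic": 0.10,
                    "symptomatic_to_advanced": 0.07, "advanced_to_severe": 0.20},
            "knee": {"incidence": 0.03, "radiological_to_symptomatic": 0.10,
                     "symptomatic_to_advanced": 0.08, "advanced_to_severe": 0.22},
        },
        bilateral_proportion=0.5,
        surgical_uptake_rate={"hip": 0.15, "knee": 0.12},
        surgical_death_prob=0.006,
        complication_prob={"primary": 0.13, "revision": 0.20},
        implant_failure={
            "hip": WeibullMixture(WeibullComponent(1.2, 3.0),
                                  WeibullComponent(3.0, 24.0), 0.25),
            "knee": WeibullMixture(WeibullComponent(1.1, 2.5),
                                   WeibullComponent(2.8, 20.0), 0.30),
        },
        dw_by_grade={"none": 0.0, "g2_radiological": 0.0, "g2_symptomatic": 0.06,
                     "g34_asymptomatic": 0.10, "g34_symptomatic": 0.30},
        dw_failed_implant={"hip": 0.35, "knee": 0.35},
        effects=effects,
        costs=costs,
        discount_rate=0.03,
        pyld_rate=pyld,
        cost_uncertainty=cost_unc,
        provenance={
            "effects": "published-effect-table",
            "costs.government": "published-cost-table",
            "costs.other_surgery": "published-cost-table",
            "costs.out_of_pocket": "published-cost-table",
            "costs.time_pre_visit": "published-cost-table",
            "costs.time_recuperation": "published-cost-table",
            "costs.oa_annual_expenditure": "fixture-invented",
            "costs.unrelated_annual_expenditure": "fixture-invented",
            "cost_uncertainty": "published-uncertainty-table",
            "discount_rate": "stated",
            "oa_mortality_rr": "stated",
            "mortality_hazard": "fixture-invented",
            "pyld_rate": "fixture-invented",
            "grade_progression": "fixture-invented",
            "surgical_uptake_rate": "fixture-invented",
            "surgical_death_prob": "fixture-invented",
            "complication_prob": "fixture-invented",
            "implant_failure": "fixture-invented",
            "dw_by_grade": "fixture-invented",
            "dw_failed_implant": "fixture-invented",
            "bilateral_proportion": "fixture-invented",
            "effects.hip.primary.regression": "fixture-invented",
        },
    )
    ps.validate()
    return ps, FixtureSpec()


def generate_cohort(spec: FixtureSpec, ps: ParameterSet, site: str,
                    scale: float, rng: np.random.Generator) -> list:
    """Build a cohort of persons for one site at a given scale in (0, 1].

    Sex counts are the rounded scaled totals (stratum proportions preserved
    within rounding); ages, entry grades and bilateral status are drawn from
    the fixture distributions.  The index (qualifying) joint is joint 0.
    """
    if not 0.0 < scale <= 1.0:
        raise ValueError("scale must lie in (0, 1]")
    if site not in SITES:
        raise ValueError(f"unknown site {site!r}")
    counts = {sex: int(round(n * scale))
              for sex, n in spec.cohort_sizes[site].items()}
    if sum(counts.values()) == 0:
        raise ValueError(f"scale {scale} yields an empty cohort")
    bands = np.array(sorted(spec.age_weights))
    band_p = np.array([spec.age_weights[b] for b in bands], dtype=float)
    band_p /= band_p.sum()
    idx_g = np.array(sorted(spec.index_grade_weights))
    idx_p = np.array([spec.index_grade_weights[g] for g in idx_g], dtype=float)
    idx_p /= idx_p.sum()
    sec_g = np.array(sorted(spec.second_grade_weights))
    sec_p = np.array([spec.second_grade_weights[g] for g in sec_g], dtype=float)
    sec_p /= sec_p.sum()

    persons, pid = [], 0
    for sex in SEXES:
        n = counts[sex]
        band = rng.choice(bands, size=n, p=band_p)
        ages = band + 5.0 * rng.random(n)
        g0 = rng.choice(idx_g, size=n, p=idx_p)
        bilateral = rng.random(n) < ps.bilateral_proportion
        g1 = np.where(bilateral, rng.choice(sec_g, size=n, p=sec_p), 0)
        for i in range(n):
            persons.append(Person(
                pid=pid, sex=sex, age=float(ages[i]), site=site,
                grades=(int(g0[i]), int(g1[i])),
                bg_rate=ps.pyld(sex, float(ages[i])),
            ))
            pid += 1
    return persons


def default_revision_times() -> np.ndarray:
    """Observation grid: half-yearly registry points to 7 y, then sparser
    literature follow-up points to 30 y."""
    return np.concatenate([np.arange(0.5, 7.01, 0.5),
                           np.array([8, 10, 12, 15, 18, 21, 24, 27, 30.0])])


def synthetic_revision_curve(true_mixture: WeibullMixture, times,
                             noise_sd: float,
                             rng: np.random.Generator) -> RevisionObservations:
    """Cumulative revision fractions from a known mixture plus truncated
    noise, re-monotonized; noise_sd = 0 reproduces the exact curve."""
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise ValueError("times must be non-empty")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if noise_sd < 0:
        raise ValueError("noise sd must be non-negative")
    f = mixture_cdf(true_mixture, t)
    if noise_sd > 0:
        f = np.clip(f + rng.normal(0.0, noise_sd, size=t.size), 0.0, 1.0)
        f = np.maximum.accumulate(f)
    return RevisionObservations(times=tuple(t), fractions=tuple(f),
                                provenance="synthetic")


def generate_study_table(n_studies: int, rng: np.random.Generator,
                         true_effect: float = 0.5205,
                         jitter_sd: float = 0.02) -> list:
    """Synthetic pre/post score pairs across instruments with a known pooled
    effect (the mean per-study effect equals ``true_effect`` exactly).

    Emulates a pooled-study structure of one EQ-5D, one HAQ and SF-36-derived
    single indexes; values are invented.
    """
    if n_studies < 1:
        raise ValueError("need at least one study")
    if not 0.05 < true_effect < 0.95:
        raise ValueError("true effect must be comfortably inside (0, 1)")
    jit = rng.normal(0.0, jitter_sd, size=n_studies)
    jit -= jit.mean()                      # mean-preserving study scatter
    jit = np.clip(jit, -0.8 * true_effect, 0.8 * (1.0 - true_effect))
    jit -= jit.mean()
    pairs = []
    for i in range(n_studies):
        e_i = true_effect + jit[i]
        pre_u = 0.25 + 0.3 * rng.random()
        post_u = pre_u + e_i * (1.0 - pre_u)
        if i == 0 and n_studies >= 2:       # one EQ-5D index
            pairs.append(InstrumentScorePair(
                "EQ-5D", "higher_better", 0.0, 1.0, pre_u, post_u))
        elif i == 1 and n_studies >= 3:     # one HAQ index (0-3, higher worse)
            pairs.append(InstrumentScorePair(
                "HAQ", "higher_worse", 0.0, 3.0,
                3.0 * (1.0 - pre_u), 3.0 * (1.0 - post_u)))
        else:                               # SF-36-derived indexes (0-100)
            pairs.append(InstrumentScorePair(
                f"SF-36-{i}", "higher_better", 0.0, 100.0,
                100.0 * pre_u, 100.0 * post_u))
    return pairs
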