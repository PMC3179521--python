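"""Typed parameter model, configuration I/O and second-order sampling.

Every epidemiological, effect and cost parameter of the model lives in a
``ParameterSet`` together with the uncertainty distribution attached to it.
Parameters fall in two classes:

* first-order (individual-level): the time-to-event inputs themselves —
  mortality hazards, OA grade-progression rates, surgical uptake, implant
  failure mixtures.  These describe stochastic variation between individuals
  and are *not* redrawn by the probabilistic sensitivity analysis.
* second-order (population-level): intervention effect sizes and unit costs.
  Each carries a ``DistributionSpec`` (or a regression spec for the hip
  effect) and is redrawn per PSA iteration by :func:`sample_second_order`.

Configuration files are YAML with explicit units in key names; unknown keys
are rejected with the offending field path.
"""
from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import yaml

from .effects import RegressionEffectSpec, effect_from_regression
from .weibull import WeibullMixture

__all__ = [
    "SITES", "SEXES", "OPERATIONS", "AGE_BAND_STARTS", "GRADE_NAMES",
    "Stratum", "DistributionSpec", "EffectSpec", "CostTable", "ParameterSet",
    "ParameterError", "load_parameters", "save_parameters",
    "sample_second_order", "beta_from_moments", "age_band_start",
]

SITES = ("hip", "knee")
SEXES = ("male", "female")
OPERATIONS = ("primary", "revision")
# 5-year bands from 40-44 upward; the 95+ band is open-ended.
AGE_BAND_STARTS = tuple(range(40, 100, 5))
GRADE_NAMES = ("none", "g2_radiological", "g2_symptomatic",
               "g34_asymptomatic", "g34_symptomatic")
# Forward-only transitions of the grade ladder, in order.
TRANSITIONS = ("incidence", "radiological_to_symptomatic",
               "symptomatic_to_advanced", "advanced_to_severe")


class ParameterError(ValueError):
    """Validation failure; the message names the offending field path."""


def age_band_start(age: float) -> int:
    """The 5-year band containing ``age`` (clamped to the 40+ bands)."""
    if age < AGE_BAND_STARTS[0]:
        return AGE_BAND_STARTS[0]
    return min(AGE_BAND_STARTS[-1], int(age // 5) * 5)


@dataclass(frozen=True)
class Stratum:
    sex: str
    age_lo: int

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ParameterError(f"stratum sex must be one of {SEXES}, got {self.sex!r}")
        if self.age_lo not in AGE_BAND_STARTS:
            raise ParameterError(f"stratum age band must start at one of {AGE_BAND_STARTS}")

    @property
    def key(self) -> str:
        return f"{self.sex}.{self.age_lo}"


_FAMILIES = ("point", "normal", "beta", "gamma", "triangular")


@dataclass(frozen=True)
class DistributionSpec:
    """A second-order uncertainty distribution with optional support bounds.

    Families: point(v) | normal(mu, sd) | beta(a, b) | gamma(shape, scale) |
    triangular(low, mode, high).  Sampling re-draws (up to a cap, then clips)
    when a draw lands outside [lower, upper].
    """

    family: str
    params: tuple
    lower: float = -math.inf
    upper: float = math.inf

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ParameterError(f"unsupported distribution family {self.family!r}")
        p = self.params
        need = {"point": 1, "normal": 2, "beta": 2, "gamma": 2, "triangular": 3}
        if len(p) != need[self.family]:
            raise ParameterError(
                f"{self.family} needs {need[self.family]} parameters, got {len(p)}")
        if self.family == "normal" and p[1] < 0:
            raise ParameterError("normal sd must be non-negative")
        if self.family == "beta" and (p[0] <= 0 or p[1] <= 0):
            raise ParameterError("beta shapes must be positive")
        if self.family == "gamma" and (p[0] <= 0 or p[1] <= 0):
            raise ParameterError("gamma shape and scale must be positive")
        if self.family == "triangular" and not (p[0] <= p[1] <= p[2]):
            raise ParameterError("triangular requires low <= mode <= high")
        if not self.lower <= self.upper:
            raise ParameterError("lower bound exceeds upper bound")

    def mean(self) -> float:
        p = self.params
        return {
            "point": lambda: p[0],
            "normal": lambda: p[0],
            "beta": lambda: p[0] / (p[0] + p[1]),
            "gamma": lambda: p[0] * p[1],
            "triangular": lambda: (p[0] + p[1] + p[2]) / 3.0,
        }[self.family]()

    def sd(self) -> float:
        p = self.params
        if self.family == "point":
            return 0.0
        if self.family == "normal":
            return p[1]
        if self.family == "beta":
            a, b = p
            return math.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))
        if self.family == "gamma":
            return p[1] * math.sqrt(p[0])
        low, mode, high = p
        return math.sqrt((low * low + mode * mode + high * high
                          - low * mode - low * high - mode * high) / 18.0)

    def sample(self, rng: np.random.Generator, max_redraw: int = 1000) -> float:
        p = self.params
        if self.family == "point":
            return float(p[0])
        draw = {
            "normal": lambda: rng.normal(p[0], p[1]),
            "beta": lambda: rng.beta(p[0], p[1]),
            "gamma": lambda: rng.gamma(p[0], p[1]),
            "triangular": lambda: rng.triangular(p[0], p[1], p[2]),
        }[self.family]
        for _ in range(max_redraw):
            v = float(draw())
            if self.lower <= v <= self.upper:
                return v
        return float(min(max(v, self.lower), self.upper))

    def to_dict(self) -> dict:
        d = {"family": self.family, "params": list(self.params)}
        if math.isfinite(self.lower):
            d["lower"] = self.lower
        if math.isfinite(self.upper):
            d["upper"] = self.upper
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DistributionSpec":
        return cls(family=d["family"], params=tuple(d["params"]),
                   lower=d.get("lower", -math.inf), upper=d.get("upper", math.inf))


def beta_from_moments(mean: float, sd: float) -> tuple:
    """Beta shape parameters (a, b) matching a given mean and sd.

    Method of moments: nu = mean(1-mean)/sd^2 - 1, a = mean*nu, b = (1-mean)*nu.
    Requires 0 < mean < 1 and sd^2 < mean(1-mean).
    """
    if not 0.0 < mean < 1.0:
        raise ValueError(f"mean must lie strictly in (0, 1), got {mean}")
    var = sd * sd
    bound = mean * (1.0 - mean)
    if not 0.0 < var < bound:
        raise ValueError(
            f"infeasible moments: need 0 < sd^2 < mean(1-mean) = {bound:.6g}, got sd^2 = {var:.6g}")
    nu = bound / var - 1.0
    return mean * nu, (1.0 - mean) * nu


@dataclass(frozen=True)
class EffectSpec:
    """Effect size of an operation on the disability weight, with its
    second-order sampling rule (beta spec or regression spec)."""

    site: str
    operation: str
    sex: str
    mean: float
    sd: float
    ci_low: float
    ci_high: float
    dist: DistributionSpec | None = None
    regression: RegressionEffectSpec | None = None
    value: float | None = None      # PSA draw; None means use the mean

    def __post_init__(self) -> None:
        if not 0.0 < self.mean < 1.0:
            raise ParameterError(
                f"effects.{self.site}.{self.operation}.{self.sex}: mean must lie in (0, 1)")
        if not self.ci_low < self.mean < self.ci_high:
            raise ParameterError(
                f"effects.{self.site}.{self.operation}.{self.sex}: CI must bracket the mean")

    @property
    def key(self) -> str:
        return f"{self.site}.{self.operation}.{self.sex}"

    @property
    def current(self) -> float:
        """The effect value in force: the PSA draw if present, else the mean."""
        return self.mean if self.value is None else self.value

    def sample(self, rng: np.random.Generator) -> float:
        if self.regression is not None:
            return effect_from_regression(self.regression, rng)
        if self.dist is not None:
            return self.dist.sample(rng)
        return self.mean

    def to_dict(self) -> dict:
        d = {"mean": self.mean, "sd": self.sd,
             "ci_low": self.ci_low, "ci_high": self.ci_high}
        if self.value is not None:
            d["value"] = self.value
        if self.dist is not None:
            d["dist"] = self.dist.to_dict()
        if self.regression is not None:
            d["regression"] = self.regression.to_dict()
        return d


# Cost-class keys: "<op>.<cscc|nocscc>"
COST_CLASSES = ("primary.nocscc", "primary.cscc", "revision.nocscc", "revision.cscc")


def cost_class(op: str, cscc: bool) -> str:
    return f"{op}.{'cscc' if cscc else 'nocscc'}"


@dataclass
class CostTable:
    """Unit costs per surgery and annual expenditure rates, AUD 2003.

    ``government`` is keyed "<site>.<op>.<cscc|nocscc>";
    ``time_recuperation`` is keyed "<site>.<sex>.<op>.<cscc|nocscc>".
    """

    government: dict
    other_surgery: float
    out_of_pocket: dict                   # site -> AUD per surgery episode
    time_pre_visit: dict                  # site -> AUD per surgery episode
    time_recuperation: dict
    oa_annual_expenditure: float          # AUD per affected joint-year (offset)
    unrelated_annual_expenditure: dict    # "sex.age_lo" -> AUD per person-year

    def validate(self) -> None:
        for site in SITES:
            for cc in COST_CLASSES:
                k = f"{site}.{cc}"
                if k not in self.government:
                    raise ParameterError(f"costs.government.{k}: missing")
                if self.government[k] < 0:
                    raise ParameterError(f"costs.government.{k}: negative amount")
            if self.government[f"{site}.revision.cscc"] < self.government[f"{site}.primary.nocscc"]:
                raise ParameterError(
                    f"costs.government.{site}: revision+Cscc must cost at least primary-Cscc")
            for name, d in (("out_of_pocket", self.out_of_pocket),
                            ("time_pre_visit", self.time_pre_visit)):
                if site not in d:
                    raise ParameterError(f"costs.{name}.{site}: missing")
                if d[site] < 0:
                    raise ParameterError(f"costs.{name}.{site}: negative amount")
            for sex in SEXES:
                for cc in COST_CLASSES:
                    k = f"{site}.{sex}.{cc}"
                    if k not in self.time_recuperation:
                        raise ParameterError(f"costs.time_recuperation.{k}: missing")
                    if self.time_recuperation[k] < 0:
                        raise ParameterError(f"costs.time_recuperation.{k}: negative amount")
        if self.other_surgery < 0 or self.oa_annual_expenditure < 0:
            raise ParameterError("costs: amounts must be non-negative")
        for k, v in self.unrelated_annual_expenditure.items():
            if v < 0:
                raise ParameterError(f"costs.unrelated_annual_expenditure.{k}: negative amount")


@dataclass
class ParameterSet:
    """Complete model parameterisation (see module docstring)."""

    mortality_hazard: dict            # "sex.age_lo" -> annual rate
    oa_mortality_rr: float
    grade_progression: dict           # site -> {transition -> annual rate}
    bilateral_proportion: float
    surgical_uptake_rate: dict        # site -> annual rate among severe symptomatic
    surgical_death_prob: float
    complication_prob: dict           # op -> probability
    implant_failure: dict             # site -> WeibullMixture
    dw_by_grade: dict                 # grade name -> disability weight
    dw_failed_implant: dict           # site -> disability weight of a failed implant
    effects: dict                     # "site.op.sex" -> EffectSpec
    costs: CostTable
    discount_rate: float
    pyld_rate: dict                   # "sex.age_lo" -> background comorbid dw rate
    rr_reverts_after_replacement: bool = True
    cost_uncertainty: dict = field(default_factory=dict)  # path -> DistributionSpec
    provenance: dict = field(default_factory=dict)        # path -> source tag

    # -- lookups ---------------------------------------------------------
    def mortality(self, sex: str, age: float) -> float:
        return self.mortality_hazard[f"{sex}.{age_band_start(age)}"]

    def pyld(self, sex: str, age: float) -> float:
        return self.pyld_rate[f"{sex}.{age_band_start(age)}"]

    def unrelated(self, sex: str, age: float) -> float:
        return self.costs.unrelated_annual_expenditure[f"{sex}.{age_band_start(age)}"]

    def effect_value(self, site: str, op: str, sex: str) -> float:
        return self.effects[f"{site}.{op}.{sex}"].current

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        for table, name, lo, hi in (
            (self.mortality_hazard, "mortality_hazard", 0.0, math.inf),
            (self.pyld_rate, "pyld_rate", 0.0, 1.0),
        ):
            for sex in SEXES:
                for a in AGE_BAND_STARTS:
                    k = f"{sex}.{a}"
                    if k not in table:
                        raise ParameterError(f"{name}.{k}: missing")
                    if not lo <= table[k] <= hi:
                        raise ParameterError(f"{name}.{k}: value {table[k]} out of range")
        if self.oa_mortality_rr < 0:
            raise ParameterError("oa_mortality_rr: must be non-negative")
        if not 0.0 <= self.bilateral_proportion <= 1.0:
            raise ParameterError("bilateral_proportion: must lie in [0, 1]")
        if not 0.0 <= self.surgical_death_prob <= 1.0:
            raise ParameterError("surgical_death_prob: must lie in [0, 1]")
        for op in OPERATIONS:
            if op not in self.complication_prob:
                raise ParameterError(f"complication_prob.{op}: missing")
            if not 0.0 <= self.complication_prob[op] <= 1.0:
                raise ParameterError(f"complication_prob.{op}: must lie in [0, 1]")
        for site in SITES:
            if site not in self.grade_progression:
                raise ParameterError(f"grade_progression.{site}: missing")
            for tr in TRANSITIONS:
                if tr not in self.grade_progression[site]:
                    raise ParameterError(f"grade_progression.{site}.{tr}: missing")
                if self.grade_progression[site][tr] < 0:
                    raise ParameterError(f"grade_progression.{site}.{tr}: negative rate")
            if site not in self.surgical_uptake_rate or self.surgical_uptake_rate[site] < 0:
                raise ParameterError(f"surgical_uptake_rate.{site}: missing or negative")
            if site not in self.implant_failure:
                raise ParameterError(f"implant_failure.{site}: missing")
            if not 0.0 <= self.dw_failed_implant.get(site, -1.0) <= 1.0:
                raise ParameterError(f"dw_failed_implant.{site}: must lie in [0, 1]")
        for g in GRADE_NAMES:
            if g not in self.dw_by_grade:
                raise ParameterError(f"dw_by_grade.{g}: missing")
            if not 0.0 <= self.dw_by_grade[g] <= 1.0:
                raise ParameterError(f"dw_by_grade.{g}: must lie in [0, 1]")
        for site in SITES:
            for op in OPERATIONS:
                for sex in SEXES:
                    k = f"{site}.{op}.{sex}"
                    if k not in self.effects:
                        raise ParameterError(f"effects.{k}: missing")
        if not 0.0 <= self.discount_rate < 1.0:
            raise ParameterError("discount_rate: must lie in [0, 1)")
        self.costs.validate()


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------

_TOP_KEYS = {
    "mortality_hazard", "oa_mortality_rr", "grade_progression",
    "bilateral_proportion", "surgical_uptake_rate", "surgical_death_prob",
    "complication_prob", "implant_failure", "dw_by_grade", "dw_failed_implant",
    "effects", "costs", "discount_rate", "pyld_rate",
    "rr_reverts_after_replacement", "cost_uncertainty", "provenance",
}
_COST_KEYS = {
    "government", "other_surgery", "out_of_pocket", "time_pre_visit",
    "time_recuperation", "oa_annual_expenditure", "unrelated_annual_expenditure",
}


def to_dict(ps: ParameterSet) -> dict:
    return {
        "mortality_hazard": dict(ps.mortality_hazard),
        "oa_mortality_rr": ps.oa_mortality_rr,
        "grade_progression": {s: dict(v) for s, v in ps.grade_progression.items()},
        "bilateral_proportion": ps.bilateral_proportion,
        "surgical_uptake_rate": dict(ps.surgical_uptake_rate),
        "surgical_death_prob": ps.surgical_death_prob,
        "complication_prob": dict(ps.complication_prob),
        "implant_failure": {s: m.to_dict() for s, m in ps.implant_failure.items()},
        "dw_by_grade": dict(ps.dw_by_grade),
        "dw_failed_implant": dict(ps.dw_failed_implant),
        "effects": {k: v.to_dict() for k, v in ps.effects.items()},
        "costs": {
            "government": dict(ps.costs.government),
            "other_surgery": ps.costs.other_surgery,
            "out_of_pocket": dict(ps.costs.out_of_pocket),
            "time_pre_visit": dict(ps.costs.time_pre_visit),
            "time_recuperation": dict(ps.costs.time_recuperation),
            "oa_annual_expenditure": ps.costs.oa_annual_expenditure,
            "unrelated_annual_expenditure": dict(ps.costs.unrelated_annual_expenditure),
        },
        "discount_rate": ps.discount_rate,
        "pyld_rate": dict(ps.pyld_rate),
        "rr_reverts_after_replacement": ps.rr_reverts_after_replacement,
        "cost_uncertainty": {k: v.to_dict() for k, v in ps.cost_uncertainty.items()},
        "provenance": dict(ps.provenance),
    }


def from_dict(d: dict) -> ParameterSet:
    unknown = set(d) - _TOP_KEYS
    if unknown:
        raise ParameterError(f"unknown configuration keys: {sorted(unknown)}")
    missing = _TOP_KEYS - set(d) - {"rr_reverts_after_replacement",
                                    "cost_uncertainty", "provenance"}
    if missing:
        raise ParameterError(f"missing configuration keys: {sorted(missing)}")
    unknown_cost = set(d["costs"]) - _COST_KEYS
    if unknown_cost:
        raise ParameterError(f"unknown keys under costs: {sorted(unknown_cost)}")

    def eff(key: str, e: dict) -> EffectSpec:
        site, op, sex = key.split(".")
        return EffectSpec(
            site=site, operation=op, sex=sex,
            mean=float(e["mean"]), sd=float(e["sd"]),
            ci_low=float(e["ci_low"]), ci_high=float(e["ci_high"]),
            value=float(e["value"]) if "value" in e else None,
            dist=DistributionSpec.from_dict(e["dist"]) if "dist" in e else None,
            regression=RegressionEffectSpec.from_dict(e["regression"])
            if "regression" in e else None,
        )

    ps = ParameterSet(
        mortality_hazard={k: float(v) for k, v in d["mortality_hazard"].items()},
        oa_mortality_rr=float(d["oa_mortality_rr"]),
        grade_progression={s: {t: float(r) for t, r in v.items()}
                           for s, v in d["grade_progression"].items()},
        bilateral_proportion=float(d["bilateral_proportion"]),
        surgical_uptake_rate={k: float(v) for k, v in d["surgical_uptake_rate"].items()},
        surgical_death_prob=float(d["surgical_death_prob"]),
        complication_prob={k: float(v) for k, v in d["complication_prob"].items()},
        implant_failure={s: WeibullMixture.from_dict(m)
                         for s, m in d["implant_failure"].items()},
        dw_by_grade={k: float(v) for k, v in d["dw_by_grade"].items()},
        dw_failed_implant={k: float(v) for k, v in d["dw_failed_implant"].items()},
        effects={k: eff(k, v) for k, v in d["effects"].items()},
        costs=CostTable(
            government={k: float(v) for k, v in d["costs"]["government"].items()},
            other_surgery=float(d["costs"]["other_surgery"]),
            out_of_pocket={k: float(v) for k, v in d["costs"]["out_of_pocket"].items()},
            time_pre_visit={k: float(v) for k, v in d["costs"]["time_pre_visit"].items()},
            time_recuperation={k: float(v)
                               for k, v in d["costs"]["time_recuperation"].items()},
            oa_annual_expenditure=float(d["costs"]["oa_annual_expenditure"]),
            unrelated_annual_expenditure={
                k: float(v)
                for k, v in d["costs"]["unrelated_annual_expenditure"].items()},
        ),
        discount_rate=float(d["discount_rate"]),
        pyld_rate={k: float(v) for k, v in d["pyld_rate"].items()},
        rr_reverts_after_replacement=bool(d.get("rr_reverts_after_replacement", True)),
        cost_uncertainty={k: DistributionSpec.from_dict(v)
                          for k, v in d.get("cost_uncertainty", {}).items()},
        provenance=dict(d.get("provenance", {})),
    )
    ps.validate()
    return ps


def load_parameters(path) -> ParameterSet:
    """Read and validate a parameter configuration from a YAML file."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"parameter file not found: {p}")
    with open(p) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ParameterError(f"{p}: configuration root must be a mapping")
    return from_dict(raw)


def save_parameters(ps: ParameterSet, path) -> None:
    ps.validate()
    with open(path, "w") as fh:
        yaml.safe_dump(to_dict(ps), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Second-order sampling
# ---------------------------------------------------------------------------

def _set_cost_path(costs: CostTable, path: str, value: float) -> None:
    head, _, rest = path.partition(".")
    if head == "other_surgery":
        costs.other_surgery = value
    elif head == "oa_annual_expenditure":
        costs.oa_annual_expenditure = value
    elif head in ("government", "out_of_pocket", "time_pre_visit",
                  "time_recuperation", "unrelated_annual_expenditure"):
        table = getattr(costs, head)
        if rest not in table:
            raise ParameterError(f"cost_uncertainty targets unknown item costs.{path}")
        table[rest] = value
    else:
        raise ParameterError(f"cost_uncertainty targets unknown field costs.{path}")


def sample_second_order(ps: ParameterSet, rng: np.random.Generator) -> ParameterSet:
    """One PSA draw: a new ParameterSet with effects and costs redrawn.

    First-order fields (mortality, progression, uptake, implant-failure
    mixtures) are carried over unchanged.  Effect draws outside (0, 1) are
    handled by each spec's support bounds; the drawn value replaces the
    spec's mean so downstream consumers read it uniformly.
    """
    out = copy.deepcopy(ps)
    for key in sorted(out.effects):
        spec = out.effects[key]
        v = spec.sample(rng)
        out.effects[key] = replace(spec, value=min(max(v, 0.0), 1.0))
    for path in sorted(out.cost_uncertainty):
        _set_cost_path(out.costs, path, out.cost_uncertainty[path].sample(rng))
    return out
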