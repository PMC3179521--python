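"""Discrete-event lifetime simulation of persons with two joints.

Each simulated individual carries two joints (left/right hip or knee) whose
osteoarthritis severity advances along a forward-only grade ladder

    none -> grade-2 radiological -> grade-2 symptomatic
         -> grade-3/4 asymptomatic -> grade-3/4 symptomatic,

with exponential waiting times per rung.  In the intervention arm a joint
reaching severe symptomatic OA draws an exponential time to the decision for
primary replacement; each operation may end in surgical death (Bernoulli),
otherwise a complication Bernoulli determines the cost class, the joint's
disability weight drops by the intervention effect, and an implant-failure
time is drawn from the site's Weibull mixture.  A failed implant enters a
failed state and is revised immediately; the surgery/failure cycle repeats
for life.  The comparator arm ('doing nothing') never operates.

Background mortality is a piecewise-constant hazard over 5-year age bands,
multiplied by the OA relative risk (1.1) while any joint has untreated
symptomatic-or-worse OA; after the last affected joint receives a functioning
implant the multiplier reverts to 1.0 (intervention arm only), which is the
mechanism for extended life-years.  Ties are broken in the order
death > operation > failure > progression.

Both arms of a person consume a single pre-drawn set of uniforms (common
random numbers), so the arm difference isolates the intervention.  The two
joints' time-to-event uniforms can be correlated through a Gaussian copula
for sensitivity analysis.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

from .params import ParameterSet, Stratum, age_band_start, AGE_BAND_STARTS, GRADE_NAMES
from .weibull import sample_failure_time

__all__ = [
    "GRADE_NONE", "GRADE_G2_RAD", "GRADE_G2_SYMP", "GRADE_G34_ASYMP",
    "GRADE_G34_SYMP", "STATE_POST_PRIMARY", "STATE_FAILED",
    "STATE_POST_REVISION", "STATE_DEAD", "N_STATES",
    "Person", "EngineConfig", "PersonDraws", "OpRecord", "LifeHistory",
    "sample_event_time", "correlated_uniform_pair", "draw_person_uniforms",
    "simulate_person", "simulate_pair", "simulate_cohort",
    "replacement_distribution", "events_table",
]

# Joint-state encoding: grades occupy 0..4; implant states follow.
GRADE_NONE, GRADE_G2_RAD, GRADE_G2_SYMP, GRADE_G34_ASYMP, GRADE_G34_SYMP = range(5)
STATE_POST_PRIMARY = 5
STATE_FAILED = 6
STATE_POST_REVISION = 7
STATE_DEAD = 8          # person-level, used by the outcome accounting
N_STATES = 9

MAX_OPS_PER_JOINT = 16   # draw-array size; unreachable under realistic inputs

_EPS_U = 1e-12


@dataclass(frozen=True)
class Person:
    """A cohort member at model entry (age is continuous years)."""

    pid: int
    sex: str
    age: float
    site: str
    grades: tuple          # entry OA grade per joint, (joint0, joint1)
    bg_rate: float         # comorbid background disability rate (PYLD-derived)

    def __post_init__(self) -> None:
        if max(self.grades) < GRADE_G2_SYMP:
            raise ValueError(
                f"person {self.pid}: entry requires at least one joint at "
                "grade-2 symptomatic or grade-3/4 OA")

    @property
    def stratum(self) -> Stratum:
        return Stratum(self.sex, age_band_start(self.age))


@dataclass(frozen=True)
class EngineConfig:
    joint_correlation: float = 0.0
    unilateral_restriction: bool = False
    seed: int = 0
    max_ops: int = MAX_OPS_PER_JOINT

    def __post_init__(self) -> None:
        if not -0.99 <= self.joint_correlation <= 0.99:
            raise ValueError("joint correlation must lie in [-0.99, 0.99]")


@dataclass
class PersonDraws:
    """One person's pre-drawn randomness, shared by both arms (CRN).

    ``prog``, ``decide`` and ``fail`` are joint-indexed and copula-correlated
    across the two joints; ``surg_death`` and ``compl`` are independent.
    """

    death_exp: float          # Exp(1) threshold for the background hazard
    prog: np.ndarray          # (2, 4) uniforms, one per ladder transition
    decide: np.ndarray        # (2,)  uniforms for time-to-surgery-decision
    surg_death: np.ndarray    # (2, K)
    compl: np.ndarray         # (2, K)
    fail: np.ndarray          # (2, K)


@dataclass(frozen=True)
class OpRecord:
    time: float
    joint: int
    kind: str          # "primary" | "revision"
    cscc: bool
    fatal: bool
    age: float


@dataclass
class LifeHistory:
    """Timestamped record of one person's simulated life under one arm.

    ``joint_segments[j]`` is a list of (start_time, state) pairs; the state
    in force at time t is the last entry with start_time <= t.  States are
    the integer codes of this module.
    """

    pid: int
    arm: str
    sex: str
    site: str
    entry_age: float
    bg_rate: float
    death_time: float
    death_cause: str                    # "background" | "surgical"
    joint_segments: tuple               # (list, list)
    operations: list = field(default_factory=list)


def sample_event_time(hazard, u: float) -> float:
    """Inverse-CDF draw of a time-to-event from a hazard specification.

    ``hazard`` is either a constant annual rate (exponential waiting time,
    t = -ln(1-u)/rate) or a piecewise-constant specification as a sequence of
    (start_time, rate) pairs beginning at time 0, integrated exactly.  A
    hazard of zero everywhere returns +inf (the event never occurs).
    """
    if not (0.0 < u < 1.0):
        raise ValueError(f"u must lie strictly in (0, 1), got {u}")
    target = -math.log1p(-u)           # cumulative hazard to spend
    if np.isscalar(hazard):
        rate = float(hazard)
        if rate < 0:
            raise ValueError("hazard rate must be non-negative")
        return target / rate if rate > 0 else math.inf
    pieces = list(hazard)
    if not pieces or pieces[0][0] != 0.0:
        raise ValueError("piecewise hazard must start at time 0")
    for i, (t0, rate) in enumerate(pieces):
        if rate < 0:
            raise ValueError("hazard rates must be non-negative")
        t1 = pieces[i + 1][0] if i + 1 < len(pieces) else math.inf
        if t1 <= t0:
            raise ValueError("piecewise hazard times must be increasing")
        chunk = rate * (t1 - t0) if math.isfinite(t1) else (math.inf if rate > 0 else 0.0)
        if target <= chunk:
            return t0 + target / rate if rate > 0 else math.inf
        target -= chunk
    return math.inf


def correlated_uniform_pair(rho: float, rng: np.random.Generator, size=None):
    """Gaussian-copula uniform pair with normal-score correlation ``rho``.

    Each margin is uniform(0, 1); the rank (Spearman) correlation equals
    (6/pi) * arcsin(rho/2).
    """
    if not -0.99 <= rho <= 0.99:
        raise ValueError("correlation must lie in [-0.99, 0.99]")
    shape = () if size is None else (size,)
    z1 = rng.standard_normal(shape)
    z2 = rho * z1 + math.sqrt(1.0 - rho * rho) * rng.standard_normal(shape)
    u1 = np.clip(ndtr(z1), _EPS_U, 1.0 - _EPS_U)
    u2 = np.clip(ndtr(z2), _EPS_U, 1.0 - _EPS_U)
    return (float(u1), float(u2)) if size is None else (u1, u2)


def draw_person_uniforms(rng: np.random.Generator, rho: float = 0.0,
                         max_ops: int = MAX_OPS_PER_JOINT) -> PersonDraws:
    """Pre-draw one person's full uniform budget (both arms share it)."""
    death_exp = float(rng.exponential())
    m = 4 + 1 + max_ops                  # prog + decide + fail slots
    z1 = rng.standard_normal(m)
    z2 = rho * z1 + math.sqrt(1.0 - rho * rho) * rng.standard_normal(m)
    u = np.clip(ndtr(np.stack([z1, z2])), _EPS_U, 1.0 - _EPS_U)
    surg_death = rng.random((2, max_ops))
    compl = rng.random((2, max_ops))
    return PersonDraws(
        death_exp=death_exp,
        prog=u[:, :4].copy(),
        decide=u[:, 4].copy(),
        fail=u[:, 5:].copy(),
        surg_death=surg_death,
        compl=compl,
    )


def _waiting_time(rate: float, u: float) -> float:
    return -math.log1p(-u) / rate if rate > 0 else math.inf


class _MortalityClock:
    """Background-mortality bookkeeping under a piecewise age hazard whose
    multiplier (the OA relative risk) may change at event times.

    A single Exp(1) threshold is drawn per person; death occurs when the
    accumulated hazard integral reaches it, so the death time responds
    deterministically to multiplier changes (common random numbers)."""

    def __init__(self, ps: ParameterSet, sex: str, age0: float, threshold: float):
        self.sex = sex
        self.age0 = age0
        self.remaining = threshold
        self.t_last = 0.0
        self.rates = {a: ps.mortality_hazard[f"{sex}.{a}"] for a in AGE_BAND_STARTS}

    def _integral(self, t0: float, t1: float, rr: float) -> float:
        """Hazard integral over [t0, t1] at multiplier rr (t in model years)."""
        total, t = 0.0, t0
        while t < t1:
            band = age_band_start(self.age0 + t)
            if band == AGE_BAND_STARTS[-1]:
                t_next = t1
            else:
                t_next = min(t1, band + 5 - self.age0)
            total += rr * self.rates[band] * (t_next - t)
            t = t_next
        return total

    def advance(self, t: float, rr: float) -> None:
        """Consume hazard over [t_last, t] at multiplier rr."""
        if t > self.t_last:
            self.remaining -= self._integral(self.t_last, t, rr)
            self.t_last = t

    def death_time(self, rr: float) -> float:
        """Tentative death time assuming multiplier rr from t_last onward."""
        rem, t = self.remaining, self.t_last
        while True:
            band = age_band_start(self.age0 + t)
            rate = rr * self.rates[band]
            if band == AGE_BAND_STARTS[-1]:
                return t + rem / rate if rate > 0 else math.inf
            t_next = band + 5 - self.age0
            chunk = rate * (t_next - t)
            if rem <= chunk:
                return t + rem / rate if rate > 0 else math.inf
            rem -= chunk
            t = t_next


def _simulate_arm(person: Person, ps: ParameterSet, cfg: EngineConfig,
                  d: PersonDraws, arm: str) -> LifeHistory:
    intervention = arm == "intervention"
    site, sex = person.site, person.sex
    prog_rates = [ps.grade_progression[site][tr]
                  for tr in ("incidence", "radiological_to_symptomatic",
                             "symptomatic_to_advanced", "advanced_to_severe")]
    uptake = ps.surgical_uptake_rate[site]
    mix = ps.implant_failure[site]

    grades = list(person.grades)
    frozen = [False, False]
    if cfg.unilateral_restriction:
        grades[1] = GRADE_NONE
        frozen[1] = True

    segments = ([(0.0, grades[0])], [(0.0, grades[1])])
    implanted = [False, False]
    ops_used = [0, 0]
    next_prog = [math.inf, math.inf]
    op_time = [math.inf, math.inf]       # scheduled primary operations
    fail_time = [math.inf, math.inf]
    operations: list[OpRecord] = []

    for j in (0, 1):
        if not frozen[j] and grades[j] < GRADE_G34_SYMP:
            next_prog[j] = _waiting_time(prog_rates[grades[j]], d.prog[j, grades[j]])
        if intervention and grades[j] == GRADE_G34_SYMP:
            op_time[j] = _waiting_time(uptake, d.decide[j])

    def burdened(j: int) -> bool:
        return not implanted[j] and grades[j] >= GRADE_G2_SYMP

    def current_rr() -> float:
        if ps.oa_mortality_rr == 1.0:
            return 1.0
        if not ps.rr_reverts_after_replacement:
            return ps.oa_mortality_rr
        return ps.oa_mortality_rr if (burdened(0) or burdened(1)) else 1.0

    clock = _MortalityClock(ps, sex, person.age, d.death_exp)
    rr = current_rr()

    def refresh_rr(t: float) -> None:
        nonlocal rr
        new = current_rr()
        if new != rr:
            clock.advance(t, rr)
            rr = new

    def operate(j: int, t: float, kind: str):
        """Returns the death time if the operation is fatal, else None."""
        nonlocal rr
        k = ops_used[j]
        if k >= cfg.max_ops:
            fail_time[j] = math.inf     # cap reached: implant lasts for life
            return None
        ops_used[j] = k + 1
        fatal = d.surg_death[j, k] < ps.surgical_death_prob
        if fatal:
            # A fatal operation is costed at the +Cscc class of its kind.
            operations.append(OpRecord(t, j, kind, True, True, person.age + t))
            return t
        cscc = d.compl[j, k] < ps.complication_prob[kind]
        operations.append(OpRecord(t, j, kind, cscc, False, person.age + t))
        implanted[j] = True
        state = STATE_POST_PRIMARY if kind == "primary" else STATE_POST_REVISION
        segments[j].append((t, state))
        next_prog[j] = math.inf
        op_time[j] = math.inf
        fail_time[j] = t + sample_failure_time(mix, d.fail[j, k])
        refresh_rr(t)
        return None

    death_time, death_cause = math.inf, "background"
    while True:
        td = clock.death_time(rr)
        # Candidate events with tie-break priority death > operation >
        # failure > progression (lower priority number wins ties).
        best = (td, 0, "death", -1)
        for j in (0, 1):
            if op_time[j] < math.inf:
                c = (op_time[j], 1, "operation", j)
                if c < best:
                    best = c
            if fail_time[j] < math.inf:
                c = (fail_time[j], 2, "failure", j)
                if c < best:
                    best = c
            if next_prog[j] < math.inf:
                c = (next_prog[j], 3, "progression", j)
                if c < best:
                    best = c
        t, _, kind, j = best

        if kind == "death":
            death_time, death_cause = t, "background"
            break
        if kind == "operation":
            fatal_at = operate(j, t, "primary")
            if fatal_at is not None:
                death_time, death_cause = fatal_at, "surgical"
                break
        elif kind == "failure":
            implanted[j] = False
            segments[j].append((t, STATE_FAILED))
            fail_time[j] = math.inf
            # Failed implants are revised immediately (no waiting list).
            fatal_at = operate(j, t, "revision")
            if fatal_at is not None:
                refresh_rr(t)      # failed joint counts as burdened again
                death_time, death_cause = fatal_at, "surgical"
                break
        else:  # progression
            grades[j] += 1
            segments[j].append((t, grades[j]))
            if grades[j] < GRADE_G34_SYMP:
                next_prog[j] = t + _waiting_time(prog_rates[grades[j]],
                                                 d.prog[j, grades[j]])
            else:
                next_prog[j] = math.inf
                if intervention:
                    op_time[j] = t + _waiting_time(uptake, d.decide[j])
            refresh_rr(t)

    return LifeHistory(
        pid=person.pid, arm=arm, sex=sex, site=site, entry_age=person.age,
        bg_rate=person.bg_rate, death_time=death_time, death_cause=death_cause,
        joint_segments=segments, operations=operations,
    )


def simulate_person(person: Person, ps: ParameterSet, cfg: EngineConfig,
                    draws: PersonDraws, arm: str = "intervention") -> LifeHistory:
    """Simulate one person under one arm from pre-drawn uniforms."""
    if arm not in ("intervention", "comparator"):
        raise ValueError(f"unknown arm {arm!r}")
    return _simulate_arm(person, ps, cfg, draws, arm)


def simulate_pair(person: Person, ps: ParameterSet, cfg: EngineConfig,
                  draws: PersonDraws):
    """Both arms under common random numbers: (intervention, comparator)."""
    return (_simulate_arm(person, ps, cfg, draws, "intervention"),
            _simulate_arm(person, ps, cfg, draws, "comparator"))


def simulate_cohort(persons, ps: ParameterSet, cfg: EngineConfig):
    """Simulate every person under both arms with per-person substreams.

    The substream for person i is keyed by (cfg.seed, pid), so histories are
    reproducible and independent of cohort order.
    """
    pairs = []
    for p in persons:
        rng = np.random.default_rng([cfg.seed, p.pid])
        d = draw_person_uniforms(rng, cfg.joint_correlation, cfg.max_ops)
        pairs.append(simulate_pair(p, ps, cfg, d))
    return pairs


def replacement_distribution(histories) -> "pd.DataFrame":
    """Operation counts and proportions by sex/age band at operation time.

    Used for the internal-consistency check against registry proportions.
    """
    import pandas as pd

    rows = []
    for h in histories:
        for op in h.operations:
            rows.append((h.sex, age_band_start(op.age)))
    if not rows:
        return pd.DataFrame(columns=["sex", "age_lo", "count", "proportion"])
    df = pd.DataFrame(rows, columns=["sex", "age_lo"])
    out = df.value_counts(["sex", "age_lo"]).rename("count").reset_index()
    out["proportion"] = out["count"] / out["count"].sum()
    return out.sort_values(["sex", "age_lo"]).reset_index(drop=True)


def events_table(histories) -> "pd.DataFrame":
    """Tidy event log across histories (one row per state change/operation)."""
    import pandas as pd

    state_names = list(GRADE_NAMES) + ["post_primary", "failed", "post_revision"]
    rows = []
    for h in histories:
        for j in (0, 1):
            for t, s in h.joint_segments[j]:
                rows.append((h.pid, h.arm, t, "state", j, state_names[s]))
        for op in h.operations:
            label = f"{op.kind}{'+cscc' if op.cscc else '-cscc'}"
            if op.fatal:
                label += ",fatal"
            rows.append((h.pid, h.arm, op.time, "operation", op.joint, label))
        rows.append((h.pid, h.arm, h.death_time, "death", -1, h.death_cause))
    return pd.DataFrame(
        rows, columns=["person", "arm", "time", "event", "joint", "detail"]
    ).sort_values(["person", "arm", "time"]).reset_index(drop=True)
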