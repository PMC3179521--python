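"""Probabilistic sensitivity analysis: outer Monte Carlo over parameter draws.

Each iteration redraws the second-order (population-level) parameters —
intervention effect sizes and unit costs — and re-evaluates population totals
for every scenario.  First-order (individual-level) randomness is *not*
resampled across iterations: the cohort is simulated once under common random
numbers and each iteration re-prices the same event histories, which isolates
parameter uncertainty exactly as the first/second-order split of the
uncertainty table prescribes.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import EngineConfig, simulate_cohort
from .outcomes import (PairedOutcomeData, ScenarioFlags, SCENARIO_GRID, icer)
from .params import ParameterSet, sample_second_order

__all__ = ["PsaRun", "PsaSummary", "run_psa", "ce_plane_export"]

DEFAULT_THRESHOLD = 50_000.0      # AUD per DALY averted


@dataclass(frozen=True)
class PsaRun:
    n_iterations: int = 2000
    seed: int = 0
    scenarios: tuple = SCENARIO_GRID
    joint_correlation: float = 0.0
    unilateral_restriction: bool = False

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be at least 1")


@dataclass
class PsaSummary:
    """Per-iteration records plus derived scenario summaries."""

    records: pd.DataFrame           # scenario, iteration, delta_cost, dalys_averted
    n_persons: int
    summary: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        rows = []
        for label, g in self.records.groupby("scenario", sort=False):
            cost, daly = g["delta_cost"].to_numpy(), g["dalys_averted"].to_numpy()
            with np.errstate(divide="ignore", invalid="ignore"):
                ratios = np.where(daly != 0.0, cost / daly, np.nan)
            rows.append({
                "scenario": label,
                "cost_mean": cost.mean(),
                "cost_lo": np.percentile(cost, 2.5),
                "cost_hi": np.percentile(cost, 97.5),
                "daly_mean": daly.mean(),
                "daly_lo": np.percentile(daly, 2.5),
                "daly_hi": np.percentile(daly, 97.5),
                "icer_mean_of_ratios": np.nanmean(ratios),
                "icer_lo": np.nanpercentile(ratios, 2.5),
                "icer_hi": np.nanpercentile(ratios, 97.5),
                "icer_ratio_of_means": icer(cost.mean(), daly.mean()).value,
            })
        self.summary = pd.DataFrame(rows)


def run_psa(persons, ps: ParameterSet, run: PsaRun) -> PsaSummary:
    """Simulate the cohort once, then price it under ``run.n_iterations``
    second-order parameter draws for every scenario.

    Reproducible given ``run.seed``; the first-order substream is derived
    from the same seed so repeated calls are bit-identical.
    """
    ps.validate()
    if not persons:
        raise ValueError("empty cohort")
    cfg = EngineConfig(joint_correlation=run.joint_correlation,
                       unilateral_restriction=run.unilateral_restriction,
                       seed=run.seed)
    pairs = simulate_cohort(persons, ps, cfg)
    data = PairedOutcomeData(pairs, ps, ps.discount_rate)

    rng = np.random.default_rng([run.seed, 2_000_003])   # second-order stream
    records = []
    for it in range(run.n_iterations):
        ps_i = sample_second_order(ps, rng)
        daly = data.total_dalys_averted(ps_i)
        for flags in run.scenarios:
            cost = data.total_cost(ps_i, flags)
            records.append((flags.label, it, cost, daly))
    df = pd.DataFrame(records,
                      columns=["scenario", "iteration", "delta_cost", "dalys_averted"])
    return PsaSummary(records=df, n_persons=len(persons))


def ce_plane_export(summary: PsaSummary,
                    threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Cost-effectiveness-plane points: one row per iteration per scenario.

    ``below_threshold`` is inclusive at the boundary (an iteration whose ICER
    equals the willingness-to-pay threshold counts as acceptable).
    """
    df = summary.records.copy()
    df["below_threshold"] = df["delta_cost"] <= threshold * df["dalys_averted"]
    return df[["scenario", "iteration", "dalys_averted", "delta_cost",
               "below_threshold"]]
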