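"""Cross-walk from instrument scores to disability-weight effect sizes.

Joint-replacement efficacy is reported in the literature on many instruments
(EQ-5D, HAQ, SF-36-derived single indexes) but never directly on the DALY
disability weight.  The cross-walk assumes that the *relative* improvement in
residual health deficit is instrument-invariant: after mapping every score to
the unit interval oriented higher-is-better,

    Effect  = (score_post - score_pre) / (1 - score_pre)
    DW_post = DW_pre * (1 - Effect)

so a joint that recovers a fraction ``Effect`` of its residual deficit on any
instrument loses the same fraction of its disability weight.  Pooled effects
come either from a non-parametric bootstrap over primary studies (knee) or
from sampled regression coefficients predicting pre/post scores (hip).
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "InstrumentScorePair",
    "EffectSummary",
    "RegressionEffectSpec",
    "normalize_score",
    "effect_from_scores",
    "dw_post",
    "pooled_effect_bootstrap",
    "effect_from_regression",
]


@dataclass(frozen=True)
class InstrumentScorePair:
    """Pre/post scores from one study index on its native instrument scale."""

    instrument: str
    orientation: str            # "higher_better" | "higher_worse"
    range_min: float
    range_max: float
    pre: float
    post: float
    n: int | None = None        # source-study sample size, informational

    def __post_init__(self) -> None:
        if self.orientation not in ("higher_better", "higher_worse"):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if not self.range_min < self.range_max:
            raise ValueError("instrument range must satisfy min < max")
        for label, s in (("pre", self.pre), ("post", self.post)):
            if not (self.range_min <= s <= self.range_max):
                raise ValueError(
                    f"{label} score {s} outside declared range "
                    f"[{self.range_min}, {self.range_max}] for {self.instrument}"
                )


@dataclass(frozen=True)
class EffectSummary:
    """Pooled effect size: mean, sd, percentile 95% CI."""

    mean: float
    sd: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class RegressionEffectSpec:
    """Normal regression coefficients plus covariate profiles for the pre and
    post-surgery score predictions (hip pathway)."""

    coef_mean: tuple
    coef_se: tuple
    x_pre: tuple
    x_post: tuple
    max_retries: int = 100

    def __post_init__(self) -> None:
        k = len(self.coef_mean)
        if len(self.coef_se) != k or len(self.x_pre) != k or len(self.x_post) != k:
            raise ValueError("coefficient and profile dimensions must agree")
        if any(se < 0 for se in self.coef_se):
            raise ValueError("coefficient standard errors must be non-negative")

    def to_dict(self) -> dict:
        return {
            "coef_mean": list(self.coef_mean),
            "coef_se": list(self.coef_se),
            "x_pre": list(self.x_pre),
            "x_post": list(self.x_post),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegressionEffectSpec":
        return cls(
            coef_mean=tuple(d["coef_mean"]), coef_se=tuple(d["coef_se"]),
            x_pre=tuple(d["x_pre"]), x_post=tuple(d["x_post"]),
        )


def normalize_score(p: InstrumentScorePair) -> InstrumentScorePair:
    """Map a score pair onto [0, 1] oriented higher-is-better.

    Linear rescale by the declared native range; higher-is-worse instruments
    (e.g. HAQ, 0-3) are flipped after rescaling so that post >= pre always
    indicates improvement.  Idempotent on already-normalized pairs.
    """
    span = p.range_max - p.range_min
    pre = (p.pre - p.range_min) / span
    post = (p.post - p.range_min) / span
    if p.orientation == "higher_worse":
        pre, post = 1.0 - pre, 1.0 - post
    return replace(p, orientation="higher_better", range_min=0.0, range_max=1.0,
                   pre=pre, post=post)


def effect_from_scores(pre: float, post: float) -> float:
    """Relative improvement in residual deficit: (post - pre) / (1 - pre).

    Inputs are unit-interval scores oriented higher-is-better.  Negative
    values indicate worsening and are allowed; pre = 1 leaves no residual
    deficit to improve and is an error.
    """
    if not (0.0 <= pre <= 1.0 and 0.0 <= post <= 1.0):
        raise ValueError(f"scores must lie in [0, 1], got pre={pre}, post={post}")
    if pre == 1.0:
        raise ValueError("pre-score of 1 leaves no residual deficit (division by zero)")
    return (post - pre) / (1.0 - pre)


def dw_post(dw_pre: float, effect: float) -> float:
    """Post-intervention disability weight DW_pre * (1 - Effect), clamped to [0, 1]."""
    if not (0.0 <= dw_pre <= 1.0):
        raise ValueError(f"dw_pre must lie in [0, 1], got {dw_pre}")
    if effect > 1.0:
        raise ValueError(f"effect cannot exceed 1, got {effect}")
    return min(1.0, max(0.0, dw_pre * (1.0 - effect)))


def pooled_effect_bootstrap(pairs: Sequence[InstrumentScorePair], n_boot: int,
                            rng: np.random.Generator) -> EffectSummary:
    """Non-parametric bootstrap of the pooled effect over study score pairs.

    Studies are resampled with replacement (unweighted) ``n_boot`` times; each
    replicate's effect is the mean of the per-study effects over the resample.
    Returns the replicate mean, sd and percentile 2.5/97.5 interval.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 score pairs to bootstrap")
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    effs = np.array([
        effect_from_scores(q.pre, q.post) for q in (normalize_score(p) for p in pairs)
    ])
    idx = rng.integers(0, effs.size, size=(n_boot, effs.size))
    reps = effs[idx].mean(axis=1)
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return EffectSummary(mean=float(reps.mean()), sd=float(reps.std(ddof=1)),
                         ci_low=float(lo), ci_high=float(hi))


def effect_from_regression(spec: RegressionEffectSpec,
                           rng: np.random.Generator) -> float:
    """Sample one effect size via the regression pathway.

    Each coefficient is drawn from its normal distribution; the linear
    predictor over the pre and post covariate profiles yields unit-interval
    scores which enter the score cross-walk.  Draws with predicted scores
    outside [0, 1) for pre or [0, 1] for post are rejected and redrawn up to
    ``spec.max_retries`` times.
    """
    mean = np.asarray(spec.coef_mean, dtype=float)
    se = np.asarray(spec.coef_se, dtype=float)
    x_pre = np.asarray(spec.x_pre, dtype=float)
    x_post = np.asarray(spec.x_post, dtype=float)
    for _ in range(spec.max_retries):
        beta = mean + se * rng.standard_normal(mean.size)
        pre = float(x_pre @ beta)
        post = float(x_post @ beta)
        if 0.0 <= pre < 1.0 and 0.0 <= post <= 1.0:
            return effect_from_scores(pre, post)
    raise RuntimeError(
        f"no admissible score pair after {spec.max_retries} coefficient draws"
    )
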