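"""Conversion of relative treatment effects to absolute cure probabilities.

The evidence base reports cure odds ratios (ORs) of each comparator versus
the retropubic sling reference, plus the reference's absolute cure
proportion at 12 months. A comparator's absolute cure probability is the
reference's cure odds multiplied by the OR and mapped back to a
probability. Repeat surgeries (always one of the two mid-urethral slings)
are assumed 90% as effective as primary surgery, applied on the
probability scale.

For probabilistic sampling, ORs are given a lognormal distribution fitted
to the published median and 95% credible interval: the sampled median then
reproduces the printed median exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .parameters import (
    ModelParameters,
    REFERENCE_STRATEGY,
    RETREAT_STRATEGIES,
)

__all__ = [
    "Z95",
    "SampledEffects",
    "or_to_prob",
    "fit_lognormal_from_crl",
    "base_effects",
    "effective_cure_prob",
]

#: two-sided 95% normal quantile
Z95 = 1.959964


@dataclass
class SampledEffects:
    """One realisation of the odds-ratio vector (reference fixed at 1)."""

    ors: dict[str, float]
    draw_index: int = 0
    seed: object = None

    def __post_init__(self):
        self.ors = dict(self.ors)
        self.ors[REFERENCE_STRATEGY] = 1.0
        if any(v <= 0 for v in self.ors.values()):
            raise ValueError("sampled odds ratios must be positive")


def or_to_prob(baseline_p: float, or_: float) -> float:
    """Apply an odds ratio to a baseline probability.

    p' = odds * OR / (1 + odds * OR) with odds = p/(1-p); strictly
    increasing in OR and the identity at OR = 1.
    """
    if not (0.0 < baseline_p < 1.0):
        raise ValueError(f"baseline probability must be in (0,1), got {baseline_p}")
    if or_ <= 0:
        raise ValueError(f"odds ratio must be positive, got {or_}")
    odds = baseline_p / (1.0 - baseline_p) * or_
    return odds / (1.0 + odds)


def fit_lognormal_from_crl(median: float, low: float, high: float) -> tuple[float, float]:
    """Fit (mu, sigma) of a lognormal from a median and 95% credible interval.

    mu = ln(median); sigma = (ln(high) - ln(low)) / (2 * 1.959964).
    exp(Normal(mu, sigma)) has median exactly ``median`` and reproduces a
    log-symmetric interval approximately.
    """
    if not (0 < low <= median <= high):
        raise ValueError(
            f"need 0 < low <= median <= high, got ({median}, {low}, {high})"
        )
    mu = math.log(median)
    sigma = (math.log(high) - math.log(low)) / (2.0 * Z95)
    return mu, sigma


def sample_odds_ratio(
    median: float, low: float, high: float, rng
) -> float:
    """One lognormal odds-ratio draw from a median and 95% credible
    interval; degenerate (returns the median) when the interval has zero
    width. This is the sampler the PSA uses for every relative effect."""
    mu, sigma = fit_lognormal_from_crl(median, low, high)
    if sigma == 0.0:
        return median
    return math.exp(rng.normal(mu, sigma))


def base_effects(p: ModelParameters) -> SampledEffects:
    """The deterministic (median) odds-ratio vector from the parameter set."""
    return SampledEffects(ors={e.strategy: e.or_median for e in p.effects})


def effective_cure_prob(
    p: ModelParameters,
    strategy: str,
    surgery_number: int,
    effects: SampledEffects | None = None,
) -> float:
    """Absolute cure probability for a given strategy and surgery number.

    The primary probability converts the reference 12-month cure through the
    strategy's OR; surgeries 2 and 3 (restricted to the two mid-urethral
    slings) are multiplied by the re-treatment effectiveness multiplier.
    The result is clamped to [0, 1] (the clamp cannot bind for valid inputs).
    """
    if surgery_number not in (1, 2, 3):
        raise ValueError(f"surgery_number must be 1, 2 or 3, got {surgery_number}")
    if surgery_number > 1 and strategy not in RETREAT_STRATEGIES:
        raise ValueError(
            f"re-treatment is restricted to {RETREAT_STRATEGIES}, got {strategy!r}"
        )
    if effects is None:
        effects = base_effects(p)
    baseline = p.cure_at(12).cure_prop
    prob = or_to_prob(baseline, effects.ors.get(strategy, 1.0))
    if surgery_number > 1:
        prob *= p.retreatment.retreat_effect_multiplier
    return min(max(prob, 0.0), 1.0)
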