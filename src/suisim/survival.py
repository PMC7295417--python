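"""Weibull extrapolation of time-to-recurrence after the reference surgery.

Long-term recurrence is extrapolated from two reported cure proportions
(at 1 year and 5 years) by fitting a two-parameter Weibull survival curve
S(t) = exp(-(t/scale)^shape). The fit is closed-form: passing the curve
through both points gives

    shape = ln(ln s2 / ln s1) / ln(t2 / t1),
    scale = t1 / (-ln s1)^(1/shape).

The fitted curve is then discretised into per-cycle conditional recurrence
probabilities 1 - S(t+dt)/S(t).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "WeibullParams",
    "fit_weibull_two_points",
    "survival_at",
    "cycle_recurrence_prob",
]


@dataclass(frozen=True)
class WeibullParams:
    """Shape (k) and scale (lambda, in years) of the recurrence-time
    distribution; shape > 1 means recurrence hazard increases with time."""

    shape: float
    scale: float

    def __post_init__(self):
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("Weibull shape and scale must be positive")


def fit_weibull_two_points(t1: float, s1: float, t2: float, s2: float) -> WeibullParams:
    """Fit Weibull parameters through two survival points (t1, s1), (t2, s2).

    Requires 0 < t1 < t2 and 0 < s2 < s1 < 1 (survival must strictly
    decrease). The returned curve reproduces both inputs exactly.
    """
    if not (0 < t1 < t2):
        raise ValueError(f"need 0 < t1 < t2, got t1={t1}, t2={t2}")
    if not (0 < s2 < s1 < 1):
        raise ValueError(
            f"need survival strictly decreasing inside (0,1): s1={s1}, s2={s2}"
        )
    shape = math.log(math.log(s2) / math.log(s1)) / math.log(t2 / t1)
    scale = t1 / (-math.log(s1)) ** (1.0 / shape)
    return WeibullParams(shape=shape, scale=scale)


def survival_at(w: WeibullParams, t: float) -> float:
    """S(t) = exp(-(t/scale)^shape); S(0) = 1, monotone non-increasing."""
    if t < 0:
        raise ValueError(f"time must be non-negative, got {t}")
    return math.exp(-((t / w.scale) ** w.shape))


def cycle_recurrence_prob(w: WeibullParams, t: float, dt: float) -> float:
    """Conditional probability of recurrence in (t, t+dt] given still cured
    at t: 1 - S(t+dt)/S(t). Returns 1 when S(t) underflows to zero."""
    if t < 0:
        raise ValueError(f"time must be non-negative, got {t}")
    if dt <= 0:
        raise ValueError(f"cycle length must be positive, got {dt}")
    st = survival_at(w, t)
    if st == 0.0:
        return 1.0
    p = 1.0 - survival_at(w, t + dt) / st
    return min(max(p, 0.0), 1.0)
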