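"""Default and randomised parameter sets.

The shipped default configuration combines two kinds of values:

* published quantities — the cure odds ratios with credible intervals, the
  reference strategy's cure proportions over time, the re-treatment policy
  constants (75%/30% seeking, 55/45 sling mix, 90% repeat effectiveness,
  three-surgery cap), the 3.5% discount rate and the 15,000-per-year
  affected population — tagged ``provenance="paper"``;
* documented placeholders for everything the evidence tables do not print
  (complication incidences and costs, unit costs, utilities, the UUI
  pathway, the life table), tagged ``provenance="synthetic-default"``.
  These are chosen to be structurally plausible (day-case procedures
  cheaper than inpatient ones, persistent pain rarer than short-term
  pain) but are explicitly NOT published supplementary values.

:func:`random_parameter_set` draws the placeholder families uniformly
within configurable ranges for property/fuzz testing; every emitted set
passes :func:`suisim.parameters.validate_parameters`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .parameters import (
    COMPLICATION_NAMES,
    STRATEGY_IDS,
    BaselineCure,
    ComplicationSpec,
    CostSet,
    EconomicSettings,
    EffectEstimate,
    LifeTable,
    ModelParameters,
    Population,
    RetreatmentPolicy,
    Strategy,
    UtilitySet,
    UuiLine,
    default_strategies,
    validate_parameters,
)

__all__ = [
    "SyntheticSpec",
    "default_parameter_set",
    "random_parameter_set",
    "synthetic_life_table",
]

# Cure odds ratios versus the retropubic sling (mean, median, 95% CrI).
_EFFECTS = {
    "transob-MUS": (0.742, 0.738, 0.588, 0.923),
    "open-colpo": (0.874, 0.853, 0.544, 1.325),
    "lap-colpo": (0.605, 0.58, 0.315, 1.046),
    "trad-sling": (1.106, 1.061, 0.623, 1.846),
    "single-incision": (0.511, 0.504, 0.36, 0.699),
    "bladder-neck-needle": (0.368, 0.34, 0.154, 0.745),
    "anterior-repair": (0.235, 0.22, 0.105, 0.452),
    # no published odds ratio for injectable agents: synthetic placeholder,
    # set below the sling comparators per the qualitative evidence ordering
    "injectable-agents": (0.46, 0.45, 0.25, 0.80),
}
_SYNTHETIC_EFFECTS = ("injectable-agents",)

# Reference-strategy cure proportions (months, median, 95% CrI); the 12- and
# 60-month rows drive the Weibull extrapolation.
_BASELINE_CURE = [
    (6, 0.776, 0.175, 0.983),
    (12, 0.841, 0.214, 0.990),
    (24, 0.784, 0.454, 0.941),
    (36, 0.341, 0.001, 0.995),
    (60, 0.329, 0.005, 0.979),
]

# Synthetic placeholder complication set: name -> (incidence by strategy,
# one-off cost GBP, utility decrement, duration in monthly cycles).
_COMPLICATIONS: dict[str, tuple[dict[str, float], float, float, int]] = {
    "infection": (
        {
            "retro-MUS": 0.03, "transob-MUS": 0.03, "single-incision": 0.03,
            "injectable-agents": 0.02, "open-colpo": 0.06, "lap-colpo": 0.05,
            "trad-sling": 0.06, "bladder-neck-needle": 0.05, "anterior-repair": 0.05,
        },
        350.0, 0.05, 1,
    ),
    "uui-onset": (
        {
            "retro-MUS": 0.05, "transob-MUS": 0.05, "open-colpo": 0.08,
            "lap-colpo": 0.08, "trad-sling": 0.09, "single-incision": 0.04,
            "bladder-neck-needle": 0.07, "anterior-repair": 0.06,
            "injectable-agents": 0.02,
        },
        100.0, 0.0, 0,  # quality-of-life impact carried by the UUI state utility
    ),
    "voiding-difficulty": (
        {
            "retro-MUS": 0.04, "transob-MUS": 0.03, "open-colpo": 0.04,
            "lap-colpo": 0.04, "trad-sling": 0.07, "single-incision": 0.03,
            "bladder-neck-needle": 0.05, "anterior-repair": 0.02,
            "injectable-agents": 0.01,
        },
        550.0, 0.04, 2,
    ),
    "perforation": (
        {
            "retro-MUS": 0.04, "transob-MUS": 0.02, "trad-sling": 0.04,
            "single-incision": 0.02, "bladder-neck-needle": 0.03,
        },
        800.0, 0.10, 1,
    ),
    "mesh-removal": (
        {"retro-MUS": 0.02, "transob-MUS": 0.025, "single-incision": 0.02},
        2600.0, 0.10, 3,
    ),
    "short-term-pain": (
        {
            "retro-MUS": 0.05, "transob-MUS": 0.06, "open-colpo": 0.08,
            "lap-colpo": 0.07, "trad-sling": 0.08, "single-incision": 0.04,
            "bladder-neck-needle": 0.06, "anterior-repair": 0.07,
            "injectable-agents": 0.03,
        },
        120.0, 0.05, 1,
    ),
    # base-case duration one year; deterministic scenarios stretch it to 3/5y
    "persistent-pain": (
        {
            "retro-MUS": 0.015, "transob-MUS": 0.02, "single-incision": 0.01,
            "trad-sling": 0.01,
        },
        400.0, 0.10, 12,
    ),
}

# Synthetic placeholder tariffs (GBP 2018/19): day-case sling procedures are
# cheaper than inpatient open/laparoscopic surgery.
_PROCEDURE_COST = {
    "retro-MUS": 1800.0,
    "transob-MUS": 1750.0,
    "single-incision": 1500.0,
    "injectable-agents": 1400.0,
    "open-colpo": 3600.0,
    "lap-colpo": 3900.0,
    "trad-sling": 3100.0,
    "bladder-neck-needle": 2800.0,
    "anterior-repair": 2600.0,
}

_UTILITIES = dict(
    u_pre_treatment_sui=0.73, u_cured=0.85, u_containment=0.69, u_uui=0.67
)
_UTILITY_SE = {k: 0.02 for k in _UTILITIES}

_UUI_LINES = [
    UuiLine(success_prob=0.30, duration_cycles=3, cost=150.0),   # bladder training
    UuiLine(success_prob=0.35, duration_cycles=6, cost=250.0),   # medication
    UuiLine(success_prob=0.50, duration_cycles=3, cost=900.0),   # botulinum toxin A
]

#: effective sample size behind the beta uncertainty on each synthetic
#: complication incidence
_COMP_ESS = 300.0

# Gompertz mortality anchor for the synthetic female life table:
# q(age) = A * exp(B * age), truncated to 1 at the final age.
_GOMPERTZ_A = 2.0e-5
_GOMPERTZ_B = 0.094


def synthetic_life_table(max_age: int = 100) -> LifeTable:
    """Gompertz-shaped female life table over contiguous ages 40..max_age;
    mortality is non-decreasing in age and the final-age probability is 1."""
    if max_age <= 55:
        raise ValueError("max_age must exceed 55")
    ages = list(range(40, max_age + 1))
    qx = [min(1.0, _GOMPERTZ_A * math.exp(_GOMPERTZ_B * a)) for a in ages]
    qx[-1] = 1.0
    return LifeTable(ages=ages, qx=qx)


def _beta_ab(p: float, ess: float) -> list[float]:
    return [max(p * ess, 1e-3), max((1.0 - p) * ess, 1e-3)]


def _complication_specs(
    table: dict[str, tuple[dict[str, float], float, float, int]]
) -> list[ComplicationSpec]:
    return [
        ComplicationSpec(
            name=name,
            incidence_by_strategy=dict(inc),
            one_off_cost=cost,
            utility_decrement=decr,
            duration_cycles=dur,
            uncertainty={s: _beta_ab(p, _COMP_ESS) for s, p in inc.items()},
            utility_decrement_se=0.2 * decr,
        )
        for name, (inc, cost, decr, dur) in table.items()
    ]


def _provenance() -> dict[str, str]:
    tags = {
        "strategies": "paper",
        "effects": "paper",
        "effects.injectable-agents": "synthetic-default",
        "baseline_cure": "paper",
        "retreatment": "paper",
        "economics.discount_rate_annual": "paper",
        "economics.horizons": "paper",
        "economics.price_year": "paper",
        "economics.wtp_grid": "synthetic-default",
        "population.annual_affected": "paper",
        "population.start_age": "synthetic-default",
        "utilities": "synthetic-default",
        "costs": "synthetic-default",
        "life_table": "synthetic-default",
        "uui_pathway": "synthetic-default",
    }
    tags.update({f"complications.{n}": "synthetic-default" for n in COMPLICATION_NAMES})
    return tags


def default_parameter_set() -> ModelParameters:
    """The shipped default configuration (see module docstring)."""
    params = ModelParameters(
        strategies=default_strategies(),
        effects=[
            EffectEstimate(strategy=s, or_mean=m, or_median=md, crl_low=lo, crl_high=hi)
            for s, (m, md, lo, hi) in _EFFECTS.items()
        ],
        baseline_cure=[
            BaselineCure(time_months=t, cure_prop=p, crl_low=lo, crl_high=hi)
            for t, p, lo, hi in _BASELINE_CURE
        ],
        complications=_complication_specs(_COMPLICATIONS),
        retreatment=RetreatmentPolicy(),
        economics=EconomicSettings(),
        utilities=UtilitySet(**_UTILITIES, se=dict(_UTILITY_SE)),
        costs=CostSet(
            procedure_cost=dict(_PROCEDURE_COST),
            perioperative_cost=350.0,
            containment_cost_per_cycle=35.0,
        ),
        life_table=synthetic_life_table(100),
        uui_pathway=[UuiLine(**vars(l)) for l in _UUI_LINES],
        population=Population(start_age=50, annual_affected=15_000),
        provenance=_provenance(),
    )
    violations = validate_parameters(params)
    assert not violations, violations
    return params


@dataclass
class SyntheticSpec:
    """Ranges for randomising the synthetic parameter families.

    Each range is a ``(low, high)`` pair sampled uniformly per item. A
    range collapsed to a point (``low == high``) means "do not randomise":
    the default placeholder values are kept for that family.
    """

    seed: int = 0
    complication_incidence: tuple[float, float] = (0.0, 0.2)
    complication_cost: tuple[float, float] = (100.0, 3000.0)
    utility_decrement: tuple[float, float] = (0.0, 0.3)
    day_case_cost: tuple[float, float] = (1200.0, 2200.0)
    inpatient_cost: tuple[float, float] = (2500.0, 4500.0)
    uui_success: tuple[float, float] = (0.2, 0.6)

    def ranges(self) -> dict[str, tuple[float, float]]:
        return {
            k: getattr(self, k)
            for k in (
                "complication_incidence",
                "complication_cost",
                "utility_decrement",
                "day_case_cost",
                "inpatient_cost",
                "uui_success",
            )
        }


def random_parameter_set(spec: SyntheticSpec) -> ModelParameters:
    """A randomised parameter set: published values fixed, synthetic
    placeholder families redrawn uniformly within the spec's ranges.
    Deterministic given ``spec.seed``; always passes validation."""
    for name, (lo, hi) in spec.ranges().items():
        if lo > hi:
            raise ValueError(f"{name}: inverted range ({lo}, {hi})")
    rng = np.random.default_rng(spec.seed)
    p = default_parameter_set()

    def draw(bounds: tuple[float, float]) -> float | None:
        lo, hi = bounds
        return None if lo == hi else float(rng.uniform(lo, hi))

    for comp in p.complications:
        for s in list(comp.incidence_by_strategy):
            v = draw(spec.complication_incidence)
            if v is not None:
                comp.incidence_by_strategy[s] = v
                comp.uncertainty[s] = _beta_ab(v, _COMP_ESS)
        v = draw(spec.complication_cost)
        if v is not None:
            comp.one_off_cost = v
        v = draw(spec.utility_decrement)
        if v is not None and comp.utility_decrement > 0:
            comp.utility_decrement = min(v, p.utilities.u_cured)
    for s in STRATEGY_IDS:
        setting = next(x.setting for x in p.strategies if x.id == s)
        v = draw(spec.day_case_cost if setting == "day-case" else spec.inpatient_cost)
        if v is not None:
            p.costs.procedure_cost[s] = v
    for line in p.uui_pathway:
        v = draw(spec.uui_success)
        if v is not None:
            line.success_prob = v

    for key in (
        "complications", "costs", "uui_pathway",
    ):
        p.provenance[key + ".randomised"] = f"seed={spec.seed}"
    violations = validate_parameters(p)
    assert not violations, violations
    return p
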