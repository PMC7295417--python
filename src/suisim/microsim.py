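"""Patient-level Markov microsimulation of the surgical treatment pathway.

Each simulated woman starts at a configurable age (default 50) and receives
an initial surgery for stress urinary incontinence. Cycle length is one
month. Within a cycle, events are applied in a fixed order:

1. all-cause mortality (annual life-table probability converted to a
   monthly probability under a constant within-year hazard); death occurs
   at the start of the cycle, so no cost or QALY accrues in that cycle;
2. if a surgery happens this cycle: cure determination (12-month cure
   probability through the strategy's odds ratio, times the re-treatment
   multiplier for repeat surgeries) and complication onset draws;
3. if cured: Weibull conditional recurrence, with the recurrence clock
   anchored at the 12-month cure-assessment point;
4. if incontinent after a failure in an *earlier* cycle: re-treatment
   seeking (75% after the first failure, 30% after the second, always a
   retropubic or transobturator sling in a 55/45 mix); non-seekers and
   women whose three surgeries are exhausted move to containment
   permanently;
5. urge-incontinence (UUI) pathway progression through its three treatment
   lines;
6. expiry of time-limited complication utility decrements;
7. accrual of the cycle's costs and QALYs — one-off event costs are
   discounted at the cycle start, recurring costs and utility at mid-cycle
   (half-cycle convention).

A maximum of three surgeries is enforced; after the third failure the
woman uses containment products for the remainder of the simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .effects import SampledEffects, base_effects, effective_cure_prob
from .parameters import ModelParameters, RETREAT_STRATEGIES, STRATEGY_IDS
from .survival import WeibullParams, cycle_recurrence_prob, fit_weibull_two_points

__all__ = [
    "CURED",
    "AWAITING",
    "CONTAINMENT",
    "SimContext",
    "PatientState",
    "CohortResult",
    "parse_horizon",
    "step_cycle",
    "simulate_patient",
    "simulate_cohort",
    "write_audit",
]

# continence states
CURED = "cured"
AWAITING = "incontinent-awaiting"
CONTAINMENT = "containment"

#: age (years) at which the cure probability is assessed and the recurrence
#: clock starts; matches the 12-month evidence base.
CURE_ASSESSMENT_YEARS = 1.0

#: lifetime horizon runs to death or this age
MAX_AGE = 100


def parse_horizon(horizon: str | int, start_age: int) -> int:
    """Horizon label ('1y', '10y', 'lifetime') or raw month count -> cycles."""
    if isinstance(horizon, int):
        if horizon < 1:
            raise ValueError("horizon in months must be >= 1")
        return horizon
    if horizon == "lifetime":
        return max(1, (MAX_AGE - start_age) * 12)
    if isinstance(horizon, str) and horizon.endswith("y"):
        try:
            years = int(horizon[:-1])
        except ValueError:
            raise ValueError(f"unrecognised horizon {horizon!r}") from None
        if years < 1:
            raise ValueError(f"unrecognised horizon {horizon!r}")
        return years * 12
    raise ValueError(f"unrecognised horizon {horizon!r}")


class SimContext:
    """Pre-computed per-configuration quantities shared by all patients.

    Building the context once per parameter set (or per PSA draw) keeps the
    inner cycle loop cheap.
    """

    __slots__ = (
        "p_cure",
        "weibull",
        "policy",
        "q_month",
        "age0_table",
        "comps",
        "proc_total",
        "containment_cost",
        "uui_lines",
        "u_cured",
        "u_awaiting",
        "u_containment",
        "u_uui",
        "rate",
        "start_age",
    )

    def __init__(self, p: ModelParameters, effects: SampledEffects | None = None):
        if effects is None:
            effects = base_effects(p)
        self.p_cure = {
            s: effective_cure_prob(p, s, 1, effects) for s in STRATEGY_IDS
        }
        c12 = p.cure_at(12)
        c60 = p.cure_at(60)
        self.weibull: WeibullParams = fit_weibull_two_points(
            1.0, c12.cure_prop, 5.0, c60.cure_prop
        )
        self.policy = p.retreatment
        lt = p.life_table
        self.age0_table = lt.ages[0]
        self.q_month = np.array(
            [1.0 - (1.0 - q) ** (1.0 / 12.0) for q in lt.qx], dtype=float
        )
        # per-strategy complication risk tuples (p, one-off cost, utility
        # decrement, duration in cycles, triggers-UUI flag)
        self.comps = {
            s: [
                (
                    c.incidence(s),
                    c.one_off_cost,
                    c.utility_decrement,
                    c.duration_cycles,
                    c.name == "uui-onset",
                )
                for c in p.complications
                if c.incidence(s) > 0.0
            ]
            for s in STRATEGY_IDS
        }
        self.proc_total = {
            s: p.costs.procedure_cost[s] + p.costs.perioperative_cost
            for s in STRATEGY_IDS
        }
        self.containment_cost = p.costs.containment_cost_per_cycle
        self.uui_lines = [
            (l.success_prob, l.duration_cycles, l.cost) for l in p.uui_pathway
        ]
        u = p.utilities
        self.u_cured = u.u_cured
        self.u_awaiting = u.u_pre_treatment_sui
        self.u_containment = u.u_containment
        self.u_uui = u.u_uui
        self.rate = p.economics.discount_rate_annual
        self.start_age = p.population.start_age

    def monthly_mortality(self, age: float) -> float:
        i = int(age) - self.age0_table
        if i < 0:
            i = 0
        elif i >= len(self.q_month):
            i = len(self.q_month) - 1
        return self.q_month[i]


@dataclass(slots=True)
class PatientState:
    """One simulated woman's evolving status. Costs and QALYs are
    accumulated already discounted."""

    age: float
    alive: bool = True
    continence: str = AWAITING
    surgeries_done: int = 0
    n_failures: int = 0
    time_since_cure: int = 0  # survived recurrence draws since cure assessment
    pending_surgery: str | None = None
    failed_this_cycle: bool = False
    active_complications: list = field(default_factory=list)  # [decr, remaining]
    uui_present: bool = False
    uui_line: int = 0  # 0 none, 1..3 active lines, 4 exhausted
    uui_remaining: int = 0
    month: int = 0
    accumulated_cost: float = 0.0
    accumulated_qaly: float = 0.0


def _perform_surgery(s: PatientState, strategy: str, ctx: SimContext, rng) -> float:
    """Execute one surgery: tariff, cure determination, complication draws.
    Returns the one-off cost incurred."""
    s.surgeries_done += 1
    cost = ctx.proc_total[strategy]
    p_cure = ctx.p_cure[strategy]
    if s.surgeries_done > 1:
        p_cure = min(1.0, p_cure * ctx.policy.retreat_effect_multiplier)
    if rng.random() < p_cure:
        s.continence = CURED
        s.time_since_cure = 0
    else:
        s.continence = AWAITING
        s.n_failures += 1
        s.failed_this_cycle = True
    for p_comp, c_cost, decr, dur, is_uui in ctx.comps[strategy]:
        if rng.random() < p_comp:
            cost += c_cost
            if dur > 0 and decr > 0:
                s.active_complications.append([decr, dur])
            if is_uui and not s.uui_present:
                s.uui_present = True
                s.uui_line = 1
                succ, d, line_cost = ctx.uui_lines[0]
                s.uui_remaining = d
                cost += line_cost
    return cost


def step_cycle(
    s: PatientState,
    ctx: SimContext,
    rng: np.random.Generator,
    audit: list | None = None,
) -> PatientState:
    """Advance one monthly cycle in place (also returns the state)."""
    if not s.alive:
        raise ValueError("cannot step a dead patient")
    event = ""
    t_start = s.month / 12.0
    # 1. all-cause mortality
    if rng.random() < ctx.monthly_mortality(s.age):
        s.alive = False
        if audit is not None:
            audit.append(_audit_row(s, 0.0, 0.0, "death"))
        s.month += 1
        s.age += 1.0 / 12.0
        return s

    event_cost = 0.0
    # 2. scheduled surgery (initial surgery at cycle 0)
    if s.pending_surgery is not None:
        strat = s.pending_surgery
        s.pending_surgery = None
        event_cost += _perform_surgery(s, strat, ctx, rng)
        event = f"surgery:{strat}"
    # 3. recurrence among the cured
    elif s.continence == CURED:
        t = CURE_ASSESSMENT_YEARS + s.time_since_cure / 12.0
        if rng.random() < cycle_recurrence_prob(ctx.weibull, t, 1.0 / 12.0):
            s.continence = AWAITING
            s.n_failures += 1
            s.failed_this_cycle = True
            event = "recurrence"
        else:
            s.time_since_cure += 1

    # 4. re-treatment decision, one cycle after the failure
    if (
        s.continence == AWAITING
        and not s.failed_this_cycle
        and s.surgeries_done >= 1
    ):
        if s.surgeries_done >= ctx.policy.max_surgeries:
            s.continence = CONTAINMENT
            event = "containment"
        else:
            p_seek = (
                ctx.policy.p_seek_first_retreat
                if s.n_failures == 1
                else ctx.policy.p_seek_second_retreat
            )
            if rng.random() < p_seek:
                strat = (
                    RETREAT_STRATEGIES[0]
                    if rng.random() < ctx.policy.retreat_mix_retro
                    else RETREAT_STRATEGIES[1]
                )
                event_cost += _perform_surgery(s, strat, ctx, rng)
                event = f"surgery:{strat}"
            else:
                s.continence = CONTAINMENT
                event = "containment"

    # 5. UUI pathway progression
    if s.uui_present and 1 <= s.uui_line <= 3:
        s.uui_remaining -= 1
        if s.uui_remaining <= 0:
            succ = ctx.uui_lines[s.uui_line - 1][0]
            if rng.random() < succ:
                s.uui_present = False
                s.uui_line = 0
            else:
                s.uui_line += 1
                if s.uui_line > 3:
                    s.uui_line = 4  # exhausted; UUI persists untreated
                else:
                    _, d, line_cost = ctx.uui_lines[s.uui_line - 1]
                    s.uui_remaining = d
                    event_cost += line_cost

    # 6. complication decrement bookkeeping (effects apply to this cycle's
    # utility, then remaining durations tick down)
    cycle_decrement = 0.0
    if s.active_complications:
        keep = []
        for item in s.active_complications:
            cycle_decrement += item[0]
            item[1] -= 1
            if item[1] > 0:
                keep.append(item)
        s.active_complications = keep

    # 7. accrual, half-cycle discounting for recurring quantities
    if s.continence == CURED:
        base_u = ctx.u_cured
    elif s.continence == AWAITING:
        base_u = ctx.u_awaiting
    else:
        base_u = ctx.u_containment
    if s.uui_present:
        base_u = min(base_u, ctx.u_uui)
    utility = max(0.0, base_u - cycle_decrement)

    recurring_cost = ctx.containment_cost if s.continence == CONTAINMENT else 0.0
    t_mid = (s.month + 0.5) / 12.0
    df_start = (1.0 + ctx.rate) ** (-t_start)
    df_mid = (1.0 + ctx.rate) ** (-t_mid)
    cycle_cost = event_cost * df_start + recurring_cost * df_mid
    cycle_qaly = utility / 12.0 * df_mid
    s.accumulated_cost += cycle_cost
    s.accumulated_qaly += cycle_qaly

    if audit is not None:
        audit.append(_audit_row(s, cycle_cost, cycle_qaly, event))

    s.failed_this_cycle = False
    s.month += 1
    s.age += 1.0 / 12.0
    return s


def _audit_row(s: PatientState, cost: float, qaly: float, event: str) -> dict:
    return {
        "month": s.month,
        "alive": s.alive,
        "continence": s.continence,
        "surgeries_done": s.surgeries_done,
        "n_failures": s.n_failures,
        "uui_line": s.uui_line,
        "cycle_cost": cost,
        "cycle_qaly": qaly,
        "event": event,
    }


def simulate_patient(
    p: ModelParameters | SimContext,
    strategy: str,
    horizon: str | int,
    rng: np.random.Generator,
    audit: list | None = None,
) -> tuple[float, float]:
    """Simulate one woman; returns her discounted (cost, QALY) totals.

    ``p`` may be either a parameter set or a pre-built :class:`SimContext`.
    """
    ctx = p if isinstance(p, SimContext) else SimContext(p)
    n_cycles = parse_horizon(horizon, ctx.start_age)
    state = PatientState(age=float(ctx.start_age), pending_surgery=strategy)
    for _ in range(n_cycles):
        step_cycle(state, ctx, rng, audit)
        if not state.alive:
            break
    return state.accumulated_cost, state.accumulated_qaly


@dataclass
class CohortResult:
    """Mean discounted cost and QALYs over a simulated cohort."""

    strategy: str
    n_patients: int
    mean_cost: float
    mean_qaly: float
    se_cost: float
    se_qaly: float
    horizon: str | int


def _patient_rng(seed: int, index: int) -> np.random.Generator:
    # counter-based substream: independent of execution order, and identical
    # across strategies so that comparisons use common random numbers
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(index)]))


def simulate_cohort(
    p: ModelParameters | SimContext,
    strategy: str,
    n: int,
    horizon: str | int,
    seed: int,
    ctx: SimContext | None = None,
) -> CohortResult:
    """Simulate ``n`` independent women under one strategy.

    Patient ``i`` always uses the substream derived from ``(seed, i)``, so
    results do not depend on execution order and repeat calls with other
    strategies reuse the same random numbers patient-by-patient.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if ctx is None:
        ctx = p if isinstance(p, SimContext) else SimContext(p)
    costs = np.empty(n)
    qalys = np.empty(n)
    for i in range(n):
        costs[i], qalys[i] = simulate_patient(
            ctx, strategy, horizon, _patient_rng(seed, i)
        )
    se_c = float(costs.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    se_q = float(qalys.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return CohortResult(
        strategy=strategy,
        n_patients=n,
        mean_cost=float(costs.mean()),
        mean_qaly=float(qalys.mean()),
        se_cost=se_c,
        se_qaly=se_q,
        horizon=horizon,
    )


def write_audit(rows: Sequence[dict], path) -> None:
    """Write a trajectory audit log as tab-delimited text."""
    import csv

    fields = [
        "month", "alive", "continence", "surgeries_done", "n_failures",
        "uui_line", "cycle_cost", "cycle_qaly", "event",
    ]
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=fields, delimiter="\t")
        w.writeheader()
        w.writerows(rows)
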