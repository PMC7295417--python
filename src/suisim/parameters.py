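"""Parameter definitions, loading, validation and scenario modification.

The full input set for one model configuration lives in a single
:class:`ModelParameters` object: the nine surgical strategies, relative
cure effects (odds ratios vs the retropubic mid-urethral sling reference),
the reference strategy's absolute cure proportions over time, complication
specifications, the re-treatment policy, economic settings, health-state
utilities, unit costs, an all-cause mortality life table, the urge-
incontinence (UUI) treatment pathway and population settings.

Configurations are read from a YAML file plus a delimited ``age,qx`` life
table; every field carries a provenance tag (``paper``, ``synthetic-default``
or ``user``) so that values taken from published tables are distinguishable
from documented placeholders.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "STRATEGY_IDS",
    "REFERENCE_STRATEGY",
    "RETREAT_STRATEGIES",
    "COMPLICATION_NAMES",
    "SCENARIO_KEYS",
    "Strategy",
    "EffectEstimate",
    "BaselineCure",
    "ComplicationSpec",
    "RetreatmentPolicy",
    "EconomicSettings",
    "UtilitySet",
    "CostSet",
    "UuiLine",
    "LifeTable",
    "Population",
    "ModelParameters",
    "SchemaError",
    "ValidationError",
    "default_strategies",
    "load_parameters",
    "save_parameters",
    "validate_parameters",
    "apply_scenario",
]

# The nine surgical strategies; the retropubic mid-urethral sling is the
# reference against which all relative effects are expressed.
STRATEGY_IDS: tuple[str, ...] = (
    "retro-MUS",
    "transob-MUS",
    "open-colpo",
    "lap-colpo",
    "trad-sling",
    "single-incision",
    "bladder-neck-needle",
    "anterior-repair",
    "injectable-agents",
)
REFERENCE_STRATEGY = "retro-MUS"
# Re-treatment after a failed surgery is always one of the two mesh slings.
RETREAT_STRATEGIES: tuple[str, str] = ("retro-MUS", "transob-MUS")

_INPATIENT = frozenset(
    {"anterior-repair", "bladder-neck-needle", "open-colpo", "lap-colpo", "trad-sling"}
)

COMPLICATION_NAMES: tuple[str, ...] = (
    "infection",
    "uui-onset",
    "voiding-difficulty",
    "perforation",
    "mesh-removal",
    "short-term-pain",
    "persistent-pain",
)

SCENARIO_KEYS: tuple[str, ...] = (
    "mesh-incidence",
    "persistent-pain-incidence",
    "persistent-pain-duration-years",
    "cure-12m",
    "cure-60m",
)


class SchemaError(ValueError):
    """A required field is missing or the config file cannot be interpreted."""


class ValidationError(ValueError):
    """A structurally complete parameter set violates one or more invariants."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("invalid parameters:\n" + "\n".join(violations))


@dataclass(frozen=True)
class Strategy:
    """A surgical strategy and the setting (day-case vs inpatient) it is
    delivered in, which determines the procedure tariff used."""

    id: str
    setting: str  # "day-case" | "inpatient"


def default_strategies() -> list[Strategy]:
    """The nine strategies with their standard delivery settings."""
    return [
        Strategy(s, "inpatient" if s in _INPATIENT else "day-case")
        for s in STRATEGY_IDS
    ]


@dataclass
class EffectEstimate:
    """Odds ratio of cure for one strategy versus the reference, with its
    95% credible interval from the network meta-analysis."""

    strategy: str
    or_mean: float
    or_median: float
    crl_low: float
    crl_high: float


@dataclass
class BaselineCure:
    """Absolute cure proportion for the reference strategy at one follow-up
    point, with 95% credible interval."""

    time_months: int
    cure_prop: float
    crl_low: float
    crl_high: float


@dataclass
class ComplicationSpec:
    """One severe post-surgical complication.

    ``incidence_by_strategy`` maps strategy id -> probability of onset at
    surgery; strategies absent from the map are assumed not to experience
    the complication.  ``uncertainty`` carries per-strategy beta-distribution
    parameters ``[alpha, beta]`` for probabilistic sampling.
    ``duration_cycles`` is in model cycles (months).
    """

    name: str
    incidence_by_strategy: dict[str, float]
    one_off_cost: float
    utility_decrement: float
    duration_cycles: int
    uncertainty: dict[str, list[float]] = field(default_factory=dict)
    utility_decrement_se: float = 0.0

    def incidence(self, strategy: str) -> float:
        return self.incidence_by_strategy.get(strategy, 0.0)


@dataclass
class RetreatmentPolicy:
    """Policy constants governing repeat surgery after failure."""

    p_seek_first_retreat: float = 0.75
    p_seek_second_retreat: float = 0.30
    retreat_mix_retro: float = 0.55
    retreat_mix_transob: float = 0.45
    retreat_effect_multiplier: float = 0.90
    max_surgeries: int = 3


@dataclass
class EconomicSettings:
    discount_rate_annual: float = 0.035
    horizons: tuple[str, ...] = ("1y", "10y", "lifetime")
    wtp_grid: list[float] = field(
        default_factory=lambda: [float(w) for w in range(1_000, 50_001, 1_000)]
    )
    price_year: str = "2018/19"


@dataclass
class UtilitySet:
    """Health-state utilities (EQ-5D scale). ``se`` holds standard errors
    used when the PSA samples each utility from a beta distribution;
    ``age_adjustment`` is an optional age -> multiplier schedule, off by
    default."""

    u_pre_treatment_sui: float
    u_cured: float
    u_containment: float
    u_uui: float
    se: dict[str, float] = field(default_factory=dict)
    age_adjustment: dict[int, float] | None = None


@dataclass
class UuiLine:
    """One line of the urge-incontinence pathway: bladder training,
    medication, then botulinum toxin A."""

    success_prob: float
    duration_cycles: int
    cost: float


@dataclass
class CostSet:
    """Unit costs in GBP at the configured price year. ``cost_cv`` is the
    coefficient of variation used for gamma sampling in the PSA."""

    procedure_cost: dict[str, float]
    perioperative_cost: float
    containment_cost_per_cycle: float
    cost_cv: float = 0.2


@dataclass
class LifeTable:
    """Female general-population annual death probabilities by single year
    of age. Ages must be contiguous; lookups beyond the last age use the
    final entry."""

    ages: list[int]
    qx: list[float]

    def annual_q(self, age: float) -> float:
        a = int(age)
        if a <= self.ages[0]:
            return self.qx[0]
        if a >= self.ages[-1]:
            return self.qx[-1]
        return self.qx[a - self.ages[0]]

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        ages: list[int] = []
        qx: list[float] = []
        lines = Path(path).read_text().strip().splitlines()
        header = [h.strip().lower() for h in lines[0].split(",")]
        if header != ["age", "qx"]:
            raise SchemaError(f"life table header must be 'age,qx', got {lines[0]!r}")
        for line in lines[1:]:
            a, q = line.split(",")
            ages.append(int(a))
            qx.append(float(q))
        return cls(ages, qx)

    def to_csv(self, path: str | Path) -> None:
        out = ["age,qx"] + [f"{a},{q!r}" for a, q in zip(self.ages, self.qx)]
        Path(path).write_text("\n".join(out) + "\n")


@dataclass
class Population:
    start_age: int = 50
    annual_affected: int = 15_000


@dataclass
class ModelParameters:
    """The complete, validated input set driving one model configuration."""

    strategies: list[Strategy]
    effects: list[EffectEstimate]
    baseline_cure: list[BaselineCure]
    complications: list[ComplicationSpec]
    retreatment: RetreatmentPolicy
    economics: EconomicSettings
    utilities: UtilitySet
    costs: CostSet
    life_table: LifeTable
    uui_pathway: list[UuiLine]
    population: Population = field(default_factory=Population)
    provenance: dict[str, str] = field(default_factory=dict)

    # -- convenience accessors -------------------------------------------
    def effect_for(self, strategy: str) -> EffectEstimate | None:
        for e in self.effects:
            if e.strategy == strategy:
                return e
        return None

    def cure_at(self, time_months: int) -> BaselineCure:
        for b in self.baseline_cure:
            if b.time_months == time_months:
                return b
        raise KeyError(f"no baseline cure entry at {time_months} months")

    def complication(self, name: str) -> ComplicationSpec:
        for c in self.complications:
            if c.name == name:
                return c
        raise KeyError(f"no complication named {name!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("life_table")
        return d


# ---------------------------------------------------------------------------
# Validation

def _prob(x: float) -> bool:
    return 0.0 <= x <= 1.0


def validate_parameters(p: ModelParameters) -> list[str]:
    """Check every type invariant; return a (possibly empty) list of
    violations, each naming the field and the rule broken. Never raises."""
    v: list[str] = []

    ids = [s.id for s in p.strategies]
    if sorted(ids) != sorted(STRATEGY_IDS):
        v.append("strategies: must be exactly the nine known strategies")
    for s in p.strategies:
        expected = "inpatient" if s.id in _INPATIENT else "day-case"
        if s.setting != expected:
            v.append(f"strategies[{s.id}].setting: expected {expected}")

    seen = set()
    for e in p.effects:
        if e.strategy == REFERENCE_STRATEGY:
            v.append("effects: the reference strategy must not carry an odds ratio")
        if e.strategy in seen:
            v.append(f"effects[{e.strategy}]: duplicate entry")
        seen.add(e.strategy)
        if not (0 < e.crl_low <= e.or_median <= e.crl_high):
            v.append(
                f"effects[{e.strategy}]: require 0 < crl_low <= or_median <= crl_high"
            )
        if e.or_mean <= 0:
            v.append(f"effects[{e.strategy}].or_mean: must be positive")
    missing = set(STRATEGY_IDS) - {REFERENCE_STRATEGY} - seen
    if missing:
        v.append(f"effects: missing odds ratios for {sorted(missing)}")

    times = {b.time_months for b in p.baseline_cure}
    if not {12, 60} <= times:
        v.append("baseline_cure: entries at 12 and 60 months are required")
    for b in p.baseline_cure:
        if not (_prob(b.cure_prop) and _prob(b.crl_low) and _prob(b.crl_high)):
            v.append(f"baseline_cure[{b.time_months}m]: proportions must be in [0,1]")
        elif not (b.crl_low <= b.cure_prop <= b.crl_high):
            v.append(f"baseline_cure[{b.time_months}m]: crl_low <= cure_prop <= crl_high")

    for c in p.complications:
        for s, inc in c.incidence_by_strategy.items():
            if s not in STRATEGY_IDS:
                v.append(f"complications[{c.name}]: unknown strategy {s!r}")
            if not _prob(inc):
                v.append(f"complications[{c.name}].incidence[{s}]: must be in [0,1]")
        if not _prob(c.utility_decrement):
            v.append(f"complications[{c.name}].utility_decrement: must be in [0,1]")
        elif c.utility_decrement > p.utilities.u_cured:
            v.append(
                f"complications[{c.name}].utility_decrement: exceeds baseline utility"
            )
        if c.duration_cycles < 0:
            v.append(f"complications[{c.name}].duration_cycles: must be >= 0")
        if c.one_off_cost < 0:
            v.append(f"complications[{c.name}].one_off_cost: must be >= 0")
        if c.utility_decrement_se < 0:
            v.append(f"complications[{c.name}].utility_decrement_se: must be >= 0")
        for s, ab in c.uncertainty.items():
            if len(ab) != 2 or ab[0] <= 0 or ab[1] <= 0:
                v.append(f"complications[{c.name}].uncertainty[{s}]: needs alpha,beta > 0")

    r = p.retreatment
    if abs(r.retreat_mix_retro + r.retreat_mix_transob - 1.0) > 1e-9:
        v.append("retreatment: retreat_mix_retro + retreat_mix_transob must equal 1")
    for name in ("p_seek_first_retreat", "p_seek_second_retreat",
                 "retreat_mix_retro", "retreat_mix_transob"):
        if not _prob(getattr(r, name)):
            v.append(f"retreatment.{name}: must be in [0,1]")
    if not (0 < r.retreat_effect_multiplier <= 1):
        v.append("retreatment.retreat_effect_multiplier: must be in (0,1]")
    if r.max_surgeries != 3:
        v.append("retreatment.max_surgeries: must equal 3")

    e = p.economics
    if e.discount_rate_annual < 0:
        v.append("economics.discount_rate_annual: must be >= 0")
    if any(w <= 0 for w in e.wtp_grid):
        v.append("economics.wtp_grid: values must be > 0")
    if not {20_000.0, 30_000.0} <= {float(w) for w in e.wtp_grid}:
        v.append("economics.wtp_grid: must include 20,000 and 30,000")

    u = p.utilities
    for name in ("u_pre_treatment_sui", "u_cured", "u_containment", "u_uui"):
        if not _prob(getattr(u, name)):
            v.append(f"utilities.{name}: must be in [0,1]")
    if u.u_cured < u.u_pre_treatment_sui:
        v.append("utilities: u_cured must be >= u_pre_treatment_sui")

    lt = p.life_table
    if lt.ages[0] >= 45:
        v.append("life_table: ages must start below 45")
    if lt.ages != list(range(lt.ages[0], lt.ages[-1] + 1)):
        v.append("life_table: ages must be contiguous")
    if any(not _prob(q) for q in lt.qx):
        v.append("life_table.qx: probabilities must be in [0,1]")

    c = p.costs
    for s in STRATEGY_IDS:
        if s not in c.procedure_cost:
            v.append(f"costs.procedure_cost: missing strategy {s}")
        elif c.procedure_cost[s] < 0:
            v.append(f"costs.procedure_cost[{s}]: must be >= 0")
    if c.perioperative_cost < 0:
        v.append("costs.perioperative_cost: must be >= 0")
    if c.containment_cost_per_cycle < 0:
        v.append("costs.containment_cost_per_cycle: must be >= 0")
    if c.cost_cv < 0:
        v.append("costs.cost_cv: must be >= 0")

    if len(p.uui_pathway) != 3:
        v.append("uui_pathway: exactly three treatment lines are required")
    for i, line in enumerate(p.uui_pathway, start=1):
        if not _prob(line.success_prob):
            v.append(f"uui_pathway[line {i}].success_prob: must be in [0,1]")
        if line.duration_cycles < 1:
            v.append(f"uui_pathway[line {i}].duration_cycles: must be >= 1")
        if line.cost < 0:
            v.append(f"uui_pathway[line {i}].cost: must be >= 0")

    if p.population.start_age < lt.ages[0] or p.population.start_age > lt.ages[-1]:
        v.append("population.start_age: outside the life table's age range")
    if p.population.annual_affected <= 0:
        v.append("population.annual_affected: must be > 0")

    return v


# ---------------------------------------------------------------------------
# Serialisation

_REQUIRED_SECTIONS = (
    "strategies",
    "effects",
    "baseline_cure",
    "complications",
    "retreatment",
    "economics",
    "utilities",
    "costs",
    "life_table",
    "uui_pathway",
)


def load_parameters(path: str | Path) -> ModelParameters:
    """Load and validate a model configuration from a YAML file.

    ``life_table`` in the file is a path (relative to the config file) to a
    delimited ``age,qx`` table.  Raises :class:`SchemaError` for missing
    fields and :class:`ValidationError` when invariants are violated.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise SchemaError(f"config {path} did not parse to a mapping")
    for sec in _REQUIRED_SECTIONS:
        if sec not in raw:
            raise SchemaError(f"missing required field: {sec}")

    try:
        strategies = [Strategy(**s) for s in raw["strategies"]]
        effects = [EffectEstimate(**e) for e in raw["effects"]]
        baseline = [BaselineCure(**b) for b in raw["baseline_cure"]]
        comps = [ComplicationSpec(**c) for c in raw["complications"]]
        retreat = RetreatmentPolicy(**raw["retreatment"])
        econ_raw = dict(raw["economics"])
        econ_raw["horizons"] = tuple(econ_raw.get("horizons", ("1y", "10y", "lifetime")))
        econ = EconomicSettings(**econ_raw)
        util = UtilitySet(**raw["utilities"])
        costs = CostSet(**raw["costs"])
        uui = [UuiLine(**l) for l in raw["uui_pathway"]]
        pop = Population(**raw.get("population", {}))
    except TypeError as exc:  # wrong/missing keys inside a section
        raise SchemaError(str(exc)) from exc

    lt_entry = raw["life_table"]
    if isinstance(lt_entry, str):
        life_table = LifeTable.from_csv(path.parent / lt_entry)
    else:
        life_table = LifeTable(ages=list(lt_entry["ages"]), qx=list(lt_entry["qx"]))

    params = ModelParameters(
        strategies=strategies,
        effects=effects,
        baseline_cure=baseline,
        complications=comps,
        retreatment=retreat,
        economics=econ,
        utilities=util,
        costs=costs,
        life_table=life_table,
        uui_pathway=uui,
        population=pop,
        provenance=dict(raw.get("provenance", {})),
    )
    violations = validate_parameters(params)
    if violations:
        raise ValidationError(violations)
    return params


def save_parameters(
    p: ModelParameters,
    config_path: str | Path,
    life_table_filename: str = "life_table.csv",
) -> None:
    """Write a configuration back to YAML + life-table CSV such that
    :func:`load_parameters` round-trips it field-identically."""
    config_path = Path(config_path)
    d = p.to_dict()
    d["economics"]["horizons"] = list(d["economics"]["horizons"])
    d["life_table"] = life_table_filename
    p.life_table.to_csv(config_path.parent / life_table_filename)
    config_path.write_text(yaml.safe_dump(d, sort_keys=False))


# ---------------------------------------------------------------------------
# Scenario modification

def apply_scenario(p: ModelParameters, scenario: dict[str, float]) -> ModelParameters:
    """Return a modified deep copy of ``p`` per a deterministic-sensitivity
    scenario; the original is never mutated and the override is recorded in
    the copy's provenance map.

    Supported keys: ``mesh-incidence`` (mesh-removal incidence for both
    mid-urethral slings), ``persistent-pain-incidence`` (both slings),
    ``persistent-pain-duration-years``, ``cure-12m``, ``cure-60m``.
    """
    unknown = set(scenario) - set(SCENARIO_KEYS)
    if unknown:
        raise ValueError(
            f"unknown scenario key(s) {sorted(unknown)}; supported: {list(SCENARIO_KEYS)}"
        )
    out = copy.deepcopy(p)
    for key, value in scenario.items():
        if key == "mesh-incidence":
            comp = out.complication("mesh-removal")
            for s in RETREAT_STRATEGIES:
                comp.incidence_by_strategy[s] = float(value)
        elif key == "persistent-pain-incidence":
            comp = out.complication("persistent-pain")
            for s in RETREAT_STRATEGIES:
                comp.incidence_by_strategy[s] = float(value)
        elif key == "persistent-pain-duration-years":
            out.complication("persistent-pain").duration_cycles = int(round(value * 12))
        elif key in ("cure-12m", "cure-60m"):
            b = out.cure_at(12 if key == "cure-12m" else 60)
            b.cure_prop = float(value)
            b.crl_low = min(b.crl_low, b.cure_prop)
            b.crl_high = max(b.crl_high, b.cure_prop)
        out.provenance[f"scenario:{key}"] = repr(value)
        logger.info("scenario override %s=%r", key, value)
    return out
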