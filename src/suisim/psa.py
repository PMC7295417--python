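"""Probabilistic sensitivity analysis and value-of-information analysis.

Parameter uncertainty is propagated by Monte-Carlo draws: cure odds ratios
are sampled lognormally from their published medians and credible
intervals, probabilities and utilities from beta distributions, and unit
costs from gamma distributions. Each draw re-runs the microsimulation for
all nine strategies using common random numbers, yielding a rectangular
(draws x strategies) matrix of mean discounted costs and QALYs.

Decision uncertainty is summarised by cost-effectiveness acceptability
curves (probability of maximal net monetary benefit, NMB = WTP*QALY - cost),
the per-person expected value of perfect information

    EVPI = E_theta[max_s NMB_s(theta)] - max_s E_theta[NMB_s(theta)],

its population scaling, and the expected value of partial perfect
information (EVPPI) for named parameter groups, estimated by single-loop
regression of each strategy's NMB on the group's sampled values.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .effects import Z95, sample_odds_ratio
from .microsim import SimContext, simulate_cohort
from .parameters import ModelParameters, STRATEGY_IDS

__all__ = [
    "PsaSample",
    "VoiResult",
    "sample_parameter_set",
    "run_psa",
    "ceac",
    "evpi_per_person",
    "population_evpi",
    "evppi",
    "compute_voi",
    "write_psa_sample",
    "read_psa_sample",
    "write_ceac",
    "write_voi",
]

PARAMETER_GROUPS = {
    "odds_ratios": "or::",
    "baseline_cure": "cure::",
    "complication_incidences": "comp::",
    "utilities": "u::",
    "costs": "cost::",
}

#: effective sample size of the beta prior tying the 60-month cure draw to
#: the 12-month draw (keeps the ordering s60 < s12 by construction)
_CURE_RATIO_ESS = 50.0


# ---------------------------------------------------------------------------
# distribution helpers (method of moments)

def _beta_mm(rng, mean: float, sd: float) -> float:
    """Beta draw matched to (mean, sd); degenerate when sd == 0 or the mean
    sits on a boundary."""
    if sd == 0.0 or mean <= 0.0 or mean >= 1.0:
        return float(mean)
    var = min(sd * sd, mean * (1.0 - mean) * 0.999)
    ess = mean * (1.0 - mean) / var - 1.0
    a, b = mean * ess, (1.0 - mean) * ess
    if a <= 0 or b <= 0:
        raise ValueError(f"invalid beta moments (mean={mean}, sd={sd})")
    return float(rng.beta(a, b))


def _gamma_mm(rng, mean: float, cv: float) -> float:
    """Gamma draw with the given mean and coefficient of variation."""
    if mean == 0.0 or cv == 0.0:
        return float(mean)
    if mean < 0 or cv < 0:
        raise ValueError(f"invalid gamma moments (mean={mean}, cv={cv})")
    shape = 1.0 / (cv * cv)
    return float(rng.gamma(shape, mean / shape))


# ---------------------------------------------------------------------------

def sample_parameter_set(
    p: ModelParameters, rng: np.random.Generator
) -> tuple[ModelParameters, dict[str, float]]:
    """Draw one realisation of every uncertain parameter.

    Returns a realised copy of ``p`` (point fields overwritten with draws)
    and a flat record of the sampled values keyed ``prefix::name`` so VOI
    analyses can regress on them. Fixed parameters pass through unchanged.
    """
    import copy

    out = copy.deepcopy(p)
    rec: dict[str, float] = {}

    # odds ratios ~ lognormal(median, 95% CrI)
    for e in out.effects:
        draw = sample_odds_ratio(e.or_median, e.crl_low, e.crl_high, rng)
        e.or_median = draw
        rec[f"or::{e.strategy}"] = draw

    # reference cure: 12-month ~ beta; 60-month tied via a beta-distributed
    # ratio so the Weibull fit's ordering s60 < s12 always holds
    c12, c60 = out.cure_at(12), out.cure_at(60)
    sd12 = (c12.crl_high - c12.crl_low) / (2.0 * Z95)
    d12 = min(max(_beta_mm(rng, c12.cure_prop, sd12), 1e-4), 1.0 - 1e-4)
    ratio = c60.cure_prop / c12.cure_prop
    if c60.crl_high == c60.crl_low:  # degenerate spec: fixed ratio
        r_sd = 0.0
    else:
        r_sd = math.sqrt(ratio * (1.0 - ratio) / (_CURE_RATIO_ESS + 1.0))
    d60 = d12 * min(max(_beta_mm(rng, ratio, r_sd), 1e-4), 1.0 - 1e-4)
    c12.cure_prop, c60.cure_prop = d12, d60
    c12.crl_low, c12.crl_high = min(c12.crl_low, d12), max(c12.crl_high, d12)
    c60.crl_low, c60.crl_high = min(c60.crl_low, d60), max(c60.crl_high, d60)
    rec["cure::12m"] = d12
    rec["cure::60m"] = d60

    # complication incidences ~ beta(alpha, beta)
    for comp in out.complications:
        for s, ab in comp.uncertainty.items():
            a, b = ab
            if a <= 0 or b <= 0:
                raise ValueError(
                    f"complication {comp.name!r}/{s}: beta parameters must be > 0"
                )
            draw = float(rng.beta(a, b))
            comp.incidence_by_strategy[s] = draw
            rec[f"comp::{comp.name}::{s}"] = draw
        comp.utility_decrement = _beta_mm(
            rng, comp.utility_decrement, comp.utility_decrement_se
        )
        rec[f"u::decr::{comp.name}"] = comp.utility_decrement

    # utilities ~ beta; the pre-treatment utility is sampled as a fraction
    # of the cured utility so u_cured >= u_pre always holds
    u = out.utilities
    se = u.se
    u_cured = _beta_mm(rng, u.u_cured, se.get("u_cured", 0.0))
    frac = u.u_pre_treatment_sui / u.u_cured
    frac_sd = se.get("u_pre_treatment_sui", 0.0) / u.u_cured
    u_pre = u_cured * _beta_mm(rng, frac, frac_sd)
    u.u_cured, u.u_pre_treatment_sui = u_cured, u_pre
    u.u_containment = _beta_mm(rng, u.u_containment, se.get("u_containment", 0.0))
    u.u_uui = _beta_mm(rng, u.u_uui, se.get("u_uui", 0.0))
    rec["u::cured"] = u.u_cured
    rec["u::pre_treatment_sui"] = u.u_pre_treatment_sui
    rec["u::containment"] = u.u_containment
    rec["u::uui"] = u.u_uui

    # costs ~ gamma with configured coefficient of variation
    cv = out.costs.cost_cv
    for s in STRATEGY_IDS:
        out.costs.procedure_cost[s] = _gamma_mm(rng, out.costs.procedure_cost[s], cv)
        rec[f"cost::procedure::{s}"] = out.costs.procedure_cost[s]
    out.costs.perioperative_cost = _gamma_mm(rng, out.costs.perioperative_cost, cv)
    rec["cost::perioperative"] = out.costs.perioperative_cost
    out.costs.containment_cost_per_cycle = _gamma_mm(
        rng, out.costs.containment_cost_per_cycle, cv
    )
    rec["cost::containment"] = out.costs.containment_cost_per_cycle
    for i, line in enumerate(out.uui_pathway, start=1):
        line.cost = _gamma_mm(rng, line.cost, cv)
        rec[f"cost::uui_line{i}"] = line.cost
    for comp in out.complications:
        comp.one_off_cost = _gamma_mm(rng, comp.one_off_cost, cv)
        rec[f"cost::comp::{comp.name}"] = comp.one_off_cost

    return out, rec


@dataclass
class PsaSample:
    """Rectangular PSA output: per-draw, per-strategy mean discounted cost
    and QALYs, with the sampled parameters that produced each draw."""

    strategies: list[str]
    costs: np.ndarray  # (n_draws, n_strategies)
    qalys: np.ndarray
    params: pd.DataFrame  # one row per draw
    seed: int
    horizon: str | int
    n_patients_per_draw: int = 0
    groups: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.costs.shape[0]

    def __post_init__(self):
        self.costs = np.asarray(self.costs, dtype=float)
        self.qalys = np.asarray(self.qalys, dtype=float)
        if self.costs.shape != self.qalys.shape or self.costs.shape[1] != len(
            self.strategies
        ):
            raise ValueError("PSA sample is not rectangular")
        if not self.groups:
            self.groups = _infer_groups(list(self.params.columns))

    def nmb(self, wtp: float) -> np.ndarray:
        return wtp * self.qalys - self.costs


def _infer_groups(columns: list[str]) -> dict[str, list[str]]:
    groups = {
        name: [c for c in columns if c.startswith(prefix)]
        for name, prefix in PARAMETER_GROUPS.items()
    }
    groups = {k: v for k, v in groups.items() if v}
    groups["all"] = list(columns)
    return groups


def run_psa(
    p: ModelParameters,
    n_draws: int,
    n_patients_per_draw: int,
    horizon: str | int,
    seed: int,
) -> PsaSample:
    """Run the full PSA: sample a parameter set per draw, then simulate every
    strategy's cohort under it with common random numbers.

    Patient substreams depend only on ``(seed, patient index)``: every
    strategy — and every draw — sees the same women, so between-draw
    variation reflects parameter uncertainty rather than resampled patient
    noise (and fully degenerate distributions reproduce the base case
    draw for draw).
    """
    if n_draws < 2:
        raise ValueError("n_draws must be >= 2")
    strategies = list(STRATEGY_IDS)
    costs = np.empty((n_draws, len(strategies)))
    qalys = np.empty((n_draws, len(strategies)))
    records = []
    for d in range(n_draws):
        prng = np.random.default_rng(np.random.SeedSequence([int(seed), 777, d]))
        realized, rec = sample_parameter_set(p, prng)
        ctx = SimContext(realized)
        for j, s in enumerate(strategies):
            res = simulate_cohort(
                ctx, s, n_patients_per_draw, horizon, seed=int(seed)
            )
            costs[d, j] = res.mean_cost
            qalys[d, j] = res.mean_qaly
        records.append(rec)
    return PsaSample(
        strategies=strategies,
        costs=costs,
        qalys=qalys,
        params=pd.DataFrame.from_records(records),
        seed=int(seed),
        horizon=horizon,
        n_patients_per_draw=n_patients_per_draw,
    )


# ---------------------------------------------------------------------------
# decision summaries

def ceac(sample: PsaSample, wtp_grid) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves.

    For each willingness-to-pay value, the probability that each strategy
    has the maximal net monetary benefit; exact ties split equally, so the
    probabilities sum to 1 at every threshold.
    """
    wtps = list(wtp_grid)
    if not wtps:
        raise ValueError("wtp grid must be non-empty")
    rows = np.zeros((len(wtps), len(sample.strategies)))
    for i, w in enumerate(wtps):
        nmb = sample.nmb(w)
        best = nmb.max(axis=1, keepdims=True)
        winners = nmb == best
        rows[i] = (winners / winners.sum(axis=1, keepdims=True)).mean(axis=0)
    return pd.DataFrame(rows, index=pd.Index(wtps, name="wtp"), columns=sample.strategies)


def evpi_per_person(sample: PsaSample, wtp: float) -> float:
    """Per-person expected value of perfect information at one threshold."""
    nmb = sample.nmb(wtp)
    return float(nmb.max(axis=1).mean() - nmb.mean(axis=0).max())


def population_evpi(
    per_person: float,
    annual_affected: int,
    years: int,
    discount_rate: float = 0.0,
) -> float:
    """Scale per-person EVPI to the affected population over a number of
    years. Undiscounted by default (an exact multiple of the per-year
    figure); with a positive rate, yearly cohorts are discounted."""
    if per_person < 0 or annual_affected < 0 or years < 0 or discount_rate < 0:
        raise ValueError("all population-EVPI inputs must be >= 0")
    if discount_rate == 0.0:
        return per_person * annual_affected * years
    return per_person * annual_affected * sum(
        (1.0 + discount_rate) ** (-t) for t in range(years)
    )


def evppi(sample: PsaSample, parameter_group: str, wtp: float) -> float:
    """Expected value of partial perfect information for a named parameter
    group, by single-loop regression.

    Each strategy's NMB is regressed on the group's sampled values (cubic
    polynomial for groups of at most two parameters, ridge regression
    otherwise); EVPPI is the mean of the per-draw maximum fitted NMB minus
    the maximum of the mean fitted NMB, clipped into [0, EVPI].
    """
    if parameter_group not in sample.groups:
        raise KeyError(
            f"group {parameter_group!r} not recorded; have {sorted(sample.groups)}"
        )
    from sklearn.linear_model import LinearRegression, Ridge
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import PolynomialFeatures, StandardScaler

    cols = sample.groups[parameter_group]
    X = sample.params[cols].to_numpy(dtype=float)
    # constant columns carry no information and break scaling
    keep = X.std(axis=0) > 0
    nmb = sample.nmb(wtp)
    if not keep.any():
        return 0.0
    X = X[:, keep]
    if X.shape[1] <= 2:
        model = make_pipeline(
            StandardScaler(), PolynomialFeatures(3), LinearRegression()
        )
    else:
        model = make_pipeline(StandardScaler(), Ridge(alpha=1.0))
    fitted = np.column_stack(
        [model.fit(X, nmb[:, j]).predict(X) for j in range(nmb.shape[1])]
    )
    raw = float(fitted.max(axis=1).mean() - fitted.mean(axis=0).max())
    return float(min(max(raw, 0.0), evpi_per_person(sample, wtp)))


@dataclass
class VoiResult:
    """Value-of-information summary at a single willingness-to-pay value."""

    wtp: float
    evpi_per_person: float
    evpi_per_person_qaly: float
    population_evpi: dict[int, float]
    evppi: dict[str, float]


def compute_voi(
    sample: PsaSample,
    wtp: float,
    annual_affected: int,
    years: tuple[int, ...] = (1, 5, 10, 15, 20),
    groups: tuple[str, ...] | None = None,
) -> VoiResult:
    """EVPI, its population scaling and per-group EVPPI at one threshold."""
    per_person = evpi_per_person(sample, wtp)
    if groups is None:
        groups = tuple(g for g in sample.groups if g != "all")
    return VoiResult(
        wtp=wtp,
        evpi_per_person=per_person,
        evpi_per_person_qaly=per_person / wtp,
        population_evpi={y: population_evpi(per_person, annual_affected, y) for y in years},
        evppi={g: evppi(sample, g, wtp) for g in groups},
    )


# ---------------------------------------------------------------------------
# delimited-text persistence (re-run VOI without re-simulating)

def write_psa_sample(sample: PsaSample, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    long = pd.DataFrame(
        {
            "draw": np.repeat(np.arange(sample.n_draws), len(sample.strategies)),
            "strategy": np.tile(sample.strategies, sample.n_draws),
            "cost": sample.costs.ravel(),
            "qaly": sample.qalys.ravel(),
        }
    )
    long.to_csv(out / "psa_values.csv", index=False)
    sample.params.to_csv(out / "psa_params.csv", index=False)
    (out / "psa_meta.json").write_text(
        json.dumps(
            {
                "strategies": sample.strategies,
                "seed": sample.seed,
                "horizon": sample.horizon,
                "n_patients_per_draw": sample.n_patients_per_draw,
            }
        )
    )


def read_psa_sample(in_dir) -> PsaSample:
    src = Path(in_dir)
    meta = json.loads((src / "psa_meta.json").read_text())
    long = pd.read_csv(src / "psa_values.csv")
    params = pd.read_csv(src / "psa_params.csv")
    strategies = meta["strategies"]
    n_draws = long["draw"].nunique()
    costs = long.pivot(index="draw", columns="strategy", values="cost")[strategies]
    qalys = long.pivot(index="draw", columns="strategy", values="qaly")[strategies]
    return PsaSample(
        strategies=strategies,
        costs=costs.to_numpy(),
        qalys=qalys.to_numpy(),
        params=params,
        seed=meta["seed"],
        horizon=meta["horizon"],
        n_patients_per_draw=meta["n_patients_per_draw"],
    )


def write_ceac(curves: pd.DataFrame, path) -> None:
    curves.to_csv(path, sep="\t", float_format="%.6g")


def write_voi(results: list[VoiResult], path) -> None:
    rows = []
    for r in results:
        row = {
            "wtp": r.wtp,
            "evpi_per_person": r.evpi_per_person,
            "evpi_per_person_qaly": r.evpi_per_person_qaly,
        }
        for y, v in sorted(r.population_evpi.items()):
            row[f"population_evpi_{y}y"] = v
        for g, v in sorted(r.evppi.items()):
            row[f"evppi_{g}"] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")
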