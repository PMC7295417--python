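"""Discounting, incremental cost-effectiveness ratios and dominance.

Strategies are ranked by ascending mean cost. A strategy is *dominated*
when some alternative is no more costly and no less effective (strictly
better on at least one axis); *extendedly dominated* strategies — those
lying above the line joining their cheaper and more effective neighbours
on the cost-effectiveness plane — are removed from the efficient frontier
by a repeated sweep. ICERs (Δcost/ΔQALY) are computed between successive
frontier members and are strictly increasing along the frontier.
"""

from __future__ import annotations

import math
from typing import Sequence

import pandas as pd

from .microsim import CohortResult

__all__ = [
    "discount_factor",
    "compute_icers",
    "write_icer_table",
    "LABEL_REFERENCE",
    "LABEL_DOMINATED",
    "LABEL_EXT_DOMINATED",
]

LABEL_REFERENCE = "reference"
LABEL_DOMINATED = "Dominated"
LABEL_EXT_DOMINATED = "Extendedly dominated"


def discount_factor(rate_annual: float, t_years: float) -> float:
    """(1 + rate)^(-t); 1 at t = 0 and for a zero rate."""
    if rate_annual < 0:
        raise ValueError("discount rate must be >= 0")
    if t_years < 0:
        raise ValueError("time must be >= 0")
    return (1.0 + rate_annual) ** (-t_years)


def _as_frame(results: Sequence[CohortResult] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(results, pd.DataFrame):
        return results[["strategy", "cost", "qaly"]].copy()
    return pd.DataFrame(
        {
            "strategy": [r.strategy for r in results],
            "cost": [r.mean_cost for r in results],
            "qaly": [r.mean_qaly for r in results],
        }
    )


def compute_icers(results: Sequence[CohortResult] | pd.DataFrame) -> pd.DataFrame:
    """Build the ICER/dominance table from per-strategy mean costs and QALYs.

    Accepts a list of :class:`CohortResult` or a DataFrame with columns
    ``strategy, cost, qaly``. Returns a DataFrame ordered by ascending
    cost with columns ``strategy, cost, qaly, inc_cost, inc_qaly, icer,
    label``; ``icer`` is NaN off the frontier and +inf when ΔQALY is zero.
    """
    df = _as_frame(results)
    if len(df) < 2:
        raise ValueError("at least two strategies are required")
    if df["strategy"].duplicated().any():
        raise ValueError("duplicate strategy rows")
    df = df.sort_values(["cost", "qaly"], ascending=[True, False]).reset_index(drop=True)

    # strict dominance
    dominated = []
    for i in range(len(df)):
        ci, qi = df.loc[i, "cost"], df.loc[i, "qaly"]
        dom = any(
            (df.loc[j, "cost"] <= ci and df.loc[j, "qaly"] >= qi)
            and (df.loc[j, "cost"] < ci or df.loc[j, "qaly"] > qi)
            for j in range(len(df))
            if j != i
        )
        dominated.append(dom)
    df["label"] = [LABEL_DOMINATED if d else "" for d in dominated]

    # extended dominance: repeated sweep over the cost-ordered candidates
    frontier = [i for i in range(len(df)) if not dominated[i]]
    changed = True
    while changed and len(frontier) > 2:
        changed = False
        for k in range(1, len(frontier) - 1):
            a, b, c = frontier[k - 1], frontier[k], frontier[k + 1]
            icer_ab = _pair_icer(df, a, b)
            icer_bc = _pair_icer(df, b, c)
            if icer_ab >= icer_bc:
                df.loc[b, "label"] = LABEL_EXT_DOMINATED
                frontier.pop(k)
                changed = True
                break

    df["inc_cost"] = math.nan
    df["inc_qaly"] = math.nan
    df["icer"] = math.nan
    df.loc[frontier[0], "label"] = LABEL_REFERENCE
    for prev, cur in zip(frontier, frontier[1:]):
        dc = df.loc[cur, "cost"] - df.loc[prev, "cost"]
        dq = df.loc[cur, "qaly"] - df.loc[prev, "qaly"]
        df.loc[cur, "inc_cost"] = dc
        df.loc[cur, "inc_qaly"] = dq
        df.loc[cur, "icer"] = dc / dq if dq > 0 else math.inf
        if dq <= 0:
            df.loc[cur, "label"] = "ICER undefined (zero QALY gain)"

    return df[["strategy", "cost", "qaly", "inc_cost", "inc_qaly", "icer", "label"]]


def _pair_icer(df: pd.DataFrame, i: int, j: int) -> float:
    dq = df.loc[j, "qaly"] - df.loc[i, "qaly"]
    dc = df.loc[j, "cost"] - df.loc[i, "cost"]
    return dc / dq if dq > 0 else math.inf


def write_icer_table(table: pd.DataFrame, path) -> None:
    """Write the ICER table as tab-delimited text."""
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
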