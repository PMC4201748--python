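"""QALY and cost accounting per arm, and the two-strategy comparison.

Perspectives: the healthcare-system perspective counts medication plus
direct care costs only; the societal perspective adds indirect (informal
care) costs, which accrue in the community state only.  The dead state
accrues nothing.  Medication is charged for every year alive in either
living state (lifelong-treatment assumption — conservative, since it
overstates the cost of the more expensive arm without inflating its
effectiveness).

The comparison is always alternative minus reference.  A strategy that is
cheaper and more effective is *dominant*; costlier and less effective,
*dominated*; otherwise the incremental cost-effectiveness ratio (ICER)
delta_cost / delta_QALY applies, judged against a willingness-to-pay (WTP)
threshold via the net monetary benefit NMB = WTP * delta_QALY - delta_cost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .markov import run_trace, state_time, survival_at
from .parameters import CostTable, ModelSpec, StrategySpec, UtilitySet

__all__ = [
    "EconomicResult",
    "Comparison",
    "qalys",
    "arm_costs",
    "evaluate_arm",
    "compare",
    "net_monetary_benefit",
    "base_case_table",
]

HEALTHCARE = "healthcare"
SOCIETAL = "societal"
PERSPECTIVES = (HEALTHCARE, SOCIETAL)


@dataclass(frozen=True)
class EconomicResult:
    """Discounted outcomes for one arm over the model horizon."""

    strategy_name: str
    time_alive: float
    time_community: float
    time_institution: float
    qalys: float
    cost_healthcare: float
    cost_societal: float

    def cost(self, perspective: str) -> float:
        if perspective == HEALTHCARE:
            return self.cost_healthcare
        if perspective == SOCIETAL:
            return self.cost_societal
        raise KeyError(f"unknown perspective {perspective!r}; expected one of {PERSPECTIVES}")


@dataclass(frozen=True)
class Comparison:
    """Incremental result, alternative minus reference."""

    perspective: str
    delta_cost: float
    delta_qalys: float
    classification: str  # "dominant" | "dominated" | "icer" | "undefined"
    icer_value: float = math.nan

    @property
    def is_dominant(self) -> bool:
        return self.classification == "dominant"


def qalys(time_community: float, time_institution: float, utilities: UtilitySet) -> float:
    """Utility-weighted life years: u_comm * t_comm + u_inst * t_inst."""
    if time_community < 0 or time_institution < 0:
        raise ValueError("state times must be non-negative")
    return utilities.u_community * time_community + utilities.u_institution * time_institution


def arm_costs(
    time_alive: float,
    time_community: float,
    time_institution: float,
    strategy: StrategySpec,
    costs: CostTable,
) -> tuple[float, float]:
    """Total discounted cost of one arm from both perspectives.

    Returns ``(cost_healthcare, cost_societal)``:

    * healthcare = medication * time_alive
      + community_direct_other * time_community
      + institution_direct_other * time_institution
    * societal = healthcare + community_indirect * time_community
    """
    healthcare = (
        strategy.annual_medication_cost * time_alive
        + costs.community_direct_other * time_community
        + costs.institution_direct_other * time_institution
    )
    societal = healthcare + costs.community_indirect * time_community
    return healthcare, societal


def evaluate_arm(spec: ModelSpec, strategy: StrategySpec | str | int) -> EconomicResult:
    """Full pipeline for one arm: trace -> discounted times -> QALYs, costs."""
    trace = run_trace(spec, strategy)
    strat = next(s for s in spec.strategies if s.name == trace.strategy_name)
    t_comm = state_time(trace, "community", spec.discount)
    t_inst = state_time(trace, "institution", spec.discount)
    q = qalys(t_comm, t_inst, spec.utilities)
    healthcare, societal = arm_costs(t_comm + t_inst, t_comm, t_inst, strat, spec.costs)
    return EconomicResult(
        strategy_name=strat.name,
        time_alive=t_comm + t_inst,
        time_community=t_comm,
        time_institution=t_inst,
        qalys=q,
        cost_healthcare=healthcare,
        cost_societal=societal,
    )


def compare(
    reference: EconomicResult, alternative: EconomicResult, perspective: str = HEALTHCARE
) -> Comparison:
    """Incremental comparison of the alternative against the reference.

    Classification: *dominant* (cheaper, more effective), *dominated*
    (costlier, less effective), *icer* otherwise; a zero QALY difference
    with a nonzero cost difference yields the *undefined* sentinel rather
    than a division blow-up.
    """
    dc = alternative.cost(perspective) - reference.cost(perspective)
    dq = alternative.qalys - reference.qalys
    if dc < 0 and dq > 0:
        return Comparison(perspective, dc, dq, "dominant")
    if dc > 0 and dq < 0:
        return Comparison(perspective, dc, dq, "dominated")
    if dq == 0:
        return Comparison(perspective, dc, dq, "undefined", math.nan)
    return Comparison(perspective, dc, dq, "icer", dc / dq)


def net_monetary_benefit(comparison: Comparison, wtp: float) -> float:
    """NMB = wtp * delta_QALY - delta_cost; positive means cost-effective."""
    if wtp < 0:
        raise ValueError(f"willingness-to-pay must be non-negative, got {wtp}")
    return wtp * comparison.delta_qalys - comparison.delta_cost


def base_case_table(spec: ModelSpec) -> pd.DataFrame:
    """Incremental cost-effectiveness table for the spec's two arms.

    One row per arm plus an incremental row: survival years, % alive at the
    horizon, time in community, QALYs, and total cost per perspective, all
    at the spec's discounting.  Mirrors the standard base-case presentation
    of a two-strategy cost-effectiveness analysis.
    """
    rows = []
    results = []
    for strat in spec.strategies:
        trace = run_trace(spec, strat)
        res = evaluate_arm(spec, strat)
        results.append(res)
        rows.append(
            {
                "strategy": strat.name,
                "survival_years": res.time_alive,
                "survival_at_horizon_pct": 100.0 * survival_at(trace, spec.horizon_cycles),
                "time_in_community_years": res.time_community,
                "qalys": res.qalys,
                "cost_healthcare_eur": res.cost_healthcare,
                "cost_societal_eur": res.cost_societal,
            }
        )
    ref, alt = results
    comps = {p: compare(ref, alt, p) for p in PERSPECTIVES}
    rows.append(
        {
            "strategy": "incremental",
            "survival_years": alt.time_alive - ref.time_alive,
            "survival_at_horizon_pct": rows[1]["survival_at_horizon_pct"]
            - rows[0]["survival_at_horizon_pct"],
            "time_in_community_years": alt.time_community - ref.time_community,
            "qalys": alt.qalys - ref.qalys,
            "cost_healthcare_eur": comps[HEALTHCARE].delta_cost,
            "cost_societal_eur": comps[SOCIETAL].delta_cost,
        }
    )
    icer_row = {"strategy": "ICER"}
    for p, col in ((HEALTHCARE, "cost_healthcare_eur"), (SOCIETAL, "cost_societal_eur")):
        c = comps[p]
        icer_row[col] = c.classification if c.classification != "icer" else round(c.icer_value)
    rows.append(icer_row)
    return pd.DataFrame(rows)
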