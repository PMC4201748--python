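"""Markov cohort engine: trace computation and time-in-state accounting.

Three states — community (non-institutionalised), institution (nursing
home), dead.  The whole cohort starts in the community.  Institution is
absorbing apart from death; dead is absorbing.  The printed annual
probabilities are treated as mutually exclusive marginal one-year transition
probabilities: from community a patient dies with ``p_death``, is
institutionalised with ``p_inst``, and stays with ``1 - p_inst - p_death``;
from institution, dies with ``p_death``.  Mortality is shared by both living
states, so the alive fraction at boundary ``t`` is exactly
``prod(1 - p_death[:t])`` regardless of the institutionalisation schedule —
treatment shifts *where* patients live, never how long.

Time in state is accumulated over the horizon with optional annual
discounting (factor ``(1 + r) ** -t`` at boundary ``t``) and an optional
half-cycle correction, implemented as the trapezoid rule on the discounted
occupancy series: each cycle credits half the occupancy at its start plus
half at its end, reducing the discretization bias of pure end-of-cycle
counting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import DiscountSpec, ModelSpec, StrategySpec, validate_spec

__all__ = [
    "STATES",
    "CohortTrace",
    "cycle_transition",
    "run_trace",
    "state_time",
    "survival_at",
]

#: Column order of every occupancy array.
STATES = ("community", "institution", "dead")
_STATE_INDEX = {name: i for i, name in enumerate(STATES)}


def cycle_transition(
    state: tuple[float, float, float] | np.ndarray,
    p_inst: float,
    p_death: float,
) -> np.ndarray:
    """Advance a state-occupancy vector by one cycle.

    Parameters
    ----------
    state
        ``(community, institution, dead)`` fractions summing to 1.
    p_inst
        Conditional probability of institutionalisation for a community
        patient this cycle.
    p_death
        Conditional probability of death for any living patient this cycle.

    Returns
    -------
    numpy.ndarray
        The occupancy vector after the cycle; sums to 1.
    """
    if p_inst + p_death > 1.0 + 1e-12:
        raise ValueError(f"p_inst + p_death = {p_inst + p_death:.6f} > 1")
    community, institution, dead = (float(x) for x in state)
    new_community = community * (1.0 - p_inst - p_death)
    new_institution = institution * (1.0 - p_death) + community * p_inst
    new_dead = dead + (community + institution) * p_death
    return np.array([new_community, new_institution, new_dead])


@dataclass(frozen=True)
class CohortTrace:
    """State occupancy at every cycle boundary ``t = 0..horizon``.

    ``occupancy`` has shape ``(horizon + 1, 3)`` with columns ordered as
    :data:`STATES`; row 0 is the all-community start ``(1, 0, 0)``.
    """

    occupancy: np.ndarray
    strategy_name: str = ""

    @property
    def horizon(self) -> int:
        return self.occupancy.shape[0] - 1

    def state(self, name: str) -> np.ndarray:
        """Occupancy series for one state (length horizon + 1)."""
        try:
            return self.occupancy[:, _STATE_INDEX[name]]
        except KeyError:
            raise KeyError(f"unknown state {name!r}; expected one of {STATES}") from None

    def to_frame(self, discount: DiscountSpec | None = None) -> pd.DataFrame:
        """Tabular view, one row per cycle boundary, for export/plotting.

        When ``discount`` is given, discounted occupancy columns are added.
        """
        df = pd.DataFrame(self.occupancy, columns=list(STATES))
        df.insert(0, "cycle", np.arange(self.horizon + 1))
        if discount is not None:
            d = _discount_factors(self.horizon, discount.rate)
            for name in STATES[:2]:
                df[f"{name}_discounted"] = df[name].to_numpy() * d
        return df


def run_trace(spec: ModelSpec, strategy: StrategySpec | str | int) -> CohortTrace:
    """Run the cohort through the horizon for one treatment arm.

    ``strategy`` may be the :class:`StrategySpec` itself, its name, or its
    index within ``spec.strategies``.
    """
    violations = validate_spec(spec)
    if violations:
        raise ValueError("invalid ModelSpec: " + "; ".join(violations))
    strat = _resolve_strategy(spec, strategy)
    h = spec.horizon_cycles
    occ = np.empty((h + 1, 3))
    occ[0] = (1.0, 0.0, 0.0)
    for t in range(1, h + 1):
        occ[t] = cycle_transition(
            occ[t - 1],
            strat.p_institutionalisation[t - 1],
            spec.mortality.p_death[t - 1],
        )
    return CohortTrace(occupancy=occ, strategy_name=strat.name)


def _resolve_strategy(spec: ModelSpec, strategy: StrategySpec | str | int) -> StrategySpec:
    if isinstance(strategy, StrategySpec):
        return strategy
    if isinstance(strategy, int):
        return spec.strategies[strategy]
    for s in spec.strategies:
        if s.name == strategy:
            return s
    raise KeyError(f"no strategy named {strategy!r} in spec")


def _discount_factors(horizon: int, rate: float) -> np.ndarray:
    return (1.0 + rate) ** -np.arange(horizon + 1, dtype=float)


def state_time(trace: CohortTrace, state: str, discount: DiscountSpec) -> float:
    """Discounted years spent in a state over the trace's horizon.

    With half-cycle correction on (the default), the trapezoid rule is
    applied to the discounted occupancy series::

        sum_{t=1..H} 0.5 * (d(t-1) * occ(t-1) + d(t) * occ(t))

    with ``d(t) = (1 + rate) ** -t``.  With the correction off, only
    end-of-cycle occupancy is counted: ``sum_{t=1..H} d(t) * occ(t)``.

    ``state`` may also be ``"alive"`` (community + institution).
    """
    if state == "alive":
        occ = trace.state("community") + trace.state("institution")
    else:
        occ = trace.state(state)
    d = _discount_factors(trace.horizon, discount.rate)
    series = occ * d
    if discount.half_cycle_correction:
        return float(0.5 * (series[:-1] + series[1:]).sum())
    return float(series[1:].sum())


def survival_at(trace: CohortTrace, cycle: int) -> float:
    """Fraction of the cohort alive at a cycle boundary."""
    if not 0 <= cycle <= trace.horizon:
        raise IndexError(f"cycle {cycle} outside [0, {trace.horizon}]")
    return float(trace.occupancy[cycle, 0] + trace.occupancy[cycle, 1])
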