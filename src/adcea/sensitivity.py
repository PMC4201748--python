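"""Deterministic and probabilistic sensitivity analysis.

Deterministic sensitivity analysis (DSA): 18 one-at-a-time scenarios —
the base case; +/-20 % on each cost and utility group; 50 % and 200 % on
the institutionalisation probabilities of both arms jointly; a worst case
(reference arm halved, alternative doubled) and a best case (the reverse);
a constant-hazard smoothed institutionalisation schedule per arm; and 50 %
/ 200 % on the death probabilities.  Each scenario perturbs exactly one
parameter group and the full pipeline (trace -> economics -> comparison)
is re-run from both cost perspectives.

Probabilistic sensitivity analysis (PSA): Monte-Carlo sampling with
triangular distributions — mode at the base value, bounds at 80 %/120 %
for costs and utilities and at 50 %/200 % (the worst/best-case range) for
the institutionalisation multipliers, one multiplier per arm per draw.
Death probabilities are held fixed by default since the deterministic
ranges assign distributions only to costs, utilities and
institutionalisation; a triangular death multiplier can be switched on.
Draws producing an invalid parameterization (e.g. ``p_inst + p_death > 1``)
are rejected and resampled, with the rejection count reported.

The decision summary is the proportion of draws in which the alternative
is dominant and the proportion in which it is cost-effective (positive net
monetary benefit) at each willingness-to-pay threshold, plus a
cost-effectiveness acceptability curve (CEAC) over a WTP grid.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .economics import PERSPECTIVES, compare, evaluate_arm, net_monetary_benefit
from .parameters import (
    ModelSpec,
    MortalitySchedule,
    StrategySpec,
    UtilitySet,
    smooth_institutionalisation,
    validate_spec,
)

__all__ = [
    "ScenarioSpec",
    "PSADistributions",
    "PSAResult",
    "build_paper_scenarios",
    "apply_scenario",
    "run_dsa",
    "sample_triangular",
    "run_psa",
    "ceac",
]

#: Parameter groups a scenario may target.
SCENARIO_TARGETS = (
    "base",
    "community_direct",
    "community_indirect",
    "institution_direct",
    "u_community",
    "u_institution",
    "p_inst_both_arms",
    "p_inst_worst",
    "p_inst_best",
    "p_inst_smoothed",
    "p_death",
)


@dataclass(frozen=True)
class ScenarioSpec:
    """One deterministic-sensitivity perturbation of a model spec.

    ``target`` names the parameter group; ``multiplier`` scales it (ignored
    by the structural targets ``base``, ``p_inst_worst``, ``p_inst_best``
    and ``p_inst_smoothed``, whose transforms are fixed).
    """

    id: int
    label: str
    target: str
    multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.target not in SCENARIO_TARGETS:
            raise ValueError(f"unknown target {self.target!r}")
        if self.multiplier <= 0:
            raise ValueError(f"multiplier must be positive, got {self.multiplier}")


def build_paper_scenarios() -> list[ScenarioSpec]:
    """The standard 18-scenario deterministic sensitivity design.

    Scenario 1 is the untouched base case; 2–11 apply ±20 % to one cost or
    utility group at a time; 12–16 perturb the institutionalisation
    schedules (joint halving/doubling, worst case, best case, constant-
    hazard smoothing); 17–18 halve/double the death schedule.
    """
    s = ScenarioSpec
    return [
        s(1, "base case", "base"),
        s(2, "community direct costs -20%", "community_direct", 0.8),
        s(3, "community direct costs +20%", "community_direct", 1.2),
        s(4, "indirect costs -20%", "community_indirect", 0.8),
        s(5, "indirect costs +20%", "community_indirect", 1.2),
        s(6, "institution direct costs -20%", "institution_direct", 0.8),
        s(7, "institution direct costs +20%", "institution_direct", 1.2),
        s(8, "community utility -20%", "u_community", 0.8),
        s(9, "community utility +20%", "u_community", 1.2),
        s(10, "institution utility -20%", "u_institution", 0.8),
        s(11, "institution utility +20%", "u_institution", 1.2),
        s(12, "institutionalisation probabilities x0.5 (both arms)", "p_inst_both_arms", 0.5),
        s(13, "institutionalisation probabilities x2 (both arms)", "p_inst_both_arms", 2.0),
        s(14, "worst case (reference x0.5, alternative x2)", "p_inst_worst"),
        s(15, "best case (reference x2, alternative x0.5)", "p_inst_best"),
        s(16, "constant-hazard smoothed institutionalisation", "p_inst_smoothed"),
        s(17, "death probabilities x0.5", "p_death", 0.5),
        s(18, "death probabilities x2", "p_death", 2.0),
    ]


def _scale_strategy(strat: StrategySpec, factor: float) -> StrategySpec:
    return dataclasses.replace(
        strat,
        p_institutionalisation=tuple(p * factor for p in strat.p_institutionalisation),
    )


def _smooth_strategy(strat: StrategySpec, horizon: int) -> StrategySpec:
    p = smooth_institutionalisation(strat.p_institutionalisation, horizon)
    return dataclasses.replace(strat, p_institutionalisation=(p,) * horizon)


def apply_scenario(spec: ModelSpec, scenario: ScenarioSpec) -> ModelSpec:
    """Return a new spec with the scenario's parameter group transformed.

    The input spec is never modified.  Raises if the transformed spec no
    longer validates (e.g. scaled probabilities exceeding 1).
    """
    t, m = scenario.target, scenario.multiplier
    ref, alt = spec.strategies
    new = spec
    if t == "base":
        pass
    elif t == "community_direct":
        new = dataclasses.replace(
            spec,
            costs=dataclasses.replace(
                spec.costs, community_direct_other=spec.costs.community_direct_other * m
            ),
        )
    elif t == "community_indirect":
        new = dataclasses.replace(
            spec,
            costs=dataclasses.replace(
                spec.costs, community_indirect=spec.costs.community_indirect * m
            ),
        )
    elif t == "institution_direct":
        new = dataclasses.replace(
            spec,
            costs=dataclasses.replace(
                spec.costs, institution_direct_other=spec.costs.institution_direct_other * m
            ),
        )
    elif t == "u_community":
        new = dataclasses.replace(
            spec,
            utilities=UtilitySet(spec.utilities.u_community * m, spec.utilities.u_institution),
        )
    elif t == "u_institution":
        new = dataclasses.replace(
            spec,
            utilities=UtilitySet(spec.utilities.u_community, spec.utilities.u_institution * m),
        )
    elif t == "p_inst_both_arms":
        new = dataclasses.replace(
            spec, strategies=(_scale_strategy(ref, m), _scale_strategy(alt, m))
        )
    elif t == "p_inst_worst":
        new = dataclasses.replace(
            spec, strategies=(_scale_strategy(ref, 0.5), _scale_strategy(alt, 2.0))
        )
    elif t == "p_inst_best":
        new = dataclasses.replace(
            spec, strategies=(_scale_strategy(ref, 2.0), _scale_strategy(alt, 0.5))
        )
    elif t == "p_inst_smoothed":
        h = spec.horizon_cycles
        new = dataclasses.replace(
            spec, strategies=(_smooth_strategy(ref, h), _smooth_strategy(alt, h))
        )
    elif t == "p_death":
        new = dataclasses.replace(
            spec,
            mortality=MortalitySchedule(tuple(p * m for p in spec.mortality.p_death)),
        )
    violations = validate_spec(new)
    if violations:
        raise ValueError(
            f"scenario {scenario.id} ({scenario.label}) produced an invalid spec: "
            + "; ".join(violations)
        )
    return new


def run_dsa(
    spec: ModelSpec,
    scenarios: Sequence[ScenarioSpec] | None = None,
    wtps: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Run every scenario from both perspectives.

    Returns one row per scenario-perspective pair with the incremental cost
    and QALYs, the dominance classification, the ICER where defined, and a
    cost-effectiveness flag (positive net monetary benefit) per WTP
    threshold.
    """
    if scenarios is None:
        scenarios = build_paper_scenarios()
    if wtps is None:
        wtps = spec.wtp_thresholds
    rows = []
    for scen in scenarios:
        s = apply_scenario(spec, scen)
        ref = evaluate_arm(s, 0)
        alt = evaluate_arm(s, 1)
        for persp in PERSPECTIVES:
            c = compare(ref, alt, persp)
            row = {
                "scenario_id": scen.id,
                "label": scen.label,
                "perspective": persp,
                "delta_cost": c.delta_cost,
                "delta_qalys": c.delta_qalys,
                "classification": c.classification,
                "icer": c.icer_value,
            }
            for w in wtps:
                row[f"ce_at_{w:.0f}"] = net_monetary_benefit(c, w) > 0
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis

def sample_triangular(
    low: float, mode: float, high: float, rng: np.random.Generator
) -> float:
    """One draw from a triangular(low, mode, high) via the inverse CDF.

    Degenerate widths are allowed: if ``low == high`` the mode is returned
    deterministically (a point mass), still consuming one uniform draw so
    that the stream position does not depend on parameter values.
    """
    if not low <= mode <= high:
        raise ValueError(f"need low <= mode <= high, got ({low}, {mode}, {high})")
    u = rng.random()
    span = high - low
    if span == 0.0:
        return mode
    c = (mode - low) / span
    if u < c:
        return low + np.sqrt(u * span * (mode - low))
    return high - np.sqrt((1.0 - u) * span * (high - mode))


@dataclass(frozen=True)
class PSADistributions:
    """Triangular (low, mode, high) multipliers applied to the base values.

    ``cost_rel`` and ``utility_rel`` scale each cost/utility group;
    ``p_inst_rel`` scales each arm's institutionalisation series (one
    multiplier per arm per draw by default, per-year independent
    multipliers if ``per_year_p_inst``).  The death schedule is fixed
    unless ``vary_death``.
    """

    cost_rel: tuple[float, float, float] = (0.8, 1.0, 1.2)
    utility_rel: tuple[float, float, float] = (0.8, 1.0, 1.2)
    p_inst_rel: tuple[float, float, float] = (0.5, 1.0, 2.0)
    vary_death: bool = False
    death_rel: tuple[float, float, float] = (0.5, 1.0, 2.0)
    per_year_p_inst: bool = False

    def __post_init__(self) -> None:
        for name in ("cost_rel", "utility_rel", "p_inst_rel", "death_rel"):
            low, mode, high = getattr(self, name)
            if not low <= mode <= high:
                raise ValueError(f"{name}: need low <= mode <= high, got ({low}, {mode}, {high})")

    @classmethod
    def degenerate(cls) -> "PSADistributions":
        """Point masses at the base values (PSA collapses to the base case)."""
        one = (1.0, 1.0, 1.0)
        return cls(cost_rel=one, utility_rel=one, p_inst_rel=one, death_rel=one)


@dataclass(frozen=True)
class PSAResult:
    """Per-draw incremental outcomes plus decision-uncertainty summaries."""

    n_draws: int
    seed: int
    n_rejected: int
    wtps: tuple[float, ...]
    draws: pd.DataFrame  # delta_qalys, delta_cost_healthcare, delta_cost_societal
    proportion_dominant: dict[str, float] = field(default_factory=dict)
    proportion_cost_effective: dict[str, dict[float, float]] = field(default_factory=dict)


def _sample_spec(
    spec: ModelSpec, dists: PSADistributions, rng: np.random.Generator
) -> ModelSpec:
    """Draw one parameter set.  May violate joint probability constraints."""
    lo, mo, hi = dists.cost_rel
    costs = dataclasses.replace(
        spec.costs,
        community_direct_other=spec.costs.community_direct_other
        * sample_triangular(lo, mo, hi, rng),
        community_indirect=spec.costs.community_indirect * sample_triangular(lo, mo, hi, rng),
        institution_direct_other=spec.costs.institution_direct_other
        * sample_triangular(lo, mo, hi, rng),
    )
    lo, mo, hi = dists.utility_rel
    utilities = UtilitySet(
        u_community=spec.utilities.u_community * sample_triangular(lo, mo, hi, rng),
        u_institution=spec.utilities.u_institution * sample_triangular(lo, mo, hi, rng),
    )
    lo, mo, hi = dists.p_inst_rel
    h = spec.horizon_cycles
    strategies = []
    for strat in spec.strategies:
        if dists.per_year_p_inst:
            mult = np.array([sample_triangular(lo, mo, hi, rng) for _ in range(h)])
        else:
            mult = np.full(h, sample_triangular(lo, mo, hi, rng))
        strategies.append(
            dataclasses.replace(
                strat,
                p_institutionalisation=tuple(
                    p * m for p, m in zip(strat.p_institutionalisation, mult)
                ),
            )
        )
    mortality = spec.mortality
    if dists.vary_death:
        lo, mo, hi = dists.death_rel
        m = sample_triangular(lo, mo, hi, rng)
        mortality = MortalitySchedule(tuple(p * m for p in spec.mortality.p_death))
    return dataclasses.replace(
        spec,
        costs=costs,
        utilities=utilities,
        strategies=(strategies[0], strategies[1]),
        mortality=mortality,
    )


def run_psa(
    spec: ModelSpec,
    dists: PSADistributions | None = None,
    n: int = 10_000,
    seed: int = 20130809,
    wtps: Sequence[float] | None = None,
) -> PSAResult:
    """Monte-Carlo PSA: sample, rebuild, run both arms, summarize.

    Invalid draws (specs failing validation) are rejected and resampled;
    the count is reported in the result.  Fully reproducible from ``seed``.
    """
    if n < 1:
        raise ValueError(f"need at least one draw, got n={n}")
    if dists is None:
        dists = PSADistributions()
    if wtps is None:
        wtps = spec.wtp_thresholds
    wtps = tuple(float(w) for w in wtps)
    rng = np.random.default_rng(seed)
    records = np.empty((n, 3))
    n_rejected = 0
    for i in range(n):
        while True:
            cand = _sample_spec(spec, dists, rng)
            if not validate_spec(cand):
                break
            n_rejected += 1
        ref = evaluate_arm(cand, 0)
        alt = evaluate_arm(cand, 1)
        records[i] = (
            alt.qalys - ref.qalys,
            alt.cost_healthcare - ref.cost_healthcare,
            alt.cost_societal - ref.cost_societal,
        )
    draws = pd.DataFrame(
        records, columns=["delta_qalys", "delta_cost_healthcare", "delta_cost_societal"]
    )
    dom: dict[str, float] = {}
    ce: dict[str, dict[float, float]] = {}
    dq = draws["delta_qalys"].to_numpy()
    for persp in PERSPECTIVES:
        dc = draws[f"delta_cost_{persp}"].to_numpy()
        dom[persp] = float(np.mean((dc < 0) & (dq > 0)))
        ce[persp] = {w: float(np.mean(w * dq - dc > 0)) for w in wtps}
    return PSAResult(
        n_draws=n,
        seed=seed,
        n_rejected=n_rejected,
        wtps=wtps,
        draws=draws,
        proportion_dominant=dom,
        proportion_cost_effective=ce,
    )


def ceac(
    psa: PSAResult,
    wtp_grid: Sequence[float],
    perspective: str = "healthcare",
) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve over a WTP grid.

    For each WTP, the probability that the alternative is cost-effective:
    the fraction of draws with positive net monetary benefit.
    """
    grid = [float(w) for w in wtp_grid]
    if not grid:
        raise ValueError("empty WTP grid")
    if perspective not in PERSPECTIVES:
        raise KeyError(f"unknown perspective {perspective!r}")
    dq = psa.draws["delta_qalys"].to_numpy()
    dc = psa.draws[f"delta_cost_{perspective}"].to_numpy()
    probs = [float(np.mean(w * dq - dc > 0)) for w in grid]
    return pd.DataFrame({"wtp": grid, "probability_cost_effective": probs})
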