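"""Patient-level cohort simulation and life-table re-estimation.

The cohort model's transition probabilities originally come from an
observational study of community-dwelling patients followed for nursing-
home admission and death.  This module plays the role of that source
study: it simulates individual patient trajectories consistent with a
:class:`~adcea.parameters.ModelSpec` and re-estimates the annual
conditional transition probabilities with a discrete-time life-table
estimator, enabling closed-loop parameter-recovery tests without any
external data.

Within-year ordering: for each patient alive at the start of a year, the
death event is drawn first (probability ``p_death``); a surviving
community patient is then institutionalised with probability
``p_inst / (1 - p_death)``, so the *marginal* one-year probabilities of a
community patient dying, being institutionalised, and staying are exactly
``p_death``, ``p_inst`` and ``1 - p_inst - p_death`` — identical to the
cohort model's update rule.  Event times are whole years (the model's
cycle resolution); a patient never records both events in the same year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import ModelSpec, validate_spec

__all__ = [
    "simulate_cohort",
    "estimate_annual_probabilities",
    "EstimatedProbabilities",
    "recovery_report",
]

RECORD_COLUMNS = ["patient_id", "arm", "institutionalisation_year", "death_year", "censored_at"]


def simulate_cohort(spec: ModelSpec, n_per_arm: int, seed: int) -> pd.DataFrame:
    """Simulate individual yearly trajectories for both arms.

    Returns a DataFrame with one row per patient: ``patient_id``, ``arm``,
    ``institutionalisation_year`` (1..horizon or <NA>), ``death_year``
    (1..horizon or <NA>), and ``censored_at`` (the horizon if alive at the
    end, else <NA>).  Reproducible from ``seed``.
    """
    if n_per_arm < 1:
        raise ValueError(f"need n_per_arm >= 1, got {n_per_arm}")
    violations = validate_spec(spec)
    if violations:
        raise ValueError("invalid ModelSpec: " + "; ".join(violations))
    rng = np.random.default_rng(seed)
    h = spec.horizon_cycles
    frames = []
    offset = 0
    for strat in spec.strategies:
        inst_year = np.zeros(n_per_arm, dtype=np.int64)  # 0 = no event
        death_year = np.zeros(n_per_arm, dtype=np.int64)
        in_community = np.ones(n_per_arm, dtype=bool)
        alive = np.ones(n_per_arm, dtype=bool)
        for t in range(1, h + 1):
            p_death = spec.mortality.p_death[t - 1]
            p_inst = strat.p_institutionalisation[t - 1]
            dies = alive & (rng.random(n_per_arm) < p_death)
            death_year[dies] = t
            alive &= ~dies
            # conditional on surviving the year, so the marginal one-year
            # institutionalisation probability equals p_inst
            p_inst_given_alive = p_inst / (1.0 - p_death) if p_death < 1.0 else 0.0
            moves = in_community & alive & (rng.random(n_per_arm) < p_inst_given_alive)
            inst_year[moves] = t
            in_community &= ~moves
        df = pd.DataFrame(
            {
                "patient_id": np.arange(offset, offset + n_per_arm),
                "arm": strat.name,
                "institutionalisation_year": pd.array(
                    np.where(inst_year > 0, inst_year, -1), dtype="Int64"
                ),
                "death_year": pd.array(np.where(death_year > 0, death_year, -1), dtype="Int64"),
                "censored_at": pd.array(np.where(alive, h, -1), dtype="Int64"),
            }
        )
        for col in ("institutionalisation_year", "death_year", "censored_at"):
            df[col] = df[col].where(df[col] >= 0, pd.NA)
        frames.append(df)
        offset += n_per_arm
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class EstimatedProbabilities:
    """Life-table estimates of the annual transition probabilities.

    ``institutionalisation`` has one row per (arm, year) with the estimate,
    its binomial standard error and the at-risk count (community patients
    alive at the start of the year); ``death`` pools both arms (the model
    assumes a shared mortality schedule), with all alive patients at risk.
    Years with nobody at risk carry NaN estimates, not zero.
    """

    institutionalisation: pd.DataFrame  # arm, year, n_at_risk, estimate, se
    death: pd.DataFrame  # year, n_at_risk, estimate, se
    horizon: int


def _binom_se(p: np.ndarray, n: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.sqrt(p * (1.0 - p) / n)


def estimate_annual_probabilities(
    records: pd.DataFrame, horizon: int
) -> EstimatedProbabilities:
    """Discrete-time life-table estimator of the annual probabilities.

    For year ``t``, the conditional probability is (events in year t) /
    (patients at risk at the start of year t) — per arm for
    institutionalisation, pooled across arms for death.  Standard errors
    use the binomial formula ``sqrt(p (1 - p) / n)``.
    """
    if records.empty:
        raise ValueError("no patient records")
    inst = records["institutionalisation_year"].to_numpy(dtype=float, na_value=np.inf)
    dead = records["death_year"].to_numpy(dtype=float, na_value=np.inf)
    arms = records["arm"].to_numpy()
    years = np.arange(1, horizon + 1)

    death_rows = []
    for t in years:
        at_risk = ~(dead < t)  # alive entering year t (death strictly before t)
        n = int(at_risk.sum())
        events = int((dead == t).sum())
        p = events / n if n > 0 else np.nan
        death_rows.append({"year": t, "n_at_risk": n, "events": events, "estimate": p})
    death_df = pd.DataFrame(death_rows)
    death_df["se"] = _binom_se(death_df["estimate"].to_numpy(), death_df["n_at_risk"].to_numpy())

    inst_rows = []
    for arm in pd.unique(arms):
        mask = arms == arm
        for t in years:
            # community and alive entering year t: no prior event of either kind
            at_risk = mask & ~(inst < t) & ~(dead < t)
            n = int(at_risk.sum())
            events = int((mask & (inst == t)).sum())
            p = events / n if n > 0 else np.nan
            inst_rows.append(
                {"arm": arm, "year": t, "n_at_risk": n, "events": events, "estimate": p}
            )
    inst_df = pd.DataFrame(inst_rows)
    inst_df["se"] = _binom_se(inst_df["estimate"].to_numpy(), inst_df["n_at_risk"].to_numpy())
    return EstimatedProbabilities(
        institutionalisation=inst_df, death=death_df, horizon=horizon
    )


def recovery_report(
    true_spec: ModelSpec, estimates: EstimatedProbabilities
) -> pd.DataFrame:
    """Per-parameter recovery summary: estimate, truth, bias, CI coverage.

    One row per estimated probability (each arm-year institutionalisation
    probability and each pooled death probability) with the bias
    (estimate - truth) and whether the truth lies within the 95 % Wald
    interval ``estimate +/- 1.96 se``.  Zero-SE rows cover only on exact
    equality.
    """
    if estimates.horizon != true_spec.horizon_cycles:
        raise ValueError(
            f"horizon mismatch: estimates {estimates.horizon} vs "
            f"spec {true_spec.horizon_cycles}"
        )
    by_name = {s.name: s for s in true_spec.strategies}
    rows = []
    for rec in estimates.institutionalisation.itertuples():
        truth = by_name[rec.arm].p_institutionalisation[rec.year - 1]
        rows.append(
            {
                "parameter": "p_institutionalisation",
                "arm": rec.arm,
                "year": rec.year,
                "truth": truth,
                "estimate": rec.estimate,
                "se": rec.se,
                "bias": rec.estimate - truth,
                "covered": bool(abs(rec.estimate - truth) <= 1.96 * rec.se)
                if np.isfinite(rec.estimate)
                else False,
            }
        )
    for rec in estimates.death.itertuples():
        truth = true_spec.mortality.p_death[rec.year - 1]
        rows.append(
            {
                "parameter": "p_death",
                "arm": "both",
                "year": rec.year,
                "truth": truth,
                "estimate": rec.estimate,
                "se": rec.se,
                "bias": rec.estimate - truth,
                "covered": bool(abs(rec.estimate - truth) <= 1.96 * rec.se)
                if np.isfinite(rec.estimate)
                else False,
            }
        )
    return pd.DataFrame(rows)
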