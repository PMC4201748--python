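# Methods

## Model structure and assumptions

A deterministic Markov cohort model with three states — community,
institution (nursing home), dead — at 1-year cycles over a 7-year horizon.
Assumptions inherited from the source analysis:

- **No return from the nursing home.** Institution is absorbing apart from
  death (supported by French survey data showing <1 % of residents return
  home over three months).
- **Treatment does not affect mortality.** Both arms and both living states
  share one annual death schedule. This is deliberate: with this model
  structure, a higher institutional mortality would let a treatment that
  merely delays admission *appear* to extend life. A corollary used
  throughout the tests: the alive fraction at boundary `t` equals
  `prod(1 − p_death[1..t])` whatever the institutionalisation schedule.
- **Competing risks within a cycle** are treated as mutually exclusive
  marginal one-year probabilities: from community, death with `p_death`,
  admission with `p_inst`, stay with `1 − p_inst − p_death` (validity
  requires `p_inst + p_death ≤ 1`, enforced by validation).
- **Lifelong treatment.** Medication is charged every year alive in either
  state. In the source data patients actually received combination therapy
  for ~19 months on average, so this overstates the dearer arm's costs —
  a conservative bias for the cost-effectiveness conclusion.

## Parameters (defaults = the bundled base case)

| Parameter | Default | Units / notes |
|---|---|---|
| horizon | 7 cycles of 1 year | matches the source follow-up |
| p_inst, ChEI arm | 0.0167, 0.1031, 0.0947, 0.0808, 0.0891, 0, 0 | per year |
| p_inst, combination arm | 0, 0, 0, 0.0167, 0.0418, 0, 0 | per year |
| p_death (shared) | 0.0300 … 0.0612 | per year, AD-adjusted French life tables |
| utilities | 0.60 community / 0.34 institution | Health Utilities Index–based |
| medication | 855 / 2,013 | €/yr alive (ChEI / ChEI+memantine) |
| other direct care | 13,625 community / 28,843 institution | €/yr, 2010 euros |
| indirect care | 5,132 | €/yr in community; societal perspective only |
| discount rate | 3 % (0 % and 5 % supportive) | half-cycle correction on |
| WTP thresholds | 23,065 and 34,598 | €/QALY |

Care costs were published as 2005 values and inflated to 2010; the package
stores the 2010 values directly and exposes `inflate_cost` with an explicit
factor (the implied factor 28,843/26,301 ≈ 1.09665 is a documented constant,
not a hidden CPI lookup). Probabilities are stored exactly as printed
(4 decimals).

## Numerical choices

- **Discount timing:** factor `(1+r)^−t` at cycle boundary `t`; boundary 0
  undiscounted.
- **Half-cycle correction:** trapezoid on the *discounted* occupancy series,
  `Σ_t ½(d(t−1)·occ(t−1) + d(t)·occ(t))`; exposed as a flag so the
  end-of-cycle variant is also testable. The corrected value always lies
  between the start-of-cycle and end-of-cycle sums.
- **Constant-hazard smoothing** solves `(1−p)^H = Π(1−p_t)` in log space
  (`log1p`/`expm1`); full precision is kept internally, 4 decimals are used
  only for display. A series containing an annual probability of 1 cannot be
  smoothed (log of zero) and is rejected.
- **ICER degeneracies:** ΔQALY = 0 yields an explicit `undefined`
  classification with a NaN ICER, never a division error. Dominance is
  `Δcost < 0 and ΔQALY > 0`; dominated is the reverse.
- **Rounding for display:** costs to the euro, QALYs to 2 decimals,
  probabilities to 4 decimals; machine-readable outputs keep full precision.

## Deterministic sensitivity analysis

Eighteen scenarios, each perturbing exactly one parameter group: base case;
±20 % on community direct, indirect, and institution direct costs and on each
utility; ×0.5 and ×2 on both arms' institutionalisation schedules; a worst
case (reference ×0.5, alternative ×2) and best case (reverse); per-arm
constant-hazard smoothed schedules (0.0559 / 0.0085); ×0.5 and ×2 on the
death schedule. Scenario transforms are applied at full precision; published
scenario tables were evidently derived from unrounded base values, so
round-trip comparisons carry a one-unit-in-the-last-printed-digit tolerance.

## Probabilistic sensitivity analysis

10,000 Monte-Carlo draws by default. Triangular distributions via the
inverse CDF: multiplier (0.8, 1, 1.2) on each cost and utility group, and
(0.5, 1, 2) on each arm's institutionalisation schedule — one multiplier per
arm per draw (preserving the year-pattern of the source data), with per-year
independent sampling available as an option. The two arms' multipliers are
independent, so the worst/best cases are corners of the support. The death
schedule is fixed by default because the published distribution assignments
cover only costs, utilities and institutionalisation; a (0.5, 1, 2) death
multiplier can be switched on. Draws violating `p_inst + p_death ≤ 1` are
rejected and resampled (count reported; zero on the base model). Degenerate
widths are point masses that still consume one uniform, keeping the stream
position independent of parameter values. Everything is reproducible from a
single integer seed.

## Synthetic cohorts and what a green test establishes

`simulate_cohort` inverts the cohort model into individual yearly
trajectories: each year the death draw comes first (`p_death`); a surviving
community patient is then admitted with `p_inst / (1 − p_death)`, making the
individual-level marginal one-year probabilities identical to the cohort
model's. Event times are whole years; a patient never records both events in
one year. `estimate_annual_probabilities` is the matching discrete-time
life-table estimator (events over at-risk, per arm for admission, pooled for
death, binomial standard errors; zero-at-risk years yield NaN, not 0).

The generator emulates *only* the stated world of the model: no covariates,
no treatment discontinuation, no continuous-time hazards, no dependence
between patients, and the within-year event ordering is one consistent
convention (the source study's true ordering is unknown). A passing
parameter-recovery test therefore establishes internal consistency of
simulator + estimator + engine — not that the source study's digitised
survival curves would be recovered. Note that with competing mortality the
raw fraction of patients ever institutionalised is *below* the death-free
cumulative incidence `1 − Π(1 − p_inst)`; the latter is recovered from the
life-table estimates, not from raw counts.

## Known limitations

- **Source survival inconsistency.** The printed death probabilities imply
  73.1 % survival at 7 years and ≈5.58 discounted life-years, whereas the
  source prints 63 % and states 4.57 / 5.54 years in the community (our
  engine: 4.50 / 5.47, within 1.5 %). The source's AD-mortality adjustment
  was not published, so the printed schedule is taken at face value and the
  residual is asserted openly in the acceptance tests rather than patched.
- Published PSA proportions (99.5 % / 87.0 % dominant) are reproduced
  qualitatively (sampling granularity and correlation in the original are
  unknown); with this package's sampling scheme the proportions land within
  about one point of the published ones.
- No tunnel states, no time-in-state-dependent mortality, no extrapolation
  beyond 7 years, two strategies only (no efficiency frontier).
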