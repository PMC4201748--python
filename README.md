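# adcea

Cost-effectiveness analysis of memantine + cholinesterase-inhibitor (ChEI)
combination therapy versus ChEI monotherapy in Alzheimer's disease, built
around the delay of nursing-home admission.

## Who this is for

Health-economics analysts and biostatisticians who want a tested, scriptable
re-implementation of a published three-state Markov cohort model — base case,
an 18-scenario deterministic sensitivity analysis (DSA), a 10,000-draw
probabilistic sensitivity analysis (PSA) with triangular distributions, and a
patient-level synthetic-cohort generator for parameter-recovery testing —
instead of an opaque spreadsheet.

## The model

Three health states: community-dwelling (*C*), institutionalised (*I*,
absorbing apart from death), dead (*D*, absorbing). One-year cycles over a
7-year horizon; the whole cohort starts in *C*. With annual institutionalisation
probability `p_inst[t]` (arm-specific) and death probability `p_death[t]`
(shared by both arms and both living states):

```
C(t) = C(t-1) · (1 − p_inst[t] − p_death[t])
I(t) = I(t-1) · (1 − p_death[t]) + C(t-1) · p_inst[t]
D(t) = D(t-1) + (C(t-1) + I(t-1)) · p_death[t]
```

Discounted time in state uses the trapezoid (half-cycle-corrected) sum of the
occupancy series with discount factor `(1+r)^−t`. QALYs weight community time
by 0.60 and institution time by 0.34. Costs per year: medication (855 €/yr
ChEI, 2,013 €/yr combination, charged while alive), other direct care
(13,625 €/yr community, 28,843 €/yr institution), indirect informal care
(5,132 €/yr, community only, societal perspective only). Strategies are
compared by incremental cost and QALYs; dominance or the ICER
`Δcost / ΔQALY` is judged against willingness-to-pay thresholds of 23,065 and
34,598 €/QALY via the net monetary benefit `NMB = WTP·ΔQALY − Δcost`.

## Worked example

```python
from adcea import paper_fixture, base_case_table

print(base_case_table(paper_fixture()).to_string(index=False))
```

prints (columns abbreviated):

```
        strategy  survival_years  time_in_community_years    qalys cost_healthcare_eur cost_societal_eur
      ChEI alone        5.579001                 4.502138 3.067416        97171.636051     120276.608658
ChEI + memantine        5.579001                 5.465105 3.317788        88977.692563     117024.610094
     incremental       -0.000000                 0.962967 0.250371        -8193.943488     -3251.998563
            ICER                                                              dominant          dominant
```

Both arms survive 5.58 discounted years (treatment does not affect mortality
in this model); combination therapy keeps patients in the community 0.96
discounted years longer, gaining 0.25 QALYs while *saving* money from both
perspectives (≈8,194 € healthcare, ≈3,252 € societal) — it is dominant. The
same pipeline is available from the shell:

```bash
adcea base-case          # 0/3/5 % discounting, tables + cohort traces
adcea dsa                # 18 scenarios × 2 perspectives
adcea psa --n-draws 10000 --seed 42
adcea simulate --n-per-arm 10000 --seed 1 && \
adcea recover --records adcea_out/cohort.csv
```

The DSA leaves combination therapy dominant in 17/18 scenarios from the
healthcare perspective (the worst-case institutionalisation scenario yields an
ICER ≈ 13,500 €/QALY, still under both thresholds) and 15/18 from the societal
perspective; the PSA finds it dominant in ≈99.5 % (healthcare) and ≈87 %
(societal) of draws.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the whole analysis from the bundled configuration: the base-case
table, the DSA dominance counts, the PSA proportions (10,000 draws seeded from
`--seed`), and a 200,000-patient-per-arm parameter-recovery run, printing each
summary to stdout and writing the JSON file to `--out`.

## Layout

- `adcea.parameters` — typed parameter sets, validation, the bundled YAML
  base case (`src/adcea/data/base_case.yaml`), cost inflation,
  constant-hazard smoothing
- `adcea.markov` — cohort trace, discounting, half-cycle correction
- `adcea.economics` — QALYs, perspective costs, ICER/dominance/NMB
- `adcea.sensitivity` — DSA scenarios, triangular sampling, PSA, CEAC
- `adcea.synthetic` — patient-level simulation + life-table estimation
- `adcea.cli` — the `adcea` command

See `docs/methods.md` for modelling assumptions, numerical choices, and known
limitations (including a documented inconsistency in the source survival
figures).
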