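# oamodel

Lifetime cost-utility modelling of a structured education and exercise
therapy program (with the option of later surgery) versus immediate
total knee replacement (TKR) for knee osteoarthritis, from a health
system perspective.

## The question and the model

Clinical guidelines recommend exhausting nonsurgical care — education
and exercise therapy programs such as GLA:D — before knee replacement,
but surgery has high upfront costs and long-lasting quality-of-life
benefits, so the trade-off only resolves over a lifetime horizon.
`oamodel` implements the standard decision-analytic machinery for this
question:

* **Life-table + semi-Markov cohort engine.** A national cohort of
  everyone who would otherwise undergo primary TKR in the index year
  (age-band × sex strata) moves through annual cycles over four health
  states — *no/mild pain*, *moderate pain*, *severe/extreme pain*
  (EQ-5D-5L pain domain) and *dead* — expanded with tunnel states for
  years since the primary procedure, so revision hazards and
  post-surgical excess mortality can depend on time since surgery.
  In the comparator arm everyone is operated in year 1; in the
  intervention arm a fraction converts to surgery each year (0.26 in
  year 1, 0.08 annually thereafter).
* **Economics layer.** Discounted (5%/year) costs and QALYs with
  half-cycle correction, incremental net monetary benefit
  `INMB = λ·ΔQALY − ΔCost` at λ = A$28 033 per QALY, ICER handling for
  the dominance quadrants, USD conversion, and the INMB-versus-horizon
  sweep.
* **Subgroups** by baseline pain state, age band, sex and hospital type.
* **Sensitivity analysis.** One-way deterministic (tornado) analysis and
  a probabilistic sensitivity analysis drawing Dirichlet transition
  rows, Beta probabilities, Gamma costs and log-normal mortality ratios,
  with cost-effectiveness plane fractions and the acceptability curve.
* **Synthetic input bundles.** The real stratified inputs come from
  registries and statistical agencies and are not redistributable, so a
  seeded generator produces structurally faithful bundles (Gompertz
  mortality calibrated to national life expectancies, protective-then-
  elevated excess mortality after surgery, ~60 000-person national
  cohort), and an individual-level microsimulation oracle cross-checks
  the cohort engine.

## Worked example

```sh
oa-model synth --seed 1 --out demo_bundle
oa-model run --bundle demo_bundle --out demo_out --analyses base,horizon
```

prints (abbreviated):

```json
{
 "cohort_n": 60716.24,
 "base_case": {
  "cost_exercise": 17223.58,
  "cost_usual_care": 25580.51,
  "delta_cost": -8356.92,
  "delta_qalys": -0.864,
  "inmb": -15874.77
 },
 "tkr_avoidance_fraction": 0.245,
 "crossover_horizon": 4
}
```

Reading: on this synthetic bundle the program saves A$8 357 per person
over a lifetime (24.5% of people never need the operation) but forgoes
0.86 QALYs per person, so at A$28 033 per QALY the lifetime INMB is
negative — the program is only cost-effective when the horizon is
truncated at 4 years or less (`demo_out/horizon_curve.csv` has the full
curve). The same quantities are available programmatically:

```python
from oamodel import ScenarioConfig, generate_input_bundle, build_cohort, run_base_case

inputs = generate_input_bundle(ScenarioConfig(seed=1))
result = run_base_case(inputs, build_cohort(inputs))
print(result.per_person())          # costs, QALYs, increments, INMB
print(result.tkr_avoidance_fraction)
```

Add `--analyses base,subgroups,horizon,dsa,psa` for the tornado table
(`tornado.csv`), the PSA draws (`psa_draws.csv`) and the acceptability
curve (`ceac.csv`).

## Layout

| module | contents |
| --- | --- |
| `oamodel.inputs` | bundle schema, loading, validation, serialisation |
| `oamodel.distributions` | Beta/Gamma/Dirichlet/log-normal fits to reported summaries |
| `oamodel.synthetic` | seeded synthetic bundle generator |
| `oamodel.cohort` | eligible-cohort sizing and baseline allocation |
| `oamodel.engine` | annual-cycle semi-Markov cohort engine |
| `oamodel.economics` | discounting, accrual, INMB/ICER, horizon sweep |
| `oamodel.sensitivity` | tornado DSA, Monte Carlo PSA, CEAC |
| `oamodel.microsim` | individual-level simulation oracle |
| `oamodel.reporting` | subgroups, report rendering, consistency checks |
| `oamodel.cli` | the `oa-model` command |

See `docs/methods.md` for the model's assumptions, parameter defaults
and known limitations.
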