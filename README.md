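# equisim

Agent-based microsimulation of depression among expectant mothers under
income-inequality-reducing interventions (a stepped minimum-wage increase,
two child-benefit programs, and a guaranteed-income top-up), jointly with
social-network dynamics.

Agents are expectant mothers living in dissemination areas (DAs, the
smallest census geography). Each agent's depression risk is a logistic
function of her **relative income** (household income minus her DA's
median after-tax income) plus individual and neighborhood covariates, with
optional network terms (a protective per-tie effect and a smaller adverse
per-depressed-tie effect). Because the original model's coefficients were
fit on restricted cohort data, the package ships a documented default
coefficient set and calibrates a probability threshold so that 34.43% of
agents are depressed at baseline. A trial then steps forward: incomes are
transformed by the active intervention, agents may sever ties to depressed
peers and/or add new within-DA ties, depression is recomputed, and
incident/reduced cases are accounted against baseline.

## Layout

| module | role |
|---|---|
| `equisim.cohort` | synthetic DA + agent generator matching the published baseline marginals; within-DA random networks |
| `equisim.depression` | logistic risk model, prevalence-threshold calibration, ML fitting for parameter-recovery validation |
| `equisim.interventions` | wage-floor, child-benefit phase-out and guaranteed-income transforms |
| `equisim.networks` | the eight experimental conditions and agent network decisions |
| `equisim.engine` | trial orchestration and the 4-intervention + 8-condition suite |
| `equisim.stats` | % change, two-proportion z / exact McNemar tests, Gini |
| `equisim.config`, `equisim.io`, `equisim.cli` | YAML config, CSV/JSON schemas, CLI |

## CLI

```sh
equisim write-config --out config.yaml      # full default configuration
equisim generate --seed 1 --out-dir data    # synthetic cohort + DA CSVs
equisim run --condition 4 --intervention min_wage --seed 1
equisim suite --seed 1 --out-dir results    # all 12 trials -> CSV + JSON
equisim curves --out curves.csv             # benefit schedules over an income grid
equisim tabulate --results results/results.json --out table.csv
```

All randomness flows from the config seed (or `--seed`); identical
invocations produce byte-identical outputs.

## Notes on defaults

- Published category probabilities (age, education, nativity, ethnicity,
  income bands, government support) are generator defaults; everything
  unpublished (within-band income shapes, DA covariate distributions,
  network mean degree, coefficient magnitudes, benefit amounts) is
  configurable and documented in `equisim write-config` output.
- DA median incomes are held fixed during interventions (the exposure is
  defined against census medians); set `recompute_da_medians: true` to
  recompute them from agents each step.
- The two significance tests are both available; the default is the
  pooled two-proportion z test.
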