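# hefsim

A Markov microsimulation of diabetes care in Cambodia under different Health
Equity Fund (HEF) benefit packages. The HEF is Cambodia's fee-exemption
scheme for the poor; `hefsim` asks what happens — to societal costs, to
population health, and to households' financial risk — if the scheme starts
paying for diabetes diagnostics, glucose-lowering drugs, and/or treatment of
diabetes complications. It is written for health economists and modellers
who want a tested, configurable, seedable implementation of this style of
extended cost-effectiveness analysis.

## The model

Each simulated person carries demographics (age 25–69 at baseline, sex),
gamma-distributed annual household income (Gamma(0.5, 11566.32), mean
≈ $5,783), HEF eligibility (income below the analytic 20th or 30th income
percentile) and enrollment (75% of eligible). Disease and care states are
`no_diabetes → undiagnosed → diagnosed_untreated (diet) → OAD / insulin /
combination therapy`. For 45 annual cycles the engine applies, in order:
background mortality (age/sex schedule, mean 0.046/yr over 25–69), diabetes
onset (0.001/yr), care seeking and FPG screening of the undiagnosed,
therapy assignment and a yearly adherence draw, incidence of eight
complications (nephropathy, retinopathy, neuropathy, angina, PVD, MI,
stroke, heart failure) modified by glucose control, complication care and
costs, complication and diabetes-related mortality, and disability accrual.

Outcomes follow the standard extended-CEA quantities:

- **DALYs** = YLL + YLD, undiscounted. YLL values each diabetes-attributable
  death at max(0, LE₀ − age at death) with LE₀ = 67 (men) / 71 (women); YLD
  uses GBD-style multiplicative comorbidity, 1 − Π(1 − dwᵢ).
- **Costs** by payer (HEF/government vs out-of-pocket), discounted at 3%/yr.
  Benefit packages shift a subsidy share (80% or 100%) of covered direct
  medical costs to the HEF; transport is always out-of-pocket.
- **Catastrophic health expenditure (CHE)**: a diabetic person-year whose
  OOP spending strictly exceeds 10/25/40% of household income;
  **impoverishment**: OOP pushing a household below $1.90/day.
- **ICERs** versus the current standard (cost per DALY averted, cost per CHE
  case averted) with explicit dominance handling.

Strategies are compared under common random numbers: every run with the
same seed consumes identical random streams, so incremental results isolate
the policy effect. A two-layer uncertainty analysis draws parameter sets
from the registry's distributions (lognormal costs, beta probabilities,
truncated-normal strategy effects) and bootstraps the population.

All inputs live in one packaged YAML registry
(`src/hefsim/data/table2_base.yaml`); every value is overridable. The
registry is transcribed verbatim from its sources, and
`hefsim.consistency_report` / `hefsim validate-params` flag its known
internal inconsistencies (e.g. the MI incidence of 0.174/yr, an order of
magnitude above the other cardiovascular incidences) rather than silently
"fixing" them.

## Worked example

Compare all six benefit packages against the current standard on 16,000
HEF-eligible individuals (each representing 200 people, i.e. the ~3.2 M
Cambodians likely eligible for HEF):

```bash
hefsim compare --n 16000 --seed 1 --outdir out
```

`out/daly_table.csv` (seed 1):

```text
strategy,eligibility,total_cost,incremental_cost,dalys,incremental_dalys,icer_per_daly_averted,icer_status
diagnostics_only,0.2,113569708,5264639,3648936,-16126,326,ok
drug_therapy_only,0.2,109482018,1176949,3653307,-11754,100,ok
complications_only,0.2,195719709,87414640,3665062,0,,dominated
diagnostics_drug,0.2,114284421,5979352,3633877,-31185,192,ok
drug_complications,0.2,197458192,89153123,3653307,-11754,7585,ok
diagnostics_drug_complications,0.2,204204248,95899179,3633877,-31185,3075,ok
```

Reading it: covering drug therapy is cheap (incremental cost ≈ $1.2 M,
scaled) and averts ≈ 11,800 DALYs at ≈ $100 per DALY averted, because higher
adherence (0.125 → 0.40 among enrolled beneficiaries) prevents
complications and diabetes-related deaths. Covering complication treatment
alone moves large costs onto the HEF but — since treatment does not alter
complication mortality in this model — averts exactly zero DALYs
(`dominated`); its benefit appears instead in `out/che_table.csv`, where it
averts ≈ 54,000 CHE person-year cases. Every output directory includes a
`manifest.json` with the seed and a parameter hash; re-running the command
reproduces the CSVs byte for byte.

The same pipeline is available as a library:

```python
import hefsim as hs

params = hs.load_parameters()                      # packaged base case
cohort = hs.generate_eligible_cohort(params, 16_000, seed=1)
base   = hs.simulate(cohort, hs.build_strategy("current_standard"), params, seed=1)
drug   = hs.simulate(cohort, hs.build_strategy("drug_therapy_only"), params, seed=1)
inc    = hs.incremental(hs.summarize(base, params), hs.summarize(drug, params))
print(round(inc.icer_daly))                        # cost per DALY averted
```

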