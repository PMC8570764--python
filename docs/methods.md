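# Methods

## Model structure

`hefsim` is a discrete-time individual-level state-transition
(microsimulation) model with annual cycles and a fixed 45-year horizon. The
population is closed: no births, in-migration, or replenishment. Each
person's year applies events in a fixed order:

1. background all-cause mortality;
2. diabetes onset among non-diabetics (0.001/yr);
3. care seeking by undiagnosed diabetics and, conditional on a visit, FPG
   screening with diagnosis probability 0.370;
4. therapy assignment for the newly diagnosed (OAD 0.224, insulin 0.017,
   combination 0.07, otherwise diet advice), OAD→insulin switching
   (0.04/yr), and a yearly adherence Bernoulli draw;
5. complication incidence for each of the eight complications not yet
   active, with hazard = incidence × m, where m is the therapy RR when the
   person is adherent on drugs that year, 0.90 on diet, and 1.0 otherwise;
6. care seeking and treatment costs for every active complication;
7. mortality: acute case fatality (MI 0.707, stroke 0.693) in the event
   year only; chronic case fatality (nephropathy 0.311/yr, PVD 0.002/yr,
   heart failure 0 by default) every active year; diabetes-related
   mortality 0.030/yr for diabetics not adherent on drug therapy that year;
8. disability accrual for everyone who lived through the year.

Diagnosis-before-treatment-before-complications mirrors the care cascade;
the ordering within a cycle is otherwise a modelling choice and is the main
reason individual-level results are not expected to replicate any other
implementation exactly.

Complications are comorbid flags: several can be active at once, acute
events leave chronic sequelae, and the combined disability weight is the
GBD-style multiplicative combination 1 − Π(1 − dwᵢ), including the 0.049
uncomplicated-diabetes weight. By default undiagnosed diabetics also carry
the 0.049 weight (config switch `dw_undiagnosed_counts`; turning it off
makes the weight start at diagnosis, which flips the sign of the
diagnostics-only strategy's health impact — with the default, earlier
diagnosis is purely beneficial because it opens the treatment pathway at no
disability price).

Treatment of complications has **no** effect on complication mortality;
complication coverage therefore changes costs and financial risk protection
but, structurally, zero DALYs. This is asserted in the test suite as an
exact invariant.

## Parameters

All parameters live in `src/hefsim/data/table2_base.yaml`, each as a point
value plus an optional distribution (used only by the uncertainty
analysis). Monetary values are 2019 USD. Notable conventions and verbatim
quirks, all surfaced by `hefsim.consistency_report`:

- Cost distributions are lognormal with exp(μ+σ²/2) equal to the point
  value (within 0.11% for all 16 entries on the point-value scale). The
  per-day complication drug costs (neuropathy/angina/PVD/MI/stroke/heart
  failure) have lognormals specified on the *annualized* (×365) scale; PSA
  draws are rescaled back to per-day.
- The outpatient care-seeking betas and the provider-share betas have means
  visibly inconsistent with their printed point values; both are stored
  verbatim, and the base case always uses point values.
- MI incidence is 0.174/yr — an order of magnitude above the other
  cardiovascular incidences and almost certainly a per-1000 transcription
  in the source. It is stored verbatim and overridable in config. It makes
  MI the dominant cause of death among untreated diabetics, which shortens
  diabetic survival, makes drug-therapy benefits strongly
  mortality-dominated, and depresses complication person-years (hence CHE
  counts and per-diabetic lifetime costs). This single value is the main
  driver of the divergences listed under Limitations.
- Heart-failure case fatality has no published value and defaults to 0,
  like the other complications treated conservatively as non-fatal.
- The provider mix for a public visit renormalizes the printed population
  shares (0.114/0.025/0.030/0.042) into a conditional distribution over
  health centre/CPA1/CPA2/CPA3.

Costing rules: a screening visit costs the level-specific outpatient fee
plus FPG ($1.10) plus laboratory ($1.41), with outpatient transport ($0.92)
always out-of-pocket. Prescribed drugs are dispensed and costed every
treated person-year (OAD $27.86/yr, insulin $125.80/yr, combination their
sum); the adherence draw governs effectiveness, not billing. Outpatient
complication therapy costs the annualized treatment amount (per-day drugs
×365, per-year amounts as-is); an inpatient episode costs (facility per-day
+ complication drug per-day) × 5-day length of stay plus inpatient
transport ($11.65). Including the drug component in inpatient episodes is a
package choice: the alternative (facility cost only) would leave the
MI/stroke/heart-failure treatment-cost parameters unused.

## Synthetic population

The cohort generator emulates the study population rather than any
microdata: ages uniform on [25, 69] (the source cites survey distributions
without printing them; the grid is configurable), sex Bernoulli(0.5),
income i.i.d. Gamma(0.5, 11566.32). The gamma shape implies a Gini of
≈ 0.64 — more unequal than Cambodia's reported 36.0, an inconsistency
inherited from the income specification itself; the gamma is treated as
authoritative because every downstream quantity (eligibility threshold,
CHE denominators) is defined on it. HEF eligibility uses the *analytic*
gamma quantile (20th percentile ≈ $371, vs the ~$377 quoted from an
empirical national distribution), so the threshold is identical across
cohort sizes and seeds. `generate_eligible_cohort` samples incomes from the
gamma conditional on falling below the threshold via inverse-CDF
conditioning — exactly equivalent to simulating the nation and keeping the
poorest stratum, at a fraction of the cost. Baseline diabetics (prevalence
0.062, of whom 37% diagnosed and therapy assigned by the printed mix) start
free of complications; prevalent complications at baseline are a documented
omission.

Because the generator *is* the study population, passing tests demonstrate
internal consistency of the method under these stylized conditions, not
calibration to Cambodian microdata.

## Background mortality and life expectancy

The packaged schedule is synthetic: a Gompertz hazard (7%/yr log-slope,
male:female ratio 1.15:0.85) in 5-year bands from 25 to 100+, scaled so the
band mean over ages 25–69 is exactly the printed 0.046/yr, capped at
0.7/yr. An observed WHO schedule can be dropped into
`population.mortality_schedule` without code changes. Note 0.046/yr is very
high for this age range; it implies most of the cohort dies within the
horizon and is another inherited constraint on complication person-years.

Years of life lost value each diabetes-attributable death (diabetes-related
or complication case fatality) at max(0, LE₀ − age at death), LE₀ = 67/71.
Background deaths contribute no YLL: they are not premature mortality
caused by diabetes, and counting them would swamp the totals by an order of
magnitude. One consequence worth knowing: when drug therapy prevents a
diabetes death, the survivor goes on accruing diabetic/complication
disability, so the YLD component of the incremental DALY comparison can be
*negative* and the YLL share of averted DALYs can exceed 100%.

## Financial risk protection

CHE is assessed per diabetic person-year: out-of-pocket spending (medical +
transport, undiscounted) strictly greater than 10/25/40% of that person's
annual household income. Impoverishment counts person-years where income is
at or above the $1.90/day line but income minus OOP falls below it.
Societal cost totals are discounted at 3%/yr; CHE uses undiscounted
within-year OOP. Extensive totals scale by `national_population ×
eligibility_percentile / n` (20 for 160,000 eligible simulated persons).
ICERs report the raw signed ratio with a status: `ok` (positive cost per
unit averted), `dominant` (cost-saving; the signed negative ratio is kept
for table fidelity), `dominated` (costlier, nothing averted; no ratio).

## Uncertainty analysis

Layer one draws 50 parameter sets by default: lognormal costs, beta
probabilities, strategy relative risks Normal(point, σ² = 0.1) truncated at
zero. The adherence-under-coverage probability (0.40) is held fixed — the
varied quantities are the effects "expressed as relative risks" — and the
income gamma is never redrawn, since it defines the population rather than
an input measured with error. Layer two bootstraps 100 populations of
40,000 with replacement. The full 50 × 100 cross is the default; every cell
runs all strategies against the current standard with common random
numbers, and summaries report 2.5th/97.5th percentiles and the fraction of
runs with no DALYs averted. Parameter-set streams are spawned per index, so
enlarging a design leaves earlier draws unchanged.

## Numerical choices

- The engine is vectorized across the cohort; every cycle draws
  fixed-shape uniform arrays for the *whole* cohort regardless of who is
  alive or at risk. This costs a few harmless draws and buys exact common
  random numbers: two strategies on the same seed differ only where the
  policy touches behaviour.
- Seeds are plain integers; all internal streams derive from
  `numpy.random.SeedSequence`. Identical (cohort, strategy, params, seed)
  gives a bit-identical ledger.
- Probabilities scaled by relative risks are capped at 1. Death causes in
  a cycle resolve in order background → complication → diabetes-related.
- Person-years are recorded for everyone alive at the cycle start; the
  death-year record keeps the costs accrued before death, and background
  deaths (resolved first) accrue nothing in their final year.

## Scale and runtime

The reference configuration (160,000 eligible, 45 cycles) runs in ≈ 6 s per
strategy and ≈ 20 s for the three-strategy acceptance script. The test
suite uses 1/10-scale cohorts (16,000, scale factor 200) and completes in
well under a minute; PSA smoke tests use 2 × 2 designs on 4,000 people.

## Limitations

- No effect of complication treatment on complication mortality, no care
  for non-diabetics, no type 1 / type 2 distinction, no population
  replenishment or supply-side modelling — all inherited scope limits.
- The verbatim MI incidence (0.174/yr) and the high background mortality
  mean simulated diabetics die markedly faster than published totals imply.
  Under the base case the model reproduces the published DALYs averted by
  drug coverage and OOP averted per diabetic within the wide (±50%)
  tolerance appropriate to this under-specification, but computes roughly
  1.8× the published per-diabetic annual medical cost, ~0.4× the published
  CHE person-year count, and a death-dominated (>100% YLL) decomposition of
  averted DALYs versus the published 36%. These are structural consequences
  of the registry and the documented design choices, not free parameters;
  overriding `complications.mi.incidence` is the first experiment a user
  should run.
- Adherence is redrawn yearly, so "covered drugs" raise the *fraction of
  adherent person-years* rather than converting individuals permanently.
- The $371 vs $377 eligibility threshold gap reflects the analytic-quantile
  choice against a quoted empirical percentile.
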