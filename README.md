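# wgcea

Economic evaluation of participatory women's-group interventions for neonatal
survival: standardized trial costing, discounted life-years saved,
cost-effectiveness ratios with income-based threshold classification,
cross-trial variation screening, national scale-up projection and one-way
deterministic sensitivity analysis.

## The problem

Facilitated participatory learning and action cycles with women's groups reduce
neonatal mortality in low-resource settings and are a WHO-recommended strategy.
Six cluster-randomized trials in India, Nepal, Bangladesh and Malawi evaluated
the intervention, but their published cost-effectiveness estimates varied
widely, and the cost of delivering the intervention at national scale was
largely unknown. `wgcea` implements, as a reusable and tested pipeline, the
comparative re-analysis that harmonizes costing methods across the six trials,
asks why cost-effectiveness varies, and projects scale-up cost, affordability
and lives saved. All monetary values are 2016 international dollars (INT$).

It is aimed at health economists and epidemiologists who want to rerun or
extend trial-based economic evaluations of community interventions: the package
ships the six trials' design parameters and published results as reference
data, consumes user-supplied cost ledgers and scale-up configs, and includes a
synthetic-trial generator so the full pipeline can be exercised and calibrated
without any external data.

## The model

**Costing.** A trial's cost ledger (line items tagged by month, category,
start-up vs implementation phase, and a joint-cost flag) is standardized into

- total cost *C* = start-up + implementation over the cost-effectiveness
  horizon *H* (months); annual figures are *C*·12/*H*;
- unit costs *C*/births, annual cost per person, annual cost per group, using
  halved denominators for the two factorial Malawi trials (costs refer to the
  women's-groups-only arm, half the trial area);
- joint costs scaled by an allocation share before summarizing.

**Effectiveness.** Each neonatal death averted *D* is valued at the discounted
standard life expectancy

  DLE(r, L) = (1 − e^(−rL)) / r,  DLE(0.03, 86) = 30.81 years,

so LYS = *D* × 30.81 in the base case (3%/year, 86-year standard life
expectancy, no age weighting). Deaths recorded under partial vital surveillance
are first inflated by the reciprocal of the surveillance fraction (×11 for
Malawi-MaiKhanda). Maternal LYS (sensitivity only) derive deaths averted from
an odds ratio under the rare-event approximation and use the residual life
expectancy at the mean age at maternal death.

**Cost-effectiveness.** CER = *C*/LYS versus current practice, classified
against WHO income-based thresholds (very cost-effective below 1× GDP per
capita per LYS, cost-effective below 3×, strict inequalities) and a stricter
supply-side flag at 60% of GDP per capita.

**Variation screen.** Pearson correlations (exact two-sided t p-values,
n = 6 trials) of CER and unit cost against effectiveness, coverage, scale and
intensity.

**Scale-up.** Annual cost = trial cost per person-year × rural population
(constant unit cost); lives saved = rural births × NMR/1000 × 33% effect, with
a 30% effectiveness loss as the lower bound; affordability as % of total and
government health expenditure and GDP.

**Sensitivity.** One-way scenarios on a per-trial base case: add maternal LYS,
halve start-up costs, shift the joint-cost allocation share by ±10 points,
re-attribute factorial implementation costs (33%/75% vs base 50%), and
alternative discount rates. Scenarios whose inputs a base case lacks yield
explicit N/A cells.

## Worked example

```python
from wgcea import load_fixture, cost_effectiveness_ratio, classify_threshold

profile, reported = load_fixture("India")
cer = cost_effectiveness_ratio(reported.total_cost, reported.neonatal_lys)
res = classify_threshold(cer, profile.gdp_pc_ppp)
print(round(cer), res.who_class, f"{res.pct_of_gdp}% of GDP pc")
```

prints

```
135 very_cost_effective 2% of GDP pc
```

— the India trial spent $797,212 to save 5,887 discounted neonatal life-years:
$135 per LYS, 2% of GDP per capita, far below every cost-effectiveness
threshold. Across the six trials the ratio spans $135–$1,627 per LYS
(`examples/cost_effectiveness.py` prints the full table), and the variation
screen (`examples/variation_screen.py`) shows the spread is driven by unit
costs (r = 0.90, p = 0.01 against cost per live birth) rather than by
effectiveness, coverage, scale or intensity.

The other `examples/` scripts each demonstrate one capability — ledger
standardization, scale-up projection, the sensitivity grid, synthetic-trial
parameter recovery — and print a line explaining the numbers.

A thin CLI wraps the same functions, e.g.

```bash
wgcea reproduce --out tables/          # emit the reference tables + consistency report
wgcea sa --scenario startup:0.5        # start-up halving scenario, all trials
wgcea simulate --seed 7 --out sim/     # synthetic ledger + outcomes
```

## Fixture schema

Each trial ships as one YAML file (`src/wgcea/data/trials/`) with a `profile`
block (intervention period and horizon in months, population, live births,
groups, meetings per group, coverage, surveillance fraction, factorial flag,
GDP per capita PPP) and a `reported` block (total/start-up/annual costs, unit
costs, deaths averted, LYS, CER, joint-share rule) stored exactly as published.
User ledgers are CSV with header
`period,amount,category,phase,joint,cost_centre`; scale-up scenarios and
allocation/currency rules are YAML.

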