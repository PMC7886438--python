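"""Project national rural scale-up: cost, affordability and lives saved.

Inputs are illustrative round numbers for a Nepal-like setting; real analyses
supply country population and health-expenditure aggregates via YAML config
(`ScaleUpScenario.from_yaml`).
"""

from wgcea import ScaleUpScenario, attenuate, lives_saved, load_reported_scaleup

scenario = ScaleUpScenario(
    country="Nepal-like",
    rural_population=23_000_000,
    cost_per_person_year=4.5,  # trial annual cost per person, constant at scale
    rural_live_births=510_000,
    nmr=20.0,
    total_health_expenditure=4_100_000_000,
    government_health_expenditure=1_660_000_000,
    gdp=71_000_000_000,
    national_neonatal_deaths=16_500,
)
res = lives_saved(scenario)
print(f"annual cost            {res.annual_cost/1e6:,.0f} million $")
print(f"% THE / GHE / GDP      {res.pct_the} / {res.pct_ghe} / {res.pct_gdp}")
print(f"lives saved (full)     {res.lives_saved_full:,.0f}  ({res.pct_burden_full:.0f}% of burden)")
print(f"lives saved (30% loss) {res.lives_saved_attenuated:,.0f}  ({res.pct_burden_attenuated:.0f}% of burden)")

published = load_reported_scaleup()["countries"]["India"]
print(f"\npublished India check: {published['lives_saved_full']:,} x 0.7 = "
      f"{attenuate(published['lives_saved_full']):,.0f} (printed {published['lives_saved_attenuated']:,})")
# A 33% neonatal-mortality reduction at full trial effectiveness, attenuated by
# 30% for programmatic delivery; affordability is the cost share of national
# health spending.
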