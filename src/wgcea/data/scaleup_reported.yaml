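# Published national scale-up projections (2016 INT$): annual cost of delivering the
# intervention to the whole rural population, its share of health-expenditure aggregates,
# and neonatal lives saved with full trial effectiveness and with a 30% loss at scale.
# Stored as printed; the underlying rural-population and expenditure denominators are
# config-supplied by users (see ScaleUpScenario), not part of this fixture.
countries:
  India:
    annual_cost_million: 1514
    pct_the: 0.37
    pct_ghe: 1.23
    pct_gdp: 0.02
    lives_saved_full: 42780
    pct_burden_full: 5
    lives_saved_attenuated: 29946
    pct_burden_attenuated: 3
  Nepal:
    annual_cost_million: 105
    pct_the: 2.54
    pct_ghe: 6.30
    pct_gdp: 0.15
    lives_saved_full: 2527
    pct_burden_full: 15
    lives_saved_attenuated: 1769
    pct_burden_attenuated: 11
  Bangladesh:
    annual_cost_million: 278
    pct_the: 1.70
    pct_ghe: 6.10
    pct_gdp: 0.05
    lives_saved_full: 15445
    pct_burden_full: 14
    lives_saved_attenuated: 10812
    pct_burden_attenuated: 10
  Malawi:
    annual_cost_million: 41
    pct_the: 1.70
    pct_ghe: 3.23
    pct_gdp: 0.19
    lives_saved_full: 473
    pct_burden_full: 3
    lives_saved_attenuated: 331
    pct_burden_attenuated: 2
totals:
  lives_saved_full: 61226
  pct_burden_full: 9
  lives_saved_attenuated: 42858
  pct_burden_attenuated: 7
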