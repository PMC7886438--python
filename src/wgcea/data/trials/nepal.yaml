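# Makwanpur trial, Nepal — the first women's-group trial; smallest scale, highest unit cost.
trial_id: Nepal
profile:
  intervention_period_months: 24
  ce_horizon_months: 48
  population: 86704
  live_births: 2899
  n_groups: 111
  meetings_per_group: 10
  coverage: 0.37
  surveillance_fraction: 1.0
  factorial: false
  gdp_pc_ppp: 2468
reported:
  total_cost: 1556020
  startup_cost: 517970
  annual_total_cost: 389005
  annual_implementation_cost: 259512
  cost_per_live_birth: 537
  annual_cost_per_group: 3505
  annual_cost_per_person: 4.5
  deaths_averted: 31
  neonatal_lys: 956
  cer: 1627
  joint_share_rule: null  # joint-allocation sensitivity could not be run for this trial
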