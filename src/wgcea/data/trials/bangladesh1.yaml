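# Bangladesh I trial (low coverage: 3% of pregnant women ever attended a group).
trial_id: BangladeshI
profile:
  intervention_period_months: 35
  ce_horizon_months: 66
  population: 229195
  live_births: 15153
  n_groups: 162
  meetings_per_group: 20
  coverage: 0.03
  surveillance_fraction: 1.0
  factorial: false
  gdp_pc_ppp: 3581
reported:
  total_cost: 1387949
  startup_cost: 711312
  annual_total_cost: 252354
  annual_implementation_cost: 123025
  cost_per_live_birth: 92
  annual_cost_per_group: 1558
  annual_cost_per_person: 1.1
  deaths_averted: 57
  neonatal_lys: 1763
  cer: 787
  joint_share_rule: [0.40, 0.40]
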