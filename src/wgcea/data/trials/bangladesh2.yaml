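# Bangladesh II (Modelled) trial.
trial_id: BangladeshII
profile:
  intervention_period_months: 30
  ce_horizon_months: 42
  population: 243341
  live_births: 8819
  n_groups: 810
  meetings_per_group: 24
  coverage: 0.36
  surveillance_fraction: 1.0
  factorial: false
  gdp_pc_ppp: 3581
reported:
  total_cost: 2237115
  startup_cost: 1094497
  annual_total_cost: 639176
  annual_implementation_cost: 326462
  cost_per_live_birth: 254
  annual_cost_per_group: 789
  annual_cost_per_person: 2.6
  deaths_averted: 115
  neonatal_lys: 3531
  cer: 634
  joint_share_rule: [0.40, 0.40]
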