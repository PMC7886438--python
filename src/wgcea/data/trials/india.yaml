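# Ekjut trial, Jharkhand and Odisha, India. Values as printed; never recomputed on load.
trial_id: India
profile:
  intervention_period_months: 36
  ce_horizon_months: 49
  population: 114141
  live_births: 9469
  n_groups: 244
  meetings_per_group: 20
  coverage: 0.37
  surveillance_fraction: 1.0
  factorial: false
  gdp_pc_ppp: 6572
reported:
  total_cost: 797212
  startup_cost: 308810
  annual_total_cost: 195236
  annual_implementation_cost: 119609
  cost_per_live_birth: 84
  annual_cost_per_group: 800
  annual_cost_per_person: 1.7
  deaths_averted: 191
  neonatal_lys: 5887
  cer: 135
  joint_share_rule: [0.29, 0.36]
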