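# Malawi MaiKhanda trial. Factorial design; full-area population/births are estimates, and
# birth/death surveillance covered only ~1/11 of the area, so recorded deaths are inflated
# by 11. Largest trial (~100 000 live births) and lowest cost per live birth.
trial_id: MaiKhanda
profile:
  intervention_period_months: 27
  ce_horizon_months: 48
  population: 1200000
  live_births: 100000
  n_groups: 729
  meetings_per_group: 16
  coverage: 0.10
  surveillance_fraction: 0.0909090909090909  # 1/11
  factorial: true
  gdp_pc_ppp: 1169
reported:
  total_cost: 3064842
  startup_cost: 444687
  annual_total_cost: 766211
  annual_implementation_cost: 655039
  cost_per_live_birth: 61
  annual_cost_per_group: 2102
  annual_cost_per_person: 1.3
  deaths_averted: 350
  neonatal_lys: 10770
  cer: 285
  joint_share_rule: [0.30, 0.35]
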