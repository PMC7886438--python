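# Malawi MaiMwana trial. Factorial design (women's groups x infant-feeding counselling):
# population, live births and groups are full-area figures; costs and effects refer to the
# women's-groups-only arm, so unit-cost denominators are halved downstream.
trial_id: MaiMwana
profile:
  intervention_period_months: 36
  ce_horizon_months: 55
  population: 94992
  live_births: 9174
  n_groups: 207
  meetings_per_group: 20
  coverage: 0.51
  surveillance_fraction: 1.0
  factorial: true
  gdp_pc_ppp: 1169
reported:
  total_cost: 904504
  startup_cost: 231969
  annual_total_cost: 197346
  annual_implementation_cost: 146735
  cost_per_live_birth: 193
  annual_cost_per_group: 1907
  annual_cost_per_person: 4.2
  deaths_averted: 38
  neonatal_lys: 1178
  cer: 768
  joint_share_rule: [0.25, 0.25]
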