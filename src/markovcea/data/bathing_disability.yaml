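# Published inputs of the bathing-disability reablement evaluation:
# five-state annual dependency model, all-severe start, 8-year horizon,
# 3% discounting, 1.4 recovery boost in year 1, 128 EUR intervention cost.
states:
  labels: [mild, moderate, severe, total, death]
  absorbing: [death]

transition_matrix:
  mild:     {mild: 0.79, moderate: 0.13, severe: 0.03, total: 0.02, death: 0.03}
  moderate: {mild: 0.08, moderate: 0.82, severe: 0.03, total: 0.01, death: 0.06}
  severe:   {mild: 0.02, moderate: 0.12, severe: 0.61, total: 0.11, death: 0.14}
  total:    {mild: 0.00, moderate: 0.03, severe: 0.18, total: 0.63, death: 0.16}
  death:    {death: 1.00}

rewards:
  utility:     {mild: 0.77, moderate: 0.60, severe: 0.47, total: 0.41, death: 0.0}
  annual_cost: {mild: 2864, moderate: 8593, severe: 22915, total: 68746, death: 0}

discount: {rate: 0.03, convention: from-first-cycle}
horizon: 8
initial: {severe: 1.0}

intervention:
  from_state: severe
  to_state: moderate
  effect_multiplier: 1.4
  donor: severe
  cycles_applied: [1]
  per_person_cost: 128

scenarios:
  - {name: reduced effect, effect_multiplier: 1.2}
  - {name: increased cost, per_person_cost: 546}
  - {name: combined, effect_multiplier: 1.2, per_person_cost: 546}

seed: 0
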