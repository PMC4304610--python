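# Exposure-factor risk functions shared by every agent's model.
# Daily liquid amount: normal solved from the 25th percentile (3 ml) and
# 75th percentile (5 ml) of reported daily consumption; vaporization
# percentage: uniform over the reported device range; bodyweight: normal
# for an adult population (males and females combined).  All truncated at
# zero since negative values are physically impossible.
liquid_amount_per_day:
  family: normal_from_quantiles
  params: [0.25, 3, 0.75, 5]
  truncate: [0, null]
  unit: ml/day
vaporization_percentage:
  family: uniform
  params: [6, 81]
  truncate: [0, null]
  unit: "%"
bodyweight:
  family: normal
  params: [73.9, 12]
  truncate: [0, null]
  unit: kg
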