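# Default fuzzy membership functions for the four MS risk factors.
# Each piece is [lower, upper, value_at_lower, value_at_upper], interpolated
# linearly on the left-closed / right-open interval [lower, upper).
# Above the last piece the function is constant at the last value_at_upper.
memberships:
  1:
    factor_name: age_at_onset
    domain_min: 0.0
    soft_max: 100.0
    pieces:
      - [0.0, 20.0, 0.0, 1.0]
      - [20.0, 45.0, 1.0, 1.0]
      - [45.0, 70.0, 1.0, 0.0]
  2:
    factor_name: vitamin_d
    domain_min: 0.0
    soft_max: 200.0
    pieces:
      - [0.0, 10.0, 1.0, 1.0]
      - [10.0, 30.0, 1.0, 0.0]
  3:
    factor_name: bmi
    domain_min: 0.0
    soft_max: 60.0
    pieces:
      - [0.0, 15.0, 0.3, 0.3]
      - [15.0, 30.0, 0.3, 1.0]
  4:
    factor_name: kinship_degree
    domain_min: 0.0
    soft_max: 6.0
    pieces:
      - [0.0, 1.0, 1.0, 1.0]
      - [1.0, 6.0, 1.0, 0.0]
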