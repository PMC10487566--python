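# Reference non-additive measures (capacities) on the factor index set
# N = {1: age at onset, 2: vitamin D, 3: BMI, 4: family kinship}, one column
# per sex, elicited from the study population's descriptive statistics.
# Subsets are keyed in canonical sorted-index form; "" is the empty set.
n_factors: 4
capacities:
  female:
    "": 0.000
    "1": 0.055
    "2": 0.071
    "3": 0.055
    "4": 0.095
    "1,2": 0.081
    "1,3": 0.071
    "1,4": 0.095
    "2,3": 0.076
    "2,4": 0.110
    "3,4": 0.095
    "1,2,3": 0.103
    "1,2,4": 0.115
    "1,3,4": 0.105
    "2,3,4": 0.110
    "1,2,3,4": 0.121
  male:
    "": 0.000
    "1": 0.049
    "2": 0.065
    "3": 0.049
    "4": 0.098
    "1,2": 0.074
    "1,3": 0.065
    "1,4": 0.098
    "2,3": 0.065
    "2,4": 0.108
    "3,4": 0.098
    "1,2,3": 0.075
    "1,2,4": 0.113
    "1,3,4": 0.103
    "2,3,4": 0.108
    "1,2,3,4": 0.117
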