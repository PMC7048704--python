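# Bundled synthetic-survey configuration with wealth-gradient coverage.
n_households: 4000
year: 2016
seed: 20160101
residence_split: 0.4
education_split: 0.6
fertility_spec: 0.35
coverage_spec:
  sba:
    poorest: 34
    poorer: 48
    middle: 62
    wealthier: 76
    wealthiest: 90
  anc_skilled:
    poorest: 75
    poorer: 81
    middle: 87
    wealthier: 91
    wealthiest: 94
  td2plus: 65
  cpr_modern: 43
  unmet_need: 24
  bcg:
    poorest: 96
    poorer: 97
    middle: 98
    wealthier: 99
    wealthiest: 99
  dpt3: 86
  msl:
    poorest: 91
    poorer: 90
    middle: 90
    wealthier: 89
    wealthiest: 87
  polio3: 88
  ort:
    poorest: 52
    poorer: 57
    middle: 62
    wealthier: 66
    wealthiest: 70
  cpnm:
    poorest: 78
    poorer: 82
    middle: 85
    wealthier: 88
    wealthiest: 92
  vitamin_a: 83
  improved_water:
    poorest: 88
    poorer: 92
    middle: 95
    wealthier: 97
    wealthiest: 99
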