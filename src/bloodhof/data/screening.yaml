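# Correlation-screening design: matched subgroups per clinical covariate,
# Spearman correlation of every blood feature against the covariate, and a
# fixed |rho| threshold by group size (0.305 for the n=60 groups, 0.321 for
# the n=52 smoking group).  The thresholds are reported constants carried
# as configuration; critical_rho() offers a t-approximation alternative.
confidence: 0.95
rs_thresholds:
  60: 0.305
  52: 0.321
alpha_fallback: false
groups:
  sex:
    filters: {age: [30, 65], smoking: never, pathotype: adenocarcinoma, stage: II}
    balance: {male: 30, female: 30}
  age:
    filters: {sex: female, age: [33, 78], smoking: never, pathotype: adenocarcinoma, stage: II}
    group_size: 60
  smoking:
    filters: {sex: male, age: [30, 65], pathotype: adenocarcinoma, stage: II}
    balance: {never: 23, ever: 29}
  pathotype:
    filters: {sex: male, age: [30, 65], smoking: never, stage: II}
    balance: {adenocarcinoma: 30, squamous: 30}
  stage:
    filters: {sex: female, age: [30, 65], smoking: never, pathotype: adenocarcinoma}
    balance: {I: 15, II: 15, III: 15, IV: 15}
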