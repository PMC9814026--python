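# Kidney catheter analysis: linear effects + patient frailty
terms:
  - type: linear
    columns: [age, female, GN, AN, PKD]
    prior_variance: 1000
  - type: frailty
    prior: {family: exponential, median: 2}
aghq: {k: 15}
samples: 10000
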