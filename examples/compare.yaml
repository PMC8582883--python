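# Pooled vs period-specific fits with separation and transferability tests.
data_a:
  synthetic:
    n: 800
    seed: 11
    constants: {minor: -0.515, severe: -1.125, fatal: -2.233}
data_b:
  synthetic:
    n: 800
    seed: 12
    constants: {minor: -0.515, severe: -1.125, fatal: -2.233}
model:
  spec:
    baseline: 1
    fixed:
      minor: [female_bicyclist]
      severe: [truck, downtown]
      fatal: [truck]
    random: []
optimizer:
  gtol: 1.0e-6
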