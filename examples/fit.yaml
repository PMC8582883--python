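# Fit the three-model heterogeneity ladder on a synthetic sample.
data:
  synthetic:
    n: 1500
    seed: 7
    constants: {minor: -0.515, severe: -1.125, fatal: -2.233}
model:
  spec:
    baseline: 1
    fixed:
      severe: [truck, downtown, protection_fences, road_segments]
      fatal: [truck]
    random:
      - covariate: visibility_50_100
        severity: severe
        mean_covariates: [road_segments]
        variance_covariates: [no_lights_at_night]
draws:
  n_draws: 200
  burn: 10
optimizer:
  gtol: 1.0e-5
  maxiter: 1000
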