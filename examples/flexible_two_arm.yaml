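# Two-arm trial on the standardized time region [-1, 1] with linear and
# quadratic retention; flexible condition (per-group schedules), q = 4.
# Group 1 has the quadratic retention function, group 2 the linear one.
seed: 3
model:
  model: Mg
  c: 2
  random_class: RIRS
  d11: 1.0
  d22: 3.0
  sigma2: 1.0
  corr_kind: ar1
  rho: 0.0
dropout:
  - family: quadratic
    coefficients: [0.5, -0.35, 0.15]
  - family: linear
    coefficients: [0.65, -0.35]
problem:
  time_region: [-1, 1]
  q: 4
  condition: flexible
  fixed_times: {0: -1, 3: 1}
  optimize_weights: true
  N: 100
  n_starts: 12
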