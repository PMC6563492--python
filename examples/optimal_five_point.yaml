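# Five-occasion redesign of the one-year Alzheimer's trial:
# random-intercept AR(1) model, logistic retention, optimize
# (t3, t4, dose1, w1) with days 0, 42 and 364 fixed.
seed: 1
model:
  model: Md
  c: 2
  beta: [8.939, -0.0866, 0.01458]
  random_class: RI
  d11: 7.080921      # 2.661^2
  sigma2: 6.827769   # 2.613^2
  corr_kind: ar1
  rho: 0.3326
dropout:
  family: logistic
  coefficients: [-2.2332, -0.0131, 0.0100]
  baseline_certain: true
problem:
  time_region: [0, 364]
  q: 5
  condition: restricted
  fixed_times: {0: 0, 1: 42, 4: 364}
  optimize_weights: true
  fixed_doses: [null, 100]
  dose_region: [0, 100]
  N: 144
  include_baseline_only: false
  n_starts: 20
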