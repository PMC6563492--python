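# Simulation comparison of the original schedule against the
# D-optimal five- and four-occasion redesigns.
seed: 7
model:
  model: Md
  c: 2
  beta: [8.939, -0.0866, 0.01458]
  random_class: RI
  d11: 7.080921
  sigma2: 6.827769
  corr_kind: ar1
  rho: 0.3326
dropout:
  family: logistic
  coefficients: [-2.2332, -0.0131, 0.0100]
simulation:
  reps: 20000
  designs:
    xi_ori:
      times: [0, 42, 126, 210, 364]
      w1: 0.5
      N: 144
    xi_D_star:
      times: [0, 42, 285.2340, 355.6943, 364]
      w1: 0.4221
      N: 144
    xi_D4_star:
      times: [0, 42, 318.5670, 364]
      w1: 0.4183
      N: 172
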