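# Default population model: five-wave quadratic multilevel latent growth
# model (students nested in schools; achievement-score scale).
time_codes: [0.0, 1.0, 2.0, 3.0, 4.0]
degree: 2
alpha_between: [49.96, 4.32, -0.13]
phi_between:  # lower triangle: intercept, linear, quadratic growth factors
  - [16.2]
  - [2.82, 0.61]
  - [0.0, 0.0, 0.02]
theta_between: [11.91, 15.25, 10.32, 12.59, 1.93]
phi_within:
  - [71.45]
  - [6.76, 14.76]
  - [0.0, 0.0, 0.07]
theta_within: [1.80, 1.28, 0.06, 0.54, 0.31]
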