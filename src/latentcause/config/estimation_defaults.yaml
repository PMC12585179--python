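# Default estimation configuration (flat key-value).
# Bounds per parameter as <name>.lower / <name>.upper; optional <name>.init
# sets the initial guess (default: mid-bounds).
alpha.lower: 1.0e-6
alpha.upper: 5.0
g.lower: 0.0
g.upper: 2.0
eta.lower: 1.0e-6
eta.upper: 1.0
max_em_iter.lower: 1.0
max_em_iter.upper: 10.0
w0.lower: -0.05
w0.upper: 0.05
sigma_r2.lower: 1.0e-3
sigma_r2.upper: 5.0
sigma_x2.lower: 1.0e-3
sigma_x2.upper: 5.0
theta.lower: 0.0
theta.upper: 0.1
lam.lower: 1.0e-4
lam.upper: 0.05
K.lower: 1.0
K.upper: 40.0
n_steps: 200000
thin: 100
burn_in_samples: 1000
rhat_threshold: 1.1
halfnormal_sigma: 0.3
threshold_acquisition: 1.0
threshold_test: 0.25
threshold_other: 0.5
max_rounds: 20
max_stepout: 4
accept_direction: ge
seed: 0
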