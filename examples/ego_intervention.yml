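# Ego-based intervention at the supercritical operating point (d = 0.8),
# clamping K = 0.4 N seeds from the start of the run.
network:
  source: ba
  n_nodes: 500
  m_attach: 3
params:
  beta: 0.3
  mu: 0.5
  d: 0.8
  cost_infection: 2.0
  cost_support: 0.2
  omega: 0.5
init:
  sigma0: 0.2
  rho0: 0.1
run:
  n_steps: 1000
  window: 100
  engine: mmca
intervention:
  strategy: ego
  k_seeds: 200
  apply_time: 0
  persistent: true
output:
  directory: out
  prefix: ego
rng_seed: 1
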