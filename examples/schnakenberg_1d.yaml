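# 1D Schnakenberg run with growth/contraction coupling S = r (u - 1.3 v)
dimensionality: 1
kinetics:
  name: schnakenberg
  params: {a: 0.01, b: 1.1}
growth:
  form: difference
  params: {r: 0.163, alpha: 1.3}
D: [1.0, 40.0]
domain:
  L: 10.0
  n_nodes: 1000
ic:
  mode: noisy_equilibrium
  noise_variance: 0.01
  seed: 1
t_final: 500.0
tolerances:
  rtol: 1.0e-9
  atol: 1.0e-9
n_snapshots: 51
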