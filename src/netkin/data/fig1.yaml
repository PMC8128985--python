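model: sir
level: monokinetic
grid:
  n: 100
  periodic: true
kernel:
  form: triangular
  amplitude: 0.3
  cutoff: 0.2
params:
  beta: 0.1
  variant: network
  u0_level: 1.0
  v0_center: 0.5
  v0_height: 0.05
  v0_width: 0.02
integrator:
  scheme: euler
  dt: 0.01
  t_end: 5.0
  output_times: [1.0, 2.0, 3.0, 4.0, 5.0]
seed: 0
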