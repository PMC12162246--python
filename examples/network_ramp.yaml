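# Upstream pressure-surge experiment: 50 -> 120 mmHg ramp on the
# idealized MCA tree, run to steady state with the efficient strategy
# (weak coupling, averaged active stress, implicit friction).
network: mca_tree
protocol:
  kind: ramp
  P0_mmHg: 50.0
  P1_mmHg: 120.0
  t_start_s: 5.0
  t_end_s: 7.0
  T_end_s: 45.0
preset: control
coupling:
  mode: weak
  dt_s: 1.0e-3
  T_end_s: 45.0
  output_stride_s: 0.01
  averaged_active_stress: true
  friction: implicit
output_dir: out_ramp
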