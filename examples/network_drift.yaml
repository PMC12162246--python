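# Coupled run on the idealized MCA tree with the synthetic
# variable-mean periodic inlet (network numerical stress test).
network: mca_tree
protocol:
  kind: periodic_drift
  amplitude_mmHg: 8.0
  frequency_Hz: 5.0
preset: control
coupling:
  mode: strong
  dt_s: 2.5e-4
  T_end_s: 5.0
  output_stride_s: 0.01
output_dir: out_drift
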