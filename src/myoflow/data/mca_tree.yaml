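# Idealized rat middle-cerebral-artery tree morphometry.
# Representative values for the MCA and its first three symmetric
# generations: stretched lengths per generation, load-free outer
# diameter and thickness-to-medium-radius ratio of G0, the
# parent/daughter area ratio of the branching pattern, and the
# per-generation wall-thickness-ratio fractions of the G0 value.
g0_Do_um: 240.0
g0_h_w: 0.25
lengths_cm: [0.5, 0.4, 0.3, 0.2]
area_ratio: 1.35
thickness_fractions: [0.9, 0.8, 0.7]
elements: 2
P_out_mmHg: 50.0
Z: matched
k_omega: 1.0
lambda_z: 1.0
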