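"""Unit conventions.

All internal quantities are CGS: cm, s, g, dyn/cm^2 (pressure), poise
(viscosity), g/cm^3 (density).  Pressures cross the public interfaces in
mmHg, the unit of every protocol and boundary value; lengths in
geometry files may carry an explicit ``_um`` suffix.
"""

MMHG = 1333.22  # dyn/cm^2 per mmHg
UM = 1e-4       # cm per micrometre


def mmhg_to_cgs(p_mmhg):
    return p_mmhg * MMHG


def cgs_to_mmhg(p_dyn_cm2):
    return p_dyn_cm2 / MMHG
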