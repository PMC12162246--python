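"""Default parameter sets for rat cerebral arteries.

The signalling graph wiring (which logistic link feeds which equation,
and its four parameters) is data, not code: the defaults below encode a
minimal wiring consistent with the known pathway topology —

    chi0: pressure -> Ca2+            chi1: pressure -> ROCK
    chi2: ROCK -> HSP27-p             chi3: ROCK -> MLCP-p
    chi4: ROCK -> cofilin-p           chi5: Ca2+  -> LC20 phosphorylation
    chi6: MLCP-p -> (reduced LC20 dephosphorylation)
    chi7: HSP27-p, chi8: cofilin-p -> actin polymerization

— calibrated once to the qualitative behaviours of the myogenic
response: pressure changes in the 10-60 mmHg range move the wall Ca2+
level substantially while ROCK activity (half-activation ~100 mmHg)
barely responds; tone is negligible at 10 mmHg, develops from ~40 mmHg
and constricts the vessel below its passive diameter at 60-120 mmHg.

Wall material values are physiologically plausible CGS magnitudes for
rat cerebral arteries (cross-bridge stiffness of order 1 dyn/cm = pN/nm,
myosin filament ~1.1 um, fully-activated active wall stress of order
10^5-10^6 dyn/cm^2, passive moduli of tens of kPa).
"""

from __future__ import annotations

from dataclasses import replace

from .signalling import ChiLink, SignallingParams
from .wall import ContractileParams, PassiveParams, WallGeometry, TAU_M_REF

__all__ = [
    "default_chi_table",
    "default_signalling_params",
    "default_contractile_params",
    "default_passive_params",
    "myograph_geometry",
    "TAU_M_REF",
]


def default_chi_table() -> tuple:
    """The nine logistic links of the default wiring."""
    return (
        # 0: pressure (mmHg) -> Ca2+ target
        ChiLink("pressure", midpoint=40.0, slope=0.08, floor=0.05, ceiling=0.95),
        # 1: pressure -> ROCK target (activated at medium-high pressure)
        ChiLink("pressure", midpoint=100.0, slope=0.08, floor=0.10, ceiling=0.90),
        # 2: ROCK -> HSP27 phosphorylation target
        ChiLink("xi1", midpoint=0.35, slope=5.0, floor=0.10, ceiling=0.90),
        # 3: ROCK -> MLCP phosphorylation target
        ChiLink("xi1", midpoint=0.40, slope=5.0, floor=0.10, ceiling=0.80),
        # 4: ROCK -> cofilin phosphorylation target
        ChiLink("xi1", midpoint=0.35, slope=5.0, floor=0.10, ceiling=0.90),
        # 5: Ca2+ -> LC20 phosphorylation (production)
        ChiLink("xi0", midpoint=0.55, slope=8.0, floor=0.0, ceiling=0.98),
        # 6: MLCP-p -> reduced LC20 dephosphorylation
        ChiLink("xi3", midpoint=0.40, slope=5.0, floor=0.20, ceiling=0.80),
        # 7: HSP27-p -> actin polymerization
        ChiLink("xi2", midpoint=0.40, slope=5.0, floor=0.10, ceiling=0.90),
        # 8: cofilin-p -> actin polymerization
        ChiLink("xi4", midpoint=0.40, slope=5.0, floor=0.10, ceiling=0.90),
    )


def default_signalling_params(tau_c: float = 10.0) -> SignallingParams:
    """Signalling defaults: one transduction constant tau_c for the
    Ca2+/ROCK/HSP27 pathways (identified value 10 s), infinitesimal
    constants (algebraic updates) for the downstream conversions."""
    return SignallingParams(
        tau_c=(tau_c, tau_c, tau_c, 0.0, 0.0, 0.0, 0.0),
        chi_table=default_chi_table(),
        ca_max=230.0,
    )


def default_contractile_params(tau_m: float = 1e3 * TAU_M_REF) -> ContractileParams:
    """Contractile-fibre defaults; ``tau_m`` defaults to the identified
    value 6.188e-2 s (1000x the mouse-aorta reference)."""
    return ContractileParams(tau_m=tau_m)


def default_passive_params() -> PassiveParams:
    return PassiveParams()


def myograph_geometry(D_o_um: float = 135.0, h_w: float = 0.25,
                      **kw) -> WallGeometry:
    """Geometry of a cannulated vessel from its load-free outer diameter
    (um) and thickness-to-medium-radius ratio."""
    return WallGeometry.from_outer_diameter(D_o_um * 1e-4, h_w, **kw)
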