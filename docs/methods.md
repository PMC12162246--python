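# Methods

`myoflow` couples a linearized 1D pressure–flow solver to a multi-scale
model of the myogenically-active arterial wall, node by node, through a
fixed-point fluid–structure iteration.  This note documents the model,
its numerical treatment, the parameter choices, and what the shipped
synthetic experiments do and do not demonstrate.

## Wall model

### Intracellular signalling

Seven normalized variables describe the pressure-activated state of a
smooth-muscle ring: Ca²⁺ (ξ0), ROCK (ξ1), HSP27-p (ξ2), MLCP-p (ξ3),
cofilin-p (ξ4), LC20 phosphorylation (ξ5) and G-actin content (ξ6),
with F-actin ξ7 = 1 − ξ6.  Each evolves by first-order relaxation
toward a target assembled from nine logistic links χ0..χ8, each
connecting one input (luminal pressure in mmHg, or an upstream ξ) to
one equation through four parameters (midpoint, slope, floor, ceiling).
The LC20 equation balances production χ5·(1−ξ5) against
dephosphorylation (1−χ6)·ξ5; the G-actin equation is an OR-gate on the
two polymerization pathways, with steady state ξ6 = 1 − χ7·χ8.

The graph wiring is **data, not code** (`defaults.default_chi_table`):
χ0: P→Ca²⁺, χ1: P→ROCK, χ2..χ4: ROCK→{HSP27-p, MLCP-p, cofilin-p},
χ5: Ca²⁺→LC20-p production, χ6: MLCP-p→reduced dephosphorylation,
χ7/χ8: HSP27-p/cofilin-p→polymerization.  The shipped logistic
parameters were chosen once to satisfy the qualitative physiology of
the rat cerebral myogenic response and then frozen:

* pressure changes between 10 and 60 mmHg move the Ca²⁺ link strongly
  (half-activation 40 mmHg), while the ROCK link (half-activation
  100 mmHg) barely responds — Ca²⁺-sensitization is a medium-to-high
  pressure phenomenon;
* basal LC20 phosphorylation at 10 mmHg is small (ξ5 ≈ 0.05, no
  collapse at low pressure) and rises to ≈ 0.6 at 60 mmHg and ≈ 0.75 at
  120 mmHg;
* at steady state 60 mmHg the Ca²⁺ level maps to ≈ 184 nM with the
  230 nM reporting scale, in the physiological range.

Time constants: the three transduction pathways share one constant
τ_c = τ_c0 = τ_c1 = τ_c2 (default 10 s, the value identified for the
diameter/Ca²⁺ dynamics of rat cerebral arteries); τ_c3..τ_c6 are
treated as infinitesimal.  A constant of exactly 0 selects an algebraic
quasi-steady update (the variable is replaced each step by the fixed
point of its own equation) rather than a stiff ODE — exact and
unconditionally stable.  The genuine ODEs advance with the explicit
two-step Adams–Bashforth scheme, bootstrapped by one forward-Euler
step.  For dt ≤ min(τ_c)/10 all variables remain in [0, 1] (property-
tested); departures beyond 10⁻⁶ raise an error as a parameter
misconfiguration.

### Contractile machinery

Per cellular domain, cross-bridge cycling drives filament sliding:
F_c = L̄_fo (L_m/δ_m) ξ5 n_XBmax k_XB u_PS, with filament overlap
L̄_fo = exp(−(ū_fs − ū_fs^opt)²/(2(s_f0/L_m)²)).  The overlap is
implemented as a **decaying** Gaussian: a growing exponential is
non-physical (overlap would increase without bound as filaments slide
apart); the `overlap_sign="printed"` switch preserves the growing form
for comparison.  The reaction force of N_CU contractile units in series
with actin-cortex anchors is F_a = (λθ − 1 − 2 N_CU ū_fs)·k_s with
series stiffness k_s = k_tCU k_AC/(2 k_tCU + k_AC), k_tCU ∝ ξ5 L̄_fo and
a Hill-type cortex stiffness k_AC(ξ7).  The series factor is defined as
0 when k_tCU = 0, so ξ5 = 0 implies zero active force exactly.  Sliding
evolves as dū_fs/dt = (F_a − F_c)/τ_m + (1/2N_CU) dλθ/dt, with τ_m
defaulting to 1000× the mouse-aorta reference value 6.188×10⁻⁵ s.

Parameter magnitudes (CGS): L_m = 1.1 µm, δ_m = 14.5 nm, k_XB =
1 dyn/cm (≈ pN/nm, the single cross-bridge stiffness scale), normalized
power stroke ū_PS = 9×10⁻³, overlap width s_f0/L_m = 0.35, N_CU = 5,
ū_fs^opt = 0.  Note ū_PS must be normalized like ū_fs: a dimensional
power stroke makes the fibre stiffness inconsistent with the drive by
four orders of magnitude.  N_CF = 1.1×10⁶ converts fibre force to first
Piola–Kirchhoff stress, giving a fully activated active stress
N_CF·F_c ≈ 7.5×10⁵ ξ5 dyn/cm² (≈ 75 kPa at ξ5 = 1), a physiological SMC
wall stress.  With these values the static curve of a 135 µm vessel
constricts from 40 mmHg, reaches its minimum diameter near 60 mmHg
(d_o ≈ 112 µm vs 164 µm passive), and partially yields at very high
pressure — forced dilation — while remaining well below the passive
curve at 120 mmHg.

### Tissue mechanics

The wall is an incompressible axisymmetric thick tube: λθ = k_ω r/R,
λr = R/(r k_ω λz), λr λθ λz = 1 (holds to machine precision at every
integration point), with r(R) = sqrt((R² − R_i²)/(k_ω λz) + r_i²).
The luminal pressure balances the through-thickness stress integral
P = P_ext + ∫ (λθ ∂Ψ/∂λθ − λr ∂Ψ/∂λr) dR/(λθ λz r), with
Ψ = Ψ_a + Ψ_p, the passive part a one-fibre-family exponential
(Holzapfel-type) law with defaults c0 = 4×10⁴ dyn/cm², c1 = 8×10⁴
dyn/cm², c2 = 3.5, φ = 0.3 rad; residual strain and axial stretch
default to k_ω = λz = 1 so the load-free state is exactly stress-free
(the parameters are exposed for nonunit values).  The integral is
evaluated by composite Simpson's rule on n_CD = 5 equally spaced
reference radii, which are identified with the cellular domains
(endpoints inclusive — an odd equispaced grid is what composite
Simpson requires, so "domain midpoints" and quadrature nodes cannot
both hold; the nodes win).  Five points are within 0.5% of a
1001-point quadrature over the tested deformation range.

### Wall time stepping

The unknowns per node are (ū_fs,1..ū_fs,n_CD, A), or (ū_fs, A) in
averaged-active-stress mode (one trans-mural sliding at the
thickness-average stretch).  Time derivatives use second-order backward
differences (BDF2; backward Euler on the bootstrap step) with the force
terms implicit at the new level: an explicit treatment of
(F_a − F_c)/τ_m is unstable for any practical step since τ_m can be
6×10⁻⁵ s.  The nonlinear system is solved by a **nested** damped Newton
iteration: at fixed area each sliding equation is scalar and monotone
in its own ū_fs,k; substituting the inner solution leaves one scalar
pressure-balance equation per node.  This is algebraically equivalent
to the joint root solve but far better conditioned across the mixed
sliding/area scales, and it vectorizes over all wall nodes of a
network.  Sliding rows are nondimensionalized by the maximal
cross-bridge force, the pressure row by 1 mmHg, and the scaled residual
norm must fall below 10⁻⁸ (the inner solve runs to 10⁻¹² so its error
cannot contaminate the outer residual).  Iterates with A ≤ 0 are
rejected by step halving; a residual increase triggers per-node
backtracking.  Static solves (dū/dt = dλθ/dt = 0, hence F_a = F_c) use
the same nesting with pressure continuation as a fallback; for ξ5 = 0
the sliding is indeterminate and is pinned at its initial value.

Compliance C_A = ∂A/∂P is a centred difference with δ = 0.1 mmHg,
holding the intracellular state and the filament sliding frozen — the
elastic (fast) compliance the 1D flow equations need, cleanly separated
from the slow active dynamics.

## 1D flow

Mass and momentum in pressure–flow form are linearized by freezing
(A, C_A) and the convection + friction right-hand side at the known
level.  Each element contributes the trapezoidal integral of the two
equations with BDF2 in time (BDF1 bootstrap); junction rows impose mass
conservation and static-pressure continuity (total-pressure continuity
is available as a config switch, carrying the level-n dynamic-pressure
difference explicitly — the linearized formulation drops dynamic
pressure anyway).  The inlet row prescribes P_in(t); each outlet row
imposes P − Z·Q = P_out with the characteristic impedance
Z = ρc/A, c = sqrt(A/(ρ C_A)), recomputed from the terminal state each
step ("matched"), or a fixed value, or 0 (pressure pinned).  The
resulting sparse system is solved once per (iteration of a) time step;
the linear residual is verified below 10⁻¹⁰ after every solve.

The element scheme is defined by its behaviour contract: the
hydrostatic rest state is an exact solution, and steady flow on rigid
uniform elements reproduces Poiseuille resistance exactly (verified to
10⁻⁶ against closed forms, including series and bifurcating networks).
Frozen level-n friction limits stability to roughly
dt < 4ρA/(8πμ) ≈ 3×10⁻⁴ s for the smallest (G3) vessels — the origin
of the severe time step the reference conditions require.  The
`friction="implicit"` option moves 8πμ/A² to the new level, removing
the restriction; it is used for the long-horizon ramp-to-steady-state
experiments where wave-form accuracy at 5 Hz is not the question being
asked.

## Coupling

Each step iterates {flow solve with frozen (Aᵏ, C_Aᵏ) → signalling
update at P^{k+1} → wall solve → (A^{k+1}, C_A^{k+1})} until the RMSRE
between successive area iterates falls below ε = 10⁻⁶ (strong), or
performs exactly one pass (weak).  A weak step is bit-identical to the
first strong iterate by construction.  Signalling depends only on the
nodal pressure, so it is updated before the wall solve within each
pass; because the explicit scheme uses level-n pressures, only
quasi-steady pressure-linked variables actually change between
iterates.  Under-relaxation is available but defaults to 1 (plain
fixed point, which converges in ~2 iterations on the shipped cases);
hitting the iteration cap (50) is an error, never silent acceptance.
The framework contains no randomness: reruns are bit-identical.

## Network and protocols

The idealized tree is a symmetric binary MCA tree G0..G3 (15 segments,
8 outlets): daughter diameters follow d_child = d_parent·sqrt(area
ratio/2) with area ratio 1.35, and wall thickness ratios of G1..G3 are
90/80/70% of G0's.  The shipped morphometry
(`src/myoflow/data/mca_tree.yaml`) uses representative rat-MCA values:
G0 load-free outer diameter 240 µm, h_w = 0.25, stretched lengths
0.5/0.4/0.3/0.2 cm per generation, two elements per vessel, outlet
pressure 50 mmHg behind matched impedances, external pressure 10 mmHg,
blood density 1.04 g/cm³ and viscosity 0.05 poise.

Protocols: alternating 10/60 mmHg plateaus and 10→120 mmHg staircases
(5-min holds) for the myograph; a 50→120 mmHg linear ramp for the
network surge experiment; and a **synthetic** variable-mean periodic
inlet (piecewise-linear drift over 62–84 mmHg plus an 8 mmHg, 5 Hz
sinusoid — the rat heart rate scale) standing in for the tabulated
inlet recording the network stress test requires, which is not
available in text form.  Instantaneous experimental pressure switches
are smoothed by 1-s linear transitions (configurable): the step change
itself is not the object of study, and an exact discontinuity only
injects numerical stiffness.

Condition presets: `control` (identity), `diltiazem_30uM` (χ0
flattened to ≤ 10% of the control dynamic range over 10–60 mmHg, the
marginal stretch-operated residual of L-type channel block; load-free
diameter 150 µm), `zero_ca` (χ0 *and* χ5 flattened to zero — no Ca²⁺
and hence no LC20 phosphorylation — making ξ5 = 0 exactly and the wall
exactly passive; load-free diameter 230 µm).  Flattening χ5 as well as
χ0 is required because a logistic χ5 evaluated at the Ca²⁺ floor is
small but nonzero, and the passive-equivalence guarantee is exact, not
approximate.  Network experiments apply one preset network-wide; the
per-segment preset field exists in the data model for future mixed
conditions but the runners do not mix presets within one run.

## Problem sizes of the shipped experiments

The reference-scale network comparison (which took the original study
days of wall-clock time) is reproduced at desk scale: a 5-s window of
the periodic-drift inlet at dt = 2.5×10⁻⁴ s (20 000 coupled steps, 45
wall nodes) comparing weak vs strong coupling — measured mean mid-
vessel RMSRE ≈ 2×10⁻⁴ for flow and 3×10⁻⁶ for area, two orders below
the acceptance bounds, consistent with the reference finding that weak
coupling barely degrades accuracy at this step size.  The surge
experiment runs 45 s at dt = 10⁻³ s with averaged active stress,
implicit friction and weak coupling (the efficient strategy), reaching
≈ 98% of steady state (3.8 τ_c after the ramp); the tested inequalities
(control flow increase < zero-Ca; diameter ratio < 1 everywhere;
monotone G0→G3 fluctuation attenuation) are robust at this horizon.
The τ_c–τ_m grid search is validated by self-recovery on a
model-generated reference (argmin exactly at the generating cell),
since the digitized experimental traces it was designed for are
external figures.

## What the synthetic experiments do not show

The signalling calibration is qualitative: no digitized experimental
traces ship with the package, so agreement with recorded Ca²⁺/diameter
time series — and therefore the quantitative τ_c–τ_m error table
against experiments — is out of scope.  The periodic inlet is a
synthetic stand-in, so network numbers depend on its stated parameters,
not on a recorded waveform.  Endothelial (flow-induced) tone, metabolic
control and parenchymal arteriole beds are absent by design; the
predicted flow–pressure relation therefore rises with inlet pressure
rather than exhibiting a flat autoregulatory plateau.

## Known limitations

* Explicit-friction stability ties the default time step to the
  smallest vessel's area; very small vessels need the implicit switch
  or a severe dt.
* The fixed-point iteration has no convergence acceleration; stiff
  wall states near collapse may need under-relaxation.
* One signalling parameter set serves the whole network; cellular
  heterogeneity across generations is not modelled (thickness ratios
  are the only per-generation wall difference).
* The wall solver assumes a monotone pressure–area branch per step;
  genuine myogenic S-curve multi-valuedness would require arc-length
  continuation, not implemented.
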