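"""Multi-scale mechanics of the arterial wall at one (or many) nodes.

The wall is an incompressible, axisymmetric, hyperelastic thick tube
whose volume is occupied by circumferentially-aligned smooth muscle,
partitioned into ``n_CD`` concentric cellular domains.  Luminal pressure
enters through the radial momentum balance

    P = P_ext + int_{R_i}^{R_i+H} (l_th dPsi/dl_th - l_r dPsi/dl_r)
                                   dR / (l_th l_z r),

with the strain energy split into a passive exponential-collagen part
(Holzapfel-type) and an active part generated by actin-myosin
contractile fibres.  The integral is evaluated by composite Simpson's
rule on equally spaced reference-radius nodes identified with the
cellular domains (5 by default).

Active machinery per cellular domain: cross-bridge cycling produces a
driving force F_c; the serial arrangement of N_CU contractile units with
actin-cortex anchoring produces a reaction force F_a; their imbalance
drives the normalized filament sliding u_fs:

    du_fs/dt = (F_a - F_c)/tau_m + (1/(2 N_CU)) dl_th/dt.

The coupled unknowns per node are (u_fs_1..u_fs_nCD, A) — or (u_fs, A)
in averaged-active-stress mode.  They are found each time step as the
root of the residual system (sliding evolution + pressure balance) with
second-order backward time differences and a damped Newton iteration,
vectorized across all wall nodes of a network.  Internally the sliding
rows are nondimensionalized by the maximal cross-bridge force and the
pressure row by 1 mmHg, and the area unknown is scaled by its load-free
value, so the accepted residual norm (1e-8) is meaningful across vessel
sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .units import MMHG

__all__ = [
    "TAU_M_REF",
    "ContractileParams",
    "PassiveParams",
    "WallGeometry",
    "WallState",
    "filament_overlap",
    "contractile_forces",
    "wall_kinematics",
    "transmural_pressure",
    "solve_wall_step",
    "solve_wall_static",
    "compliance_estimate",
    "WallBank",
]

#: reference filament-sliding time constant (s), estimated for mouse
#: descending aorta; cerebral values are explored as multiples of it
TAU_M_REF = 6.188e-5


@dataclass(frozen=True)
class ContractileParams:
    """Contractile-fibre parameters (CGS units).

    tau_m        filament sliding time constant (s)
    L_m          myosin filament length (cm)
    delta_m      myosin head spacing along the filament (cm)
    n_XBmax      maximum phosphorylation rate (-)
    k_XB         cross-bridge elastic stiffness (dyn/cm)
    u_PS         power-stroke displacement, normalized like u_fs (-)
    u_fs_opt     normalized sliding with maximal overlap (-)
    s_f0         overlap width parameter (cm)
    N_CU         contractile units in series per fibre (-)
    N_CF         surface density of contractile fibres; converts fibre
                 force to first Piola-Kirchhoff stress, P_a = N_CF F_a
    k_ACmax      maximal actin-cortex stiffness (dyn/cm)
    K_AC         half-activation F-actin content (-)
    n_AC         Hill exponent of cortex activation (-)
    overlap_sign "gaussian" (overlap decays away from u_fs_opt) or
                 "printed" (growing exponent, kept for comparison only)
    """

    tau_m: float = 1e3 * TAU_M_REF
    L_m: float = 1.1e-4
    delta_m: float = 1.45e-6
    n_XBmax: float = 1.0
    k_XB: float = 1.0
    u_PS: float = 9.0e-3
    u_fs_opt: float = 0.0
    s_f0: float = 3.85e-5
    N_CU: int = 5
    N_CF: float = 1.1e6
    k_ACmax: float = 20.0
    K_AC: float = 0.5
    n_AC: float = 2.0
    overlap_sign: str = "gaussian"

    def __post_init__(self):
        for name in ("tau_m", "L_m", "delta_m", "n_XBmax", "k_XB", "u_PS",
                     "s_f0", "N_CF", "k_ACmax", "K_AC", "n_AC"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if int(self.N_CU) < 1:
            raise ValueError("N_CU must be an integer >= 1")
        if self.overlap_sign not in ("gaussian", "printed"):
            raise ValueError("overlap_sign must be 'gaussian' or 'printed'")

    @property
    def F_ref(self) -> float:
        """Cross-bridge force scale (F_c at full overlap and xi5 = 1)."""
        return (self.L_m / self.delta_m) * self.n_XBmax * self.k_XB * self.u_PS


@dataclass(frozen=True)
class PassiveParams:
    """Holzapfel-type media parameters: Psi_p = c0 (I1 - 3)
    + c1/(2 c2) {exp[c2 (I4 - 1)^2] - 1}, fibre angle phi (rad) measured
    from the circumferential direction."""

    c0: float = 4.0e4
    c1: float = 8.0e4
    c2: float = 3.5
    phi: float = 0.3

    def __post_init__(self):
        if self.c0 < 0 or self.c1 < 0:
            raise ValueError("c0, c1 must be >= 0")
        if self.c2 <= 0:
            raise ValueError("c2 must be > 0")


@dataclass(frozen=True)
class WallGeometry:
    """Load-free wall geometry of one vessel ring (CGS units).

    R_i, H    load-free luminal radius and thickness (cm)
    k_omega   residual-strain parameter (-)
    lambda_z  in vivo axial stretch (-)
    n_CD      cellular domains across the thickness (= Simpson points)
    """

    R_i: float
    H: float
    k_omega: float = 1.0
    lambda_z: float = 1.0
    n_CD: int = 5

    def __post_init__(self):
        if self.R_i <= 0 or self.H <= 0:
            raise ValueError("R_i and H must be > 0")
        if self.k_omega <= 0 or self.lambda_z <= 0:
            raise ValueError("k_omega and lambda_z must be > 0")
        if self.n_CD < 3 or self.n_CD % 2 == 0:
            raise ValueError("n_CD must be odd and >= 3 (composite Simpson)")

    @property
    def D_o(self) -> float:
        """Load-free outer diameter (cm)."""
        return 2.0 * (self.R_i + self.H)

    @property
    def h_w(self) -> float:
        """Thickness-to-medium-radius ratio H / (R_i + H/2)."""
        return self.H / (self.R_i + 0.5 * self.H)

    @property
    def A0(self) -> float:
        """Load-free luminal area (cm^2)."""
        return float(np.pi * self.R_i**2)

    @classmethod
    def from_outer_diameter(cls, D_o: float, h_w: float, **kw) -> "WallGeometry":
        """Build from load-free outer diameter and thickness ratio."""
        R_o = 0.5 * D_o
        H = h_w * R_o / (1.0 + 0.5 * h_w)
        return cls(R_i=R_o - H, H=H, **kw)


@dataclass
class WallState:
    """Mechanical state of one wall node with one previous time level.

    ``u_fs`` has length ``n_CD`` in per-domain mode or 1 in averaged
    active-stress mode.  ``lambda_theta`` is the per-domain
    circumferential stretch consistent with ``A``.
    """

    A: float
    C_A: float
    u_fs: np.ndarray
    lambda_theta: np.ndarray
    A_prev: float | None = None
    u_fs_prev: np.ndarray | None = None

    @classmethod
    def initial(cls, geom: WallGeometry, averaged: bool = False,
                u_fs0: float = -0.02) -> "WallState":
        """Load-free state; filament sliding initialized to -0.02."""
        m = 1 if averaged else geom.n_CD
        lth = wall_kinematics(geom.A0, geom)[2]
        return cls(A=geom.A0, C_A=0.0, u_fs=np.full(m, u_fs0),
                   lambda_theta=lth)


# ----------------------------------------------------------------- kinematics

def wall_kinematics(A, geom: WallGeometry):
    """Map luminal area to per-domain (R, r, lambda_theta, lambda_r).

    ``A`` may be scalar or shape (n,); returned arrays carry a trailing
    axis of length ``n_CD`` over equally spaced reference radii R_k in
    [R_i, R_i + H].  Incompressibility l_r l_th l_z = 1 holds pointwise.
    """
    A = np.asarray(A, dtype=float)
    if np.any(A <= 0):
        raise ValueError("luminal area must be > 0")
    scalar = A.ndim == 0
    A = np.atleast_1d(A)
    R = np.linspace(geom.R_i, geom.R_i + geom.H, geom.n_CD)
    r = np.sqrt((R**2 - geom.R_i**2) / (geom.k_omega * geom.lambda_z)
                + (A / np.pi)[:, None])
    lth = geom.k_omega * r / R
    lr = R / (r * geom.k_omega * geom.lambda_z)
    Rb = np.broadcast_to(R, r.shape)
    if scalar:
        return Rb[0], r[0], lth[0], lr[0]
    return Rb, r, lth, lr


# ----------------------------------------------------- contractile operations

def filament_overlap(u_fs, params: ContractileParams):
    """Normalized actin-myosin filament overlap, Gaussian in the sliding:
    exp(-(u_fs - u_fs_opt)^2 / (2 (s_f0/L_m)^2)), peak 1 at u_fs_opt."""
    u_fs = np.asarray(u_fs, dtype=float)
    w = params.s_f0 / params.L_m
    z = (u_fs - params.u_fs_opt) ** 2 / (2.0 * w * w)
    if params.overlap_sign == "printed":
        return np.exp(np.clip(z, None, 700.0))
    return np.exp(-z)


def contractile_forces(u_fs, lambda_theta, xi5, xi7, params: ContractileParams):
    """Forces and stiffnesses of the contractile machinery.

    Returns ``(F_c, F_a, k_tCU, k_AC)`` where

    * ``F_c``: cross-bridge driving force,
      L_fo (L_m/delta_m) xi5 n_XBmax k_XB u_PS;
    * ``k_tCU``: stiffness of N_CU contractile units in series;
    * ``k_AC``: actin-cortex stiffness, Hill function of xi7;
    * ``F_a``: elastic reaction force,
      (l_th - 1 - 2 N_CU u_fs) k_tCU k_AC / (2 k_tCU + k_AC);
      the series factor is 0 when k_tCU = 0 (no phosphorylated bridges).
    """
    u_fs = np.asarray(u_fs, dtype=float)
    lambda_theta = np.asarray(lambda_theta, dtype=float)
    xi5 = np.asarray(xi5, dtype=float)
    xi7 = np.asarray(xi7, dtype=float)
    if not (np.all(np.isfinite(u_fs)) and np.all(np.isfinite(lambda_theta))
            and np.all(np.isfinite(xi5)) and np.all(np.isfinite(xi7))):
        raise ValueError("non-finite contractile inputs")

    L_fo = filament_overlap(u_fs, params)
    F_c = L_fo * params.F_ref * xi5
    k_tCU = L_fo * params.L_m * xi5 * params.n_XBmax * params.k_XB \
        / (2.0 * params.delta_m * params.N_CU)
    xin = np.power(xi7, params.n_AC)
    k_AC = params.k_ACmax * xin / (xin + params.K_AC ** params.n_AC)
    denom = 2.0 * k_tCU + k_AC
    k_series = np.where(denom > 0.0,
                        k_tCU * k_AC / np.where(denom > 0.0, denom, 1.0),
                        0.0)
    F_a = (lambda_theta - 1.0 - 2.0 * params.N_CU * u_fs) * k_series
    return F_c, F_a, k_tCU, k_AC


# ------------------------------------------------------- transmural pressure

def _simpson_weights(n: int) -> np.ndarray:
    w = np.ones(n)
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    return w / 3.0


def transmural_pressure(A, u_fs, signalling, geom: WallGeometry,
                        passive: PassiveParams, contractile: ContractileParams,
                        P_ext: float = 0.0, n_points: int | None = None) -> float:
    """Luminal pressure (dyn/cm^2) balancing the wall at area ``A``.

    ``u_fs`` is an array of length ``n_CD`` (per-domain) or 1 (averaged
    active stress, evaluated at the thickness-average stretch).
    ``signalling`` is a SignallingState (first node used) or a tuple
    ``(xi5, xi7)``.  ``n_points`` (odd) overrides the quadrature grid
    for convergence studies; per-domain sliding values are then linearly
    interpolated onto it.
    """
    if isinstance(signalling, tuple):
        xi5, xi7 = signalling
    else:
        xi5, xi7 = float(signalling.xi[0, 5]), float(signalling.xi7[0])
    u_fs = np.atleast_1d(np.asarray(u_fs, dtype=float))
    averaged = u_fs.size == 1
    geoms = [geom if n_points is None else replace(geom, n_CD=n_points)]
    bank = WallBank(geoms, passive, contractile, P_ext=P_ext,
                    averaged=averaged)
    if not averaged and bank.n_CD != u_fs.size:
        u_fs = np.interp(np.linspace(0.0, 1.0, bank.n_CD),
                         np.linspace(0.0, 1.0, u_fs.size), u_fs)
    res = bank._pressure_residual(np.array([float(A)]), u_fs[None, :],
                                  np.array([xi5]), np.array([xi7]),
                                  np.array([0.0]))
    # residual = 0 - P_ext - I  =>  balancing pressure P_ext + I = -res
    return -float(res[0])


# ------------------------------------------------------------------ WallBank

class WallBank:
    """Vectorized wall solver for ``n`` independent nodes.

    Geometry may differ between nodes; the parameter set is shared.
    Histories for the BDF2 operator are rotated by :meth:`commit`, so a
    fixed-point coupling loop may call :meth:`step` repeatedly at one
    time level before committing.
    """

    NEWTON_TOL = 1e-8
    NEWTON_MAX = 60

    def __init__(self, geoms, passive: PassiveParams,
                 contractile: ContractileParams,
                 P_ext: float = 0.0, averaged: bool = False,
                 u_fs0: float = -0.02):
        geoms = list(geoms)
        self.n = len(geoms)
        n_CD = geoms[0].n_CD
        if any(g.n_CD != n_CD for g in geoms):
            raise ValueError("all nodes must share n_CD")
        self.n_CD = n_CD
        self.m = 1 if averaged else n_CD
        self.averaged = averaged
        self.passive = passive
        self.contractile = contractile
        self.P_ext = P_ext

        self.R_i = np.array([g.R_i for g in geoms])
        self.H = np.array([g.H for g in geoms])
        self.k_omega = np.array([g.k_omega for g in geoms])
        self.lambda_z = np.array([g.lambda_z for g in geoms])
        s = np.linspace(0.0, 1.0, n_CD)
        self.R = self.R_i[:, None] + self.H[:, None] * s      # (n, n_CD)
        self.w_simp = _simpson_weights(n_CD)[None, :] \
            * (self.H[:, None] / (n_CD - 1))

        self.A0 = np.pi * self.R_i**2
        self.A = self.A0.copy()
        self.u_fs = np.full((self.n, self.m), float(u_fs0))
        self.C_A = np.zeros(self.n)
        self.u_nm1 = None
        self.lth_n = self._lth(self.A)
        self.lth_nm1 = None
        self._bootstrap = True

    # -- kinematics (vectorized over nodes) --------------------------------

    def _kin(self, A):
        r = np.sqrt((self.R**2 - self.R_i[:, None]**2)
                    / (self.k_omega[:, None] * self.lambda_z[:, None])
                    + (A / np.pi)[:, None])
        lth = self.k_omega[:, None] * r / self.R
        lr = self.R / (r * self.k_omega[:, None] * self.lambda_z[:, None])
        return r, lth, lr

    def _lth(self, A):
        return self._kin(A)[1]

    def _lth_u(self, lth):
        """Stretch entering the sliding law: per-domain, or its
        thickness average in averaged-active-stress mode."""
        return np.mean(lth, axis=1, keepdims=True) if self.averaged else lth

    # -- residuals ---------------------------------------------------------

    def _pressure_residual(self, A, u_fs, xi5, xi7, P):
        """(P - P_ext - transmural integral), shape (n,).  Simpson in R."""
        r, lth, lr = self._kin(A)
        c = np.cos(self.passive.phi) ** 2
        lz = self.lambda_z[:, None]
        e4 = lth * lth * c + lz * lz * (1.0 - c) - 1.0
        dth = 2.0 * self.passive.c0 * lth \
            + 2.0 * self.passive.c1 * lth * c * e4 \
            * np.exp(self.passive.c2 * e4 * e4)
        dr_ = 2.0 * self.passive.c0 * lr

        if self.averaged:
            lth_a = np.mean(lth, axis=1)
            _, F_a, _, _ = contractile_forces(
                u_fs[:, 0], lth_a, xi5, xi7, self.contractile)
            dth = dth + self.contractile.N_CF * F_a[:, None]
        else:
            _, F_a, _, _ = contractile_forces(
                u_fs, lth, xi5[:, None], xi7[:, None], self.contractile)
            dth = dth + self.contractile.N_CF * F_a

        integrand = (lth * dth - lr * dr_) / (lth * lz * r)
        return P - self.P_ext - np.sum(self.w_simp * integrand, axis=1)

    # -- nested Newton -----------------------------------------------------
    #
    # Given A, each sliding row is a scalar monotone equation in its own
    # u_fs_k (the dominant derivative is -(2 N_CU k_series) - 3 tau_m/2dt);
    # substituting the inner solution u*(A) leaves one scalar pressure
    # equation per node.  This nesting is algebraically equivalent to the
    # full residual system but unconditionally better conditioned than a
    # joint Newton across the mixed (sliding, area) scales.

    def _sliding_rows(self, u_fs, lth_u, xi5, xi7, dt, static, u_pin):
        """Sliding residual rows at precomputed stretch, shape (n, m)."""
        F_c, F_a, _, _ = contractile_forces(
            u_fs, lth_u, xi5[:, None], xi7[:, None], self.contractile)
        F_ref = self.contractile.F_ref
        if static:
            rows = (F_a - F_c) / F_ref
            if u_pin is not None:
                rows = np.where((xi5 <= 0.0)[:, None], u_fs - u_pin, rows)
            return rows
        tau_m = self.contractile.tau_m
        if self._bootstrap:
            dudt = (u_fs - self.u_fs) / dt
            dlth = (lth_u - self._lth_u(self.lth_n)) / dt
        else:
            dudt = (3.0 * u_fs - 4.0 * self.u_fs + self.u_nm1) / (2.0 * dt)
            dlth = (3.0 * lth_u - 4.0 * self._lth_u(self.lth_n)
                    + self._lth_u(self.lth_nm1)) / (2.0 * dt)
        return (tau_m * dudt - (F_a - F_c)
                - tau_m * dlth / (2.0 * self.contractile.N_CU)) / F_ref

    def _solve_sliding(self, A, xi5, xi7, dt, static, u_pin, u_guess):
        """Inner solve: sliding rows = 0 at fixed area; vectorized over
        nodes and domains.  Row k depends only on u_fs_k, so all rows
        advance together with scalar Newton updates."""
        lth_u = self._lth_u(self._lth(A))
        u = u_guess.copy()
        r0 = self._sliding_rows(u, lth_u, xi5, xi7, dt, static, u_pin)
        for _ in range(self.NEWTON_MAX):
            # solved well below the outer tolerance so the inner error
            # does not contaminate the outer pressure residual
            if np.max(np.abs(r0)) < 1e-4 * self.NEWTON_TOL:
                return u
            h = 1e-7
            r1 = self._sliding_rows(u + h, lth_u, xi5, xi7, dt, static, u_pin)
            step = -r0 * h / (r1 - r0)
            u = u + step
            r0 = self._sliding_rows(u, lth_u, xi5, xi7, dt, static, u_pin)
        raise RuntimeError(
            f"sliding solve did not converge (max residual "
            f"{np.max(np.abs(r0)):.3e})")

    def _newton(self, P, xi5, xi7, dt, static=False,
                A_guess=None, u_guess=None):
        A = (self.A if A_guess is None else np.asarray(A_guess, float)).copy()
        u = (self.u_fs if u_guess is None else np.asarray(u_guess, float)).copy()
        u_pin = u.copy() if static else None

        def outer(Av, ug):
            uv = self._solve_sliding(Av, xi5, xi7, dt, static, u_pin, ug)
            g = self._pressure_residual(Av, uv, xi5, xi7, P) / MMHG
            return g, uv

        g0, u = outer(A, u)
        for _ in range(self.NEWTON_MAX):
            norm = np.abs(g0)
            if np.max(norm) < self.NEWTON_TOL:
                return A, u
            hA = 1e-7 * self.A0
            g1, _ = outer(A + hA, u)
            dg = (g1 - g0) / hA
            with np.errstate(divide="ignore", invalid="ignore"):
                step = np.where(dg != 0.0, -g0 / dg, 0.0)
            # trust region: limit the area change per iteration and keep
            # the iterate physical
            step = np.clip(step, -0.5 * A, 2.0 * A)
            lam = np.ones(self.n)
            A_new = A + lam * step
            g_new, u_new = outer(A_new, u)
            for _ in range(30):  # backtrack nodes whose residual grew
                worse = (np.abs(g_new) > norm) & (norm > self.NEWTON_TOL) \
                    & (lam > 1e-8)
                if not np.any(worse):
                    break
                lam[worse] *= 0.5
                A_new = A + lam * step
                g_new, u_new = outer(A_new, u)
            A, u, g0 = A_new, u_new, g_new

        bad = int(np.argmax(np.abs(g0)))
        raise RuntimeError(
            f"wall solve did not converge: scaled residual "
            f"{np.abs(g0[bad]):.3e} at node {bad} "
            f"(P={P[bad] / MMHG:.3f} mmHg, A={A[bad]:.4e} cm^2, "
            f"xi5={xi5[bad]:.3f})")

    # -- public API --------------------------------------------------------

    def step(self, P, xi5, xi7, dt):
        """Solve the new time level at nodal pressures ``P`` (dyn/cm^2);
        does not rotate histories (see :meth:`commit`)."""
        if dt <= 0:
            raise ValueError("dt must be > 0")
        return self._newton(np.asarray(P, float), np.asarray(xi5, float),
                            np.asarray(xi7, float), dt)

    def commit(self, A_new, u_new):
        """Accept the converged step and rotate time histories."""
        self.u_nm1 = self.u_fs
        self.lth_nm1 = self.lth_n
        self.A = np.asarray(A_new, float)
        self.u_fs = np.asarray(u_new, float)
        self.lth_n = self._lth(self.A)
        self._bootstrap = False

    def static_solve(self, P, xi5, xi7, A_guess=None, u_guess=None):
        """Steady solution (d/dt = 0): F_a = F_c plus pressure balance."""
        return self._newton(np.asarray(P, float), np.asarray(xi5, float),
                            np.asarray(xi7, float), dt=1.0, static=True,
                            A_guess=A_guess, u_guess=u_guess)

    def compliance(self, P, xi5, xi7, A, u_fs, delta: float = 0.1 * MMHG):
        """Centred-difference compliance [A(P+d) - A(P-d)] / (2 d) with
        the intracellular state and filament sliding frozen."""
        A_hi = self._area_at(P + delta, xi5, xi7, A, u_fs)
        A_lo = self._area_at(P - delta, xi5, xi7, A, u_fs)
        C = (A_hi - A_lo) / (2.0 * delta)
        if np.any(~np.isfinite(C)) or np.any(C <= 0):
            raise RuntimeError(
                "compliance estimate failed (non-monotone bracket; "
                "delta too large?)")
        return C

    def _area_at(self, P, xi5, xi7, A_guess, u_fs):
        """Scalar Newton on the pressure balance alone (u_fs frozen)."""
        A = np.asarray(A_guess, float).copy()
        for _ in range(self.NEWTON_MAX):
            g = self._pressure_residual(A, u_fs, xi5, xi7, P) / MMHG
            if np.max(np.abs(g)) < self.NEWTON_TOL:
                return A
            h = 1e-7 * self.A0
            dg = (self._pressure_residual(A + h, u_fs, xi5, xi7, P) / MMHG
                  - g) / h
            step = -g / dg
            lam = np.ones_like(A)
            for _ in range(60):
                bad = A + lam * step <= 0.0
                if not np.any(bad):
                    break
                lam[bad] *= 0.5
            A = A + lam * step
        raise RuntimeError("area solve for compliance did not converge")


# ------------------------------------------------- single-node conveniences

def _xi57(signalling):
    if isinstance(signalling, tuple):
        return float(signalling[0]), float(signalling[1])
    return float(signalling.xi[0, 5]), float(signalling.xi7[0])


def _bank_for(geom, passive, contractile, P_ext, averaged, state=None):
    bank = WallBank([geom], passive, contractile, P_ext=P_ext,
                    averaged=averaged)
    if state is not None:
        bank.A = np.array([float(state.A)])
        bank.u_fs = np.asarray(state.u_fs, float)[None, :]
        bank.lth_n = bank._lth(bank.A)
        if state.u_fs_prev is not None:
            bank.u_nm1 = np.asarray(state.u_fs_prev, float)[None, :]
            bank.lth_nm1 = bank._lth(np.array([float(state.A_prev)]))
            bank._bootstrap = False
    return bank


def solve_wall_step(P_new: float, wall: WallState, signalling, dt: float,
                    geom: WallGeometry, passive: PassiveParams,
                    contractile: ContractileParams, P_ext: float = 0.0,
                    mode: str = "per-domain") -> WallState:
    """Advance one wall node by one time step at new luminal pressure
    ``P_new`` (dyn/cm^2); returns a new :class:`WallState`.

    The first call on a freshly initialized state (no history) uses the
    backward-Euler bootstrap; subsequent calls use BDF2.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    xi5, xi7 = _xi57(signalling)
    bank = _bank_for(geom, passive, contractile, P_ext, mode == "averaged",
                     wall)
    A_new, u_new = bank.step(np.array([P_new]), np.array([xi5]),
                             np.array([xi7]), dt)
    C_A = bank.compliance(np.array([P_new]), np.array([xi5]),
                          np.array([xi7]), A_new, u_new)
    return WallState(A=float(A_new[0]), C_A=float(C_A[0]), u_fs=u_new[0],
                     lambda_theta=bank._lth(A_new)[0],
                     A_prev=wall.A, u_fs_prev=np.asarray(wall.u_fs).copy())


def solve_wall_static(P: float, signalling, geom: WallGeometry,
                      passive: PassiveParams, contractile: ContractileParams,
                      P_ext: float = 0.0, mode: str = "per-domain",
                      A_guess: float | None = None):
    """Static equilibrium ``(u_fs, A)`` at pressure ``P`` (dyn/cm^2);
    defines the static pressure-area (and pressure-diameter) curve."""
    xi5, xi7 = _xi57(signalling)
    bank = _bank_for(geom, passive, contractile, P_ext, mode == "averaged")
    if A_guess is not None:
        bank.A = np.array([float(A_guess)])
    try:
        A, u = bank.static_solve(np.array([P]), np.array([xi5]),
                                 np.array([xi7]))
    except RuntimeError:
        # continuation in pressure for states far from the guess
        A, u = bank.A, bank.u_fs
        for Pk in np.linspace(P_ext + 0.5 * MMHG, P, 16):
            A, u = bank.static_solve(np.array([Pk]), np.array([xi5]),
                                     np.array([xi7]), A_guess=A, u_guess=u)
    return u[0], float(A[0])


def compliance_estimate(P: float, wall: WallState, signalling,
                        geom: WallGeometry, passive: PassiveParams,
                        contractile: ContractileParams, P_ext: float = 0.0,
                        delta: float = 0.1 * MMHG) -> float:
    """C_A = [A(P+delta) - A(P-delta)] / (2 delta) (dyn/cm^2 units) with
    the intracellular state and sliding frozen at their current values."""
    xi5, xi7 = _xi57(signalling)
    averaged = np.asarray(wall.u_fs).size == 1
    bank = _bank_for(geom, passive, contractile, P_ext, averaged, wall)
    C = bank.compliance(np.array([P]), np.array([xi5]), np.array([xi7]),
                        np.array([float(wall.A)]),
                        np.asarray(wall.u_fs, float)[None, :], delta=delta)
    return float(C[0])
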