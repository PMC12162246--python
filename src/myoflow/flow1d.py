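"""Linearized 1D pressure-flow haemodynamics on a vessel network.

Mass and momentum conservation for laminar axisymmetric flow with a
Poiseuille profile, written in pressure-flow form,

    C_A dP/dt + dQ/dz = 0
    (rho/A) dQ/dt + dP/dz = -[(rho/A) d(Q^2/A)/dz + 8 pi mu Q / A^2],

are linearized in time by freezing the area and compliance coefficients
and the convection/friction right-hand side at the known level n.  Each
element contributes two equations — the trapezoidal integral of mass and
momentum over the element — with a second-order backward difference
(BDF2) in time, bootstrapped by one BDF1 step.  The element blocks,
junction constraints (mass conservation + pressure continuity) and the
boundary rows (prescribed inlet pressure; terminal characteristic
impedance P - Z Q = P_out at each outlet) assemble into one global
sparse system solved for (P, Q) at the new time level.

Frozen level-n friction limits the stable time step to roughly
dt < 4 rho A / (8 pi mu); the optional ``friction="implicit"`` setting
moves the friction coefficient to the new time level and removes that
restriction (useful for long qualitative runs on small vessels).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "FluidProperties",
    "FluidState",
    "FlowMesh",
    "build_mesh",
    "element_system",
    "apply_boundary_conditions",
    "assemble_and_solve",
    "matched_impedance",
]


@dataclass(frozen=True)
class FluidProperties:
    """Blood density (g/cm^3) and dynamic viscosity (poise)."""

    rho: float = 1.04
    mu: float = 0.05

    def __post_init__(self):
        if self.rho <= 0 or self.mu <= 0:
            raise ValueError("rho and mu must be > 0")


@dataclass
class FluidState:
    """Nodal (P, Q) with the previous level needed by BDF2.

    ``P_prev``/``Q_prev`` are ``None`` before the first step (the
    scheme then bootstraps with BDF1).
    """

    P: np.ndarray
    Q: np.ndarray
    P_prev: np.ndarray | None = None
    Q_prev: np.ndarray | None = None

    @classmethod
    def initial(cls, n_nodes: int, P0: float) -> "FluidState":
        """Rest initialization: uniform pressure, zero flow."""
        return cls(P=np.full(n_nodes, float(P0)), Q=np.zeros(n_nodes))

    def advance(self, P_new: np.ndarray, Q_new: np.ndarray) -> "FluidState":
        return FluidState(P=P_new, Q=Q_new, P_prev=self.P, Q_prev=self.Q)


@dataclass
class FlowMesh:
    """Discretized network: global node numbering with junction
    closure rows.  Segment endpoints are distinct nodes; junctions tie
    them together by constraint rows rather than node merging, so each
    segment end retains its own flow unknown."""

    n_nodes: int
    elements: np.ndarray          # (n_el, 2) int node ids
    lengths: np.ndarray           # (n_el,) element lengths (cm)
    inlet_node: int
    outlet_nodes: list            # terminal node per outlet
    junctions: list               # (parent_end_node, [daughter_start_nodes])
    seg_nodes: dict               # segment id -> array of its node ids
    seg_of_node: np.ndarray       # (n_nodes,) segment id per node
    z_of_node: np.ndarray         # (n_nodes,) axial position within segment


def build_mesh(network) -> FlowMesh:
    """Mesh a :class:`~myoflow.network.NetworkTopology`, honouring each
    segment's element count."""
    offset = 0
    seg_nodes = {}
    elements, lengths = [], []
    seg_of_node, z_of_node = [], []
    for seg in network.segments:
        m = seg.elements
        ids = np.arange(offset, offset + m + 1)
        seg_nodes[seg.id] = ids
        dz = seg.L / m
        for k in range(m):
            elements.append((ids[k], ids[k + 1]))
            lengths.append(dz)
        seg_of_node.extend([seg.id] * (m + 1))
        z_of_node.extend(np.linspace(0.0, seg.L, m + 1))
        offset += m + 1

    junctions = []
    for parent, children in network.junctions:
        junctions.append((seg_nodes[parent][-1],
                          [seg_nodes[c][0] for c in children]))
    inlet_node = int(seg_nodes[network.inlet][0])
    outlet_nodes = [int(seg_nodes[s][-1]) for s in network.outlet_segments()]

    mesh = FlowMesh(
        n_nodes=offset,
        elements=np.asarray(elements, dtype=int),
        lengths=np.asarray(lengths, dtype=float),
        inlet_node=inlet_node,
        outlet_nodes=outlet_nodes,
        junctions=junctions,
        seg_nodes=seg_nodes,
        seg_of_node=np.asarray(seg_of_node, dtype=object),
        z_of_node=np.asarray(z_of_node, dtype=float),
    )
    n_rows = (2 * len(mesh.elements)
              + sum(1 + len(d) for _, d in mesh.junctions)
              + 1 + len(mesh.outlet_nodes))
    if n_rows != 2 * mesh.n_nodes:
        raise ValueError(
            f"inconsistent closure: {n_rows} equations for "
            f"{2 * mesh.n_nodes} unknowns (check junctions/outlets)")
    return mesh


def element_system(length: float, A, C_A, P_hist, Q_hist, dt: float,
                   props: FluidProperties, bdf1: bool = False,
                   friction: str = "explicit"):
    """Elemental matrices ``(F_e, G_e, h_e)`` for one element.

    ``A``, ``C_A``: level-n nodal area/compliance snapshots, shape (2,).
    ``P_hist`` = (P^n, P^{n-1} or None), each shape (2,); same for
    ``Q_hist``.  Row 0 is the mass equation, row 1 momentum;
    columns are the element's two nodes.  The assembled network system
    is F P^{n+1} + G Q^{n+1} = h.
    """
    if length <= 0:
        raise ValueError("degenerate element (length <= 0)")
    A = np.asarray(A, dtype=float)
    C_A = np.asarray(C_A, dtype=float)
    if np.any(A <= 0):
        raise ValueError("element has non-positive area")
    P_n, P_nm1 = P_hist
    Q_n, Q_nm1 = Q_hist
    if bdf1 or P_nm1 is None:
        b, cP = 1.0 / dt, np.asarray(P_n) / dt
        cQ = np.asarray(Q_n) / dt
    else:
        b = 1.5 / dt
        cP = (2.0 * np.asarray(P_n) - 0.5 * np.asarray(P_nm1)) / dt
        cQ = (2.0 * np.asarray(Q_n) - 0.5 * np.asarray(Q_nm1)) / dt

    half = 0.5 * length
    F_e = np.zeros((2, 2))
    G_e = np.zeros((2, 2))
    h_e = np.zeros(2)

    # mass: int_e (C_A dP/dt) dz + [Q] = 0, trapezoidal in z
    F_e[0, 0] = half * C_A[0] * b
    F_e[0, 1] = half * C_A[1] * b
    G_e[0, 0] = -1.0
    G_e[0, 1] = 1.0
    h_e[0] = half * (C_A[0] * cP[0] + C_A[1] * cP[1])

    # momentum: int_e (rho/A dQ/dt) dz + [P] = int_e h dz
    G_e[1, 0] = half * (props.rho / A[0]) * b
    G_e[1, 1] = half * (props.rho / A[1]) * b
    F_e[1, 0] = -1.0
    F_e[1, 1] = 1.0
    conv = (Q_n[1] ** 2 / A[1] - Q_n[0] ** 2 / A[0]) / length
    fric = 8.0 * np.pi * props.mu
    h_e[1] = half * ((props.rho / A[0]) * cQ[0]
                     + (props.rho / A[1]) * cQ[1]
                     - (props.rho / A[0]) * conv
                     - (props.rho / A[1]) * conv)
    if friction == "implicit":
        G_e[1, 0] += half * fric / A[0] ** 2
        G_e[1, 1] += half * fric / A[1] ** 2
    else:
        h_e[1] -= half * (fric * Q_n[0] / A[0] ** 2
                          + fric * Q_n[1] / A[1] ** 2)
    return F_e, G_e, h_e


class _System:
    """COO triplet accumulator for the global (2 n_nodes) system;
    column j is P_j, column n_nodes + j is Q_j."""

    def __init__(self, n_nodes: int):
        self.n = n_nodes
        self.rows, self.cols, self.vals = [], [], []
        self.rhs = []
        self.next_row = 0

    def add_row(self, p_cols=(), p_vals=(), q_cols=(), q_vals=(), rhs=0.0):
        i = self.next_row
        for c, v in zip(p_cols, p_vals):
            self.rows.append(i); self.cols.append(c); self.vals.append(v)
        for c, v in zip(q_cols, q_vals):
            self.rows.append(i); self.cols.append(self.n + c); self.vals.append(v)
        self.rhs.append(rhs)
        self.next_row += 1

    def matrix(self):
        m = 2 * self.n
        if self.next_row != m:
            raise ValueError(f"system has {self.next_row} rows for {m} unknowns")
        Amat = sp.coo_matrix(
            (self.vals, (self.rows, self.cols)), shape=(m, m)).tocsc()
        return Amat, np.asarray(self.rhs)


def apply_boundary_conditions(system: _System, mesh: FlowMesh,
                              P_in: float, outlets, state: FluidState,
                              A=None, props: FluidProperties | None = None,
                              junction: str = "static"):
    """Append junction closures and boundary rows to ``system``.

    ``outlets`` maps terminal node -> (P_out, Z); Z >= 0 (Z = 0 pins
    the terminal pressure to P_out).  ``junction`` selects static
    (default) or total pressure continuity; the total-pressure variant
    carries the level-n dynamic pressure difference on the right-hand
    side.
    """
    for parent_end, daughters in mesh.junctions:
        # mass conservation
        system.add_row(q_cols=[parent_end] + daughters,
                       q_vals=[1.0] + [-1.0] * len(daughters))
        for d in daughters:
            rhs = 0.0
            if junction == "total":
                vd = state.Q[d] / A[d]
                vp = state.Q[parent_end] / A[parent_end]
                rhs = 0.5 * props.rho * (vd ** 2 - vp ** 2)
            system.add_row(p_cols=[parent_end, d], p_vals=[1.0, -1.0],
                           rhs=rhs)

    system.add_row(p_cols=[mesh.inlet_node], p_vals=[1.0], rhs=float(P_in))
    for node, (P_out, Z) in outlets.items():
        if Z < 0:
            raise ValueError("characteristic impedance must be >= 0")
        system.add_row(p_cols=[node], p_vals=[1.0],
                       q_cols=[node], q_vals=[-float(Z)], rhs=float(P_out))
    return system


def matched_impedance(A, C_A, props: FluidProperties):
    """Reflection-free terminal impedance Z = rho c / A with the local
    wave speed c = sqrt(A / (rho C_A))."""
    c = np.sqrt(A / (props.rho * C_A))
    return props.rho * c / A


def assemble_and_solve(mesh: FlowMesh, state: FluidState, A, C_A,
                       dt: float, P_in: float, outlets,
                       props: FluidProperties,
                       friction: str = "explicit",
                       junction: str = "static",
                       check_residual: bool = True):
    """One global sparse solve for (P, Q) at the new time level.

    ``A``/``C_A`` are the frozen per-node coefficient snapshots (the
    current fixed-point iterate in strong coupling, the level-n values
    in weak coupling).  Returns ``(P_new, Q_new)``.
    """
    A = np.asarray(A, dtype=float)
    C_A = np.asarray(C_A, dtype=float)
    sysm = _System(mesh.n_nodes)
    bdf1 = state.P_prev is None
    for (i, j), L in zip(mesh.elements, mesh.lengths):
        idx = (i, j)
        P_hist = (state.P[list(idx)],
                  None if bdf1 else state.P_prev[list(idx)])
        Q_hist = (state.Q[list(idx)],
                  None if bdf1 else state.Q_prev[list(idx)])
        F_e, G_e, h_e = element_system(L, A[list(idx)], C_A[list(idx)],
                                       P_hist, Q_hist, dt, props,
                                       bdf1=bdf1, friction=friction)
        for r in range(2):
            sysm.add_row(p_cols=idx, p_vals=F_e[r],
                         q_cols=idx, q_vals=G_e[r], rhs=h_e[r])
    apply_boundary_conditions(sysm, mesh, P_in, outlets, state,
                              A=A, props=props, junction=junction)
    M, b = sysm.matrix()
    try:
        x = spla.spsolve(M, b)
    except RuntimeError as err:  # pragma: no cover - diagnostic path
        raise RuntimeError(
            "singular flow system: check that every terminal segment "
            "has an outlet and the network is connected") from err
    if not np.all(np.isfinite(x)):
        raise RuntimeError(
            "singular flow system: check that every terminal segment "
            "has an outlet and the network is connected")
    if check_residual:
        scale = max(np.max(np.abs(b)), np.max(np.abs(x)), 1.0)
        res = np.max(np.abs(M @ x - b)) / scale
        if res > 1e-10:
            raise RuntimeError(f"flow solve residual {res:.2e} > 1e-10")
    n = mesh.n_nodes
    return x[:n], x[n:]
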