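"""1D flow solver: element contract, boundary conditions, conservation
and closed-form steady states."""

import numpy as np
import pytest

from myoflow.flow1d import (FluidProperties, FluidState, assemble_and_solve,
                            build_mesh, element_system, matched_impedance)
from myoflow.network import NetworkTopology, VesselSegment
from myoflow.wall import WallGeometry

PROPS = FluidProperties()


def tube_network(A=0.01, L=1.0, elements=4, n_segments=1, areas=None):
    """Straight tube(s) in series; outlet data filled by the caller."""
    areas = areas or [A] * n_segments
    segs, juncs = [], []
    for i, a in enumerate(areas):
        g = WallGeometry(R_i=np.sqrt(a / np.pi), H=0.1 * np.sqrt(a / np.pi))
        segs.append(VesselSegment(f"s{i}", L, g, elements))
        if i:
            juncs.append((f"s{i-1}", [f"s{i}"]))
    return NetworkTopology(
        segments=segs, junctions=juncs, inlet="s0",
        outlets={f"s{len(areas)-1}": {"P_out_mmHg": 0.0, "Z": 0.0}})


def run_steady(net, areas_per_node, P_in, P_out, Z=0.0, n=400, dt=1e-3,
               C_A=0.0):
    mesh = build_mesh(net)
    A = np.asarray(areas_per_node, dtype=float)
    C = np.full(mesh.n_nodes, C_A)
    st = FluidState.initial(mesh.n_nodes, P_in)
    outlets = {node: (P_out, Z) for node in mesh.outlet_nodes}
    for _ in range(n):
        P, Q = assemble_and_solve(mesh, st, A, C, dt, P_in, outlets, PROPS)
        st = st.advance(P, Q)
    return mesh, st


class TestElementSystem:
    def test_rest_state_is_exact_solution(self):
        """Uniform P and zero Q satisfy the element equations with zero
        right-hand-side contribution from convection and friction."""
        P = np.array([500.0, 500.0])
        Q = np.zeros(2)
        F, G, h = element_system(1.0, [0.01, 0.01], [1e-6, 1e-6],
                                 (P, P), (Q, Q), 1e-3, PROPS)
        assert np.allclose(F @ P + G @ Q, h, atol=1e-12)

    def test_degenerate_element_rejected(self):
        with pytest.raises(ValueError):
            element_system(0.0, [0.01, 0.01], [0, 0],
                           (np.zeros(2), None), (np.zeros(2), None),
                           1e-3, PROPS)
        with pytest.raises(ValueError):
            element_system(1.0, [0.0, 0.01], [0, 0],
                           (np.zeros(2), None), (np.zeros(2), None),
                           1e-3, PROPS)

    def test_poiseuille_closed_form(self):
        """Rigid uniform tube at steady state: Q = dP A^2/(8 pi mu L);
        1000 dyn/cm^2 over 1 cm at A = 0.01 cm^2 gives ~0.0796 ml/s."""
        net = tube_network(A=0.01, L=1.0, elements=4)
        mesh, st = run_steady(net, np.full(5, 0.01), 1000.0, 0.0)
        Q_exact = 1000.0 * 0.01**2 / (8 * np.pi * PROPS.mu * 1.0)
        assert st.Q[0] == pytest.approx(Q_exact, rel=1e-6)
        assert Q_exact == pytest.approx(0.0796, rel=1e-2)

    def test_time_refinement_convergence(self):
        """Self-convergence on a smooth compliant transient: halving dt
        at least halves the deviation from a dt/16 reference."""
        net = tube_network(A=0.01, L=2.0, elements=8)
        mesh = build_mesh(net)
        A = np.full(mesh.n_nodes, 0.01)
        C = np.full(mesh.n_nodes, 1e-6)
        T = 0.2

        def run(dt):
            st = FluidState.initial(mesh.n_nodes, 1000.0)
            outlets = {n: (1000.0, 0.0) for n in mesh.outlet_nodes}
            for k in range(int(round(T / dt))):
                t = (k + 1) * dt
                P_in = 1000.0 + 500.0 * np.sin(2 * np.pi * 5 * t)
                P, Q = assemble_and_solve(mesh, st, A, C, dt, P_in,
                                          outlets, PROPS)
                st = st.advance(P, Q)
            return st.P.copy()

        ref = run(T / 512)
        e1 = np.max(np.abs(run(T / 32) - ref))
        e2 = np.max(np.abs(run(T / 64) - ref))
        assert e2 < 0.6 * e1  # observed order >= 1


class TestBoundaryConditions:
    def test_zero_impedance_pins_outlet_pressure(self):
        net = tube_network()
        mesh, st = run_steady(net, np.full(5, 0.01), 800.0, 0.0)
        assert st.P[mesh.outlet_nodes[0]] == pytest.approx(0.0, abs=1e-8)

    def test_impedance_row_satisfied(self):
        """Steady state with Z > 0: P_terminal = P_out + Z Q."""
        net = tube_network()
        Z = 5000.0
        mesh, st = run_steady(net, np.full(5, 0.01), 800.0, 100.0, Z=Z)
        node = mesh.outlet_nodes[0]
        assert st.P[node] == pytest.approx(100.0 + Z * st.Q[node], rel=1e-10)

    def test_negative_impedance_rejected(self):
        net = tube_network()
        mesh = build_mesh(net)
        st = FluidState.initial(mesh.n_nodes, 0.0)
        with pytest.raises(ValueError):
            assemble_and_solve(mesh, st, np.full(5, 0.01), np.zeros(5),
                               1e-3, 0.0, {mesh.outlet_nodes[0]: (0.0, -1.0)},
                               PROPS)

    def test_matched_impedance_suppresses_reflection(self):
        """A short pulse on a uniform compliant tube terminated by
        Z = rho c / A reflects less than 5% of the incident amplitude
        at the midpoint."""
        A0, L = 0.01, 10.0
        c = 100.0                       # target wave speed (cm/s)
        C_A = A0 / (PROPS.rho * c**2)
        props = FluidProperties(rho=PROPS.rho, mu=1e-4)  # near-inviscid
        net = tube_network(A=A0, L=L, elements=100)
        mesh = build_mesh(net)
        A = np.full(mesh.n_nodes, A0)
        C = np.full(mesh.n_nodes, C_A)
        Z = float(matched_impedance(A0, C_A, props))
        st = FluidState.initial(mesh.n_nodes, 0.0)
        outlets = {mesh.outlet_nodes[0]: (0.0, Z)}
        dt = 5e-4
        mid = mesh.n_nodes // 2
        trace = []
        for k in range(int(0.25 / dt)):
            t = (k + 1) * dt
            P_in = 100.0 * np.exp(-0.5 * ((t - 0.01) / 0.004) ** 2)
            P, Q = assemble_and_solve(mesh, st, A, C, dt, P_in, outlets,
                                      props)
            st = st.advance(P, Q)
            trace.append((t, P[mid]))
        trace = np.array(trace)
        # incident pulse passes the midpoint around t = 0.01 + 5/c;
        # any reflection returns around t = 0.01 + 15/c
        t_inc = 0.01 + 0.5 * L / c
        inc = np.max(np.abs(trace[np.abs(trace[:, 0] - t_inc) < 0.03, 1]))
        refl_win = trace[trace[:, 0] > 0.01 + 1.3 * L / c, 1]
        assert np.max(np.abs(refl_win)) < 0.05 * inc


class TestJunctions:
    def bifurcation(self):
        g_p = WallGeometry(R_i=np.sqrt(0.01 / np.pi), H=0.01)
        g_d = WallGeometry(R_i=np.sqrt(0.005 / np.pi), H=0.005)
        return NetworkTopology(
            segments=[VesselSegment("p", 1.0, g_p, 2),
                      VesselSegment("a", 1.0, g_d, 2),
                      VesselSegment("b", 1.0, g_d, 2)],
            junctions=[("p", ["a", "b"])], inlet="p",
            outlets={s: {"P_out_mmHg": 0.0, "Z": 0.0} for s in "ab"})

    def test_mass_conservation_and_symmetry(self):
        net = self.bifurcation()
        mesh = build_mesh(net)
        A = np.concatenate([np.full(3, 0.01), np.full(6, 0.005)])
        st = FluidState.initial(mesh.n_nodes, 2000.0)
        outlets = {n: (0.0, 0.0) for n in mesh.outlet_nodes}
        for _ in range(400):
            P, Q = assemble_and_solve(mesh, st, A, np.zeros(9), 1e-3,
                                      2000.0, outlets, PROPS)
            st = st.advance(P, Q)
        q_p = st.Q[mesh.seg_nodes["p"][-1]]
        q_a = st.Q[mesh.seg_nodes["a"][0]]
        q_b = st.Q[mesh.seg_nodes["b"][0]]
        assert abs(q_p - q_a - q_b) < 1e-10 * max(abs(q_p), 1e-30)
        assert q_a == pytest.approx(q_b, rel=1e-10)
        # closed form: parent resistance in series with parallel pair
        Rp = 8 * np.pi * PROPS.mu * 1.0 / 0.01**2
        Rd = 8 * np.pi * PROPS.mu * 1.0 / 0.005**2
        assert st.Q[0] == pytest.approx(2000.0 / (Rp + Rd / 2), rel=1e-6)

    def test_series_resistance_closed_form(self):
        """Three segments with different areas: steady flow equals
        total pressure drop over summed Poiseuille resistances."""
        areas = [0.01, 0.006, 0.003]
        net = tube_network(L=1.0, elements=2, n_segments=3, areas=areas)
        nodes_per = 3
        A = np.concatenate([np.full(nodes_per, a) for a in areas])
        mesh, st = run_steady(net, A, 3000.0, 0.0, n=600)
        R_tot = sum(8 * np.pi * PROPS.mu * 1.0 / a**2 for a in areas)
        assert st.Q[0] == pytest.approx(3000.0 / R_tot, rel=1e-6)

    def test_hydrostatic_rest_state_network(self, mca_tree):
        """Constant pressure and zero flow are preserved exactly on the
        full tree."""
        mesh = build_mesh(mca_tree)
        A = np.array([mca_tree.segment(mesh.seg_of_node[i]).geometry.A0
                      for i in range(mesh.n_nodes)])
        C = np.full(mesh.n_nodes, 1e-8)
        P0 = 50.0
        st = FluidState.initial(mesh.n_nodes, P0)
        outlets = {n: (P0, 0.0) for n in mesh.outlet_nodes}
        for _ in range(100):
            P, Q = assemble_and_solve(mesh, st, A, C, 1e-4, P0, outlets,
                                      PROPS)
            st = st.advance(P, Q)
        assert np.max(np.abs(st.Q)) < 1e-12
        assert np.max(np.abs(st.P - P0)) < 1e-9
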