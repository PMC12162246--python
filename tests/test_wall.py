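"""Wall mechanics: overlap, forces, kinematics, pressure balance,
static/dynamic solves and compliance."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from myoflow import MMHG
from myoflow.signalling import SignallingState
from myoflow.wall import (ContractileParams, PassiveParams, WallGeometry,
                          WallState, compliance_estimate, contractile_forces,
                          filament_overlap, solve_wall_static,
                          solve_wall_step, transmural_pressure,
                          wall_kinematics)


class TestFilamentOverlap:
    def test_peak_at_optimum(self, contractile):
        assert filament_overlap(contractile.u_fs_opt, contractile) == 1.0

    def test_one_width_away_and_symmetric(self, contractile):
        w = contractile.s_f0 / contractile.L_m
        lo = filament_overlap(contractile.u_fs_opt - w, contractile)
        hi = filament_overlap(contractile.u_fs_opt + w, contractile)
        assert lo == pytest.approx(np.exp(-0.5))
        assert lo == hi

    def test_tail_vanishes(self, contractile):
        assert filament_overlap(50.0, contractile) < 1e-300 or \
            filament_overlap(50.0, contractile) == 0.0

    def test_printed_sign_grows(self, contractile):
        printed = dataclasses.replace(contractile, overlap_sign="printed")
        w = contractile.s_f0 / contractile.L_m
        assert filament_overlap(contractile.u_fs_opt + w, printed) \
            == pytest.approx(np.exp(0.5))


class TestContractileForces:
    def test_no_phosphorylation_no_force(self, contractile):
        F_c, F_a, k_tCU, k_AC = contractile_forces(
            -0.02, 1.2, 0.0, 0.5, contractile)
        assert F_c == 0.0 and k_tCU == 0.0 and F_a == 0.0
        assert k_AC > 0.0  # cortex stiffness does not need cross-bridges

    def test_zero_elongation_zero_reaction(self, contractile):
        u = 0.015
        lth = 1.0 + 2.0 * contractile.N_CU * u
        _, F_a, _, _ = contractile_forces(u, lth, 0.7, 0.5, contractile)
        assert F_a == pytest.approx(0.0, abs=1e-12)

    def test_driving_force_hand_value(self):
        """L_fo = 1, L_m/delta_m = 10, xi5 = 0.5, n_XBmax = k_XB = 1,
        u_PS = 0.01 -> F_c = 0.05."""
        p = ContractileParams(L_m=1e-4, delta_m=1e-5, n_XBmax=1.0,
                              k_XB=1.0, u_PS=0.01, u_fs_opt=0.0,
                              s_f0=1e-4, N_CU=1)
        F_c, _, _, _ = contractile_forces(0.0, 1.0, 0.5, 0.5, p)
        assert F_c == pytest.approx(0.05)

    def test_cortex_hill_midpoint(self, contractile):
        _, _, _, k_AC = contractile_forces(0.0, 1.0, 0.5, contractile.K_AC,
                                           contractile)
        assert k_AC == pytest.approx(contractile.k_ACmax / 2.0)

    def test_nonfinite_rejected(self, contractile):
        with pytest.raises(ValueError):
            contractile_forces(np.nan, 1.0, 0.5, 0.5, contractile)


class TestKinematics:
    def test_identity_deformation(self):
        g = WallGeometry(R_i=0.005, H=0.0015, k_omega=1.0, lambda_z=1.0)
        R, r, lth, lr = wall_kinematics(g.A0, g)
        assert np.allclose(lth, 1.0, atol=1e-14)
        assert np.allclose(lr, 1.0, atol=1e-14)
        assert np.allclose(r, R, atol=1e-18)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0.5, 2.0), st.floats(0.8, 1.3), st.floats(0.9, 1.4))
    def test_incompressibility_identity(self, area_factor, k_omega, lambda_z):
        """lambda_r lambda_theta lambda_z = 1 at every integration point
        for any admissible deformation."""
        g = WallGeometry(R_i=0.005, H=0.0015, k_omega=k_omega,
                         lambda_z=lambda_z)
        _, _, lth, lr = wall_kinematics(area_factor * g.A0, g)
        assert np.max(np.abs(lr * lth * lambda_z - 1.0)) < 1e-12

    def test_wall_volume_preserved(self):
        """Mapped wall volume pi (r_o^2 - r_i^2) equals the reference
        volume divided by k_omega lambda_z."""
        g = WallGeometry(R_i=0.005, H=0.0015, k_omega=1.1, lambda_z=1.2)
        A = 1.44 * g.A0
        _, r, _, _ = wall_kinematics(A, g)
        vol_def = np.pi * (r[-1] ** 2 - r[0] ** 2)
        vol_ref = np.pi * ((g.R_i + g.H) ** 2 - g.R_i ** 2) \
            / (g.k_omega * g.lambda_z)
        assert vol_def == pytest.approx(vol_ref, rel=1e-12)

    def test_negative_area_rejected(self, geom):
        with pytest.raises(ValueError):
            wall_kinematics(-1.0, geom)


def passive_transmural_oracle(A, geom, passive, n=None):
    """Independent passive-only implementation of the transmural
    pressure integral (same Simpson grid, separately coded)."""
    n = n or geom.n_CD
    R = np.linspace(geom.R_i, geom.R_i + geom.H, n)
    r = np.sqrt((R**2 - geom.R_i**2) / (geom.k_omega * geom.lambda_z)
                + A / np.pi)
    lth = geom.k_omega * r / R
    lr = R / (r * geom.k_omega * geom.lambda_z)
    c2phi = np.cos(passive.phi) ** 2
    I4 = lth**2 * c2phi + geom.lambda_z**2 * (1 - c2phi)
    dpsi_dlth = 2 * passive.c0 * lth + 2 * passive.c1 * lth * c2phi \
        * (I4 - 1) * np.exp(passive.c2 * (I4 - 1) ** 2)
    dpsi_dlr = 2 * passive.c0 * lr
    f = (lth * dpsi_dlth - lr * dpsi_dlr) / (lth * geom.lambda_z * r)
    h = geom.H / (n - 1)
    w = np.ones(n)
    w[1:-1:2], w[2:-1:2] = 4.0, 2.0
    return float(np.sum(w * f) * h / 3.0)


class TestTransmuralPressure:
    def test_identity_state_gives_external_pressure(self, passive,
                                                    contractile):
        g = WallGeometry(R_i=0.005, H=0.0015, k_omega=1.0, lambda_z=1.0)
        P = transmural_pressure(g.A0, np.full(5, -0.02), (0.0, 0.5), g,
                                passive, contractile, P_ext=10.0 * MMHG)
        assert P == pytest.approx(10.0 * MMHG, abs=1e-8)

    def test_passive_reduction_matches_oracle(self, geom, passive,
                                              contractile):
        """With xi5 = 0 the model reduces exactly to the passive
        Holzapfel-type law."""
        for f in (0.8, 1.0, 1.2, 1.5):
            A = f * geom.A0
            P = transmural_pressure(A, np.zeros(5), (0.0, 0.3), geom,
                                    passive, contractile)
            P_or = passive_transmural_oracle(A, geom, passive)
            assert P == pytest.approx(P_or, rel=1e-10, abs=1e-10)

    def test_thin_wall_laplace_limit(self, contractile):
        """For H/R_i = 0.01 and c1 = 0 the thick-wall integral agrees
        with the Laplace law (sigma_th - sigma_r) h / r within 1%."""
        pas = PassiveParams(c0=4e4, c1=1e-30, c2=1.0, phi=0.0)
        g = WallGeometry(R_i=0.01, H=1e-4, k_omega=1.0, lambda_z=1.0)
        for lth_i in (1.0001, 1.1, 1.2, 1.3):
            A = np.pi * (lth_i * g.R_i) ** 2
            P = transmural_pressure(A, np.zeros(5), (0.0, 0.3), g, pas,
                                    contractile)
            # closed form: sigma_th - sigma_r = 2 c0 (lth^2 - lr^2),
            # lr = 1/lth, thin wall h = H lr, r = lth R_mid
            lr = 1.0 / lth_i
            sig = 2 * pas.c0 * (lth_i**2 - lr**2)
            P_thin = sig * (g.H * lr) / (lth_i * (g.R_i + 0.5 * g.H))
            assert P == pytest.approx(P_thin, rel=1e-2)

    def test_simpson_vs_dense_quadrature(self, geom, passive, contractile,
                                         sig_params):
        """5-point Simpson agrees with a 1001-point quadrature within
        0.5% (and improves with more points) including the active
        part."""
        from myoflow.signalling import steady_state
        s = steady_state(60.0, sig_params)
        xi = (float(s.xi[0, 5]), float(s.xi7[0]))
        u = np.full(5, -0.05)
        for f in (0.7, 1.0, 1.3):
            A = f * geom.A0
            P5 = transmural_pressure(A, u, xi, geom, passive, contractile)
            P_dense = transmural_pressure(A, u, xi, geom, passive,
                                          contractile, n_points=1001)
            P9 = transmural_pressure(A, u, xi, geom, passive, contractile,
                                     n_points=9)
            ref = abs(P_dense) if P_dense != 0 else 1.0
            assert abs(P5 - P_dense) / max(ref, 1e3) < 5e-3
            assert abs(P9 - P_dense) <= abs(P5 - P_dense) + 1e-10


class TestStaticSolve:
    def test_passive_curve_monotone(self, geom, passive, contractile):
        areas = []
        for P in (10.0, 30.0, 60.0, 90.0, 120.0):
            _, A = solve_wall_static(P * MMHG, (0.0, 0.3), geom, passive,
                                     contractile)
            areas.append(A)
        assert np.all(np.diff(areas) > 0)

    def test_tone_constricts_at_high_pressure(self, geom, passive,
                                              contractile, sig_params):
        """Control at 120 mmHg is narrower than the passive vessel."""
        from myoflow.signalling import steady_state
        s = steady_state(120.0, sig_params)
        _, A_active = solve_wall_static(120 * MMHG, s, geom, passive,
                                        contractile)
        _, A_passive = solve_wall_static(120 * MMHG, (0.0, float(s.xi7[0])),
                                         geom, passive, contractile)
        assert A_active < A_passive

    def test_u_fs_initialization(self, geom):
        w = WallState.initial(geom)
        assert np.all(w.u_fs == -0.02)
        w_avg = WallState.initial(geom, averaged=True)
        assert w_avg.u_fs.shape == (1,)


class TestDynamicSolve:
    def test_equilibrium_fixed_point(self, geom, passive, contractile):
        """Constant P = P_ext with the active branch disabled keeps the
        load-free area for all steps."""
        w = WallState.initial(geom)
        P_ext = 10.0 * MMHG
        for _ in range(20):
            w = solve_wall_step(P_ext, w, (0.0, 0.3), 0.1, geom, passive,
                                contractile, P_ext=P_ext)
        assert w.A == pytest.approx(geom.A0, rel=1e-10)

    def test_dynamic_converges_to_static(self, geom, passive, contractile,
                                         sig_params):
        """A held pressure step relaxes to the static solution."""
        from myoflow.signalling import steady_state, step_signalling
        P = 60.0
        s_inf = steady_state(P, sig_params)
        u_st, A_st = solve_wall_static(P * MMHG, s_inf, geom, passive,
                                       contractile)
        dt = 0.1
        s = SignallingState.zeros(1)
        w = WallState.initial(geom)
        for _ in range(int(150.0 / dt)):  # 15 tau_c
            s = step_signalling(s, P, dt, sig_params)
            w = solve_wall_step(P * MMHG, w, s, dt, geom, passive,
                                contractile)
        assert abs(w.A - A_st) / A_st < 1e-6
        assert np.max(np.abs(w.u_fs - u_st)) < 1e-6

    def test_invalid_dt(self, geom, passive, contractile):
        with pytest.raises(ValueError):
            solve_wall_step(10 * MMHG, WallState.initial(geom), (0.0, 0.5),
                            0.0, geom, passive, contractile)


class TestCompliance:
    def test_matches_fine_difference_oracle(self, geom, passive,
                                            contractile):
        """The 0.1 mmHg centred difference matches the derivative of
        the model's own pressure-area relation within 0.1%."""
        from scipy.optimize import brentq
        w = WallState.initial(geom)
        # relax the passive wall to 40 mmHg
        for _ in range(50):
            w = solve_wall_step(40 * MMHG, w, (0.0, 0.3), 0.5, geom,
                                passive, contractile)
        C = compliance_estimate(40 * MMHG, w, (0.0, 0.3), geom, passive,
                                contractile)

        def area_at(P):
            return brentq(
                lambda A: transmural_pressure(A, w.u_fs, (0.0, 0.3), geom,
                                              passive, contractile) - P,
                0.3 * geom.A0, 5 * geom.A0, xtol=1e-18)

        d = 1e-4 * MMHG
        C_oracle = (area_at(40 * MMHG + d) - area_at(40 * MMHG - d)) / (2 * d)
        assert C == pytest.approx(C_oracle, rel=1e-3)
        assert C > 0

    def test_decreases_with_pressure_in_stiffening_regime(
            self, geom, passive, contractile):
        """Exponential collagen stiffening makes dA/dP fall as P
        rises."""
        Cs = []
        for P in (40.0, 80.0, 120.0):
            w = WallState.initial(geom)
            for _ in range(60):
                w = solve_wall_step(P * MMHG, w, (0.0, 0.3), 0.5, geom,
                                    passive, contractile)
            Cs.append(compliance_estimate(P * MMHG, w, (0.0, 0.3), geom,
                                          passive, contractile))
        assert Cs[0] > Cs[1] > Cs[2]
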