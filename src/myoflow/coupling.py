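"""Fluid-structure coupling across the network, node by node.

Each time step advances three physics in sequence: the global 1D flow
solve (with frozen per-node area and compliance), the intracellular
signalling update at the new nodal pressures, and the per-node wall
solve returning the new luminal areas and compliances.  In strong
coupling this sequence is a fixed-point iteration on the nodal area
vector, stopped when the root-mean-square relative error (RMSRE)
between successive area iterates falls below ``epsilon``; weak coupling
performs exactly one pass.  The framework contains no randomness: a run
is a deterministic function of its configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .flow1d import (FluidProperties, FluidState, assemble_and_solve,
                     build_mesh, matched_impedance)
from .signalling import SignallingParams, SignallingState, step_signalling
from .units import MMHG
from .wall import ContractileParams, PassiveParams, WallBank

__all__ = [
    "CouplingConfig",
    "CoupledSimulation",
    "rmsre",
    "rmsre_guarded",
    "fsi_step",
    "run_simulation",
]


def rmsre(x, ref):
    """Root mean square relative error sqrt(mean(((x-ref)/ref)^2)).

    Every ``ref`` entry must be nonzero; use :func:`rmsre_guarded` for
    signals that cross zero.
    """
    x = np.asarray(x, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if x.shape != ref.shape or x.size == 0:
        raise ValueError("rmsre needs equal, nonzero-length inputs")
    if np.any(ref == 0.0):
        raise ValueError("rmsre reference contains zeros; use the guarded "
                         "variant for signals crossing zero")
    return float(np.sqrt(np.mean(((x - ref) / ref) ** 2)))


def rmsre_guarded(x, ref, floor_frac: float = 1e-12):
    """RMSRE excluding entries where |ref| < floor_frac * max|ref|.

    Returns ``(value, n_excluded)``.  Intended for comparing flow
    traces that may cross zero; the coupling criterion itself always
    operates on areas, which are bounded away from zero.
    """
    x = np.asarray(x, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if x.shape != ref.shape or x.size == 0:
        raise ValueError("rmsre needs equal, nonzero-length inputs")
    floor = floor_frac * np.max(np.abs(ref))
    keep = np.abs(ref) >= max(floor, 0.0)
    if not np.any(keep):
        raise ValueError("all reference entries below the guard floor")
    val = float(np.sqrt(np.mean(((x[keep] - ref[keep]) / ref[keep]) ** 2)))
    return val, int(np.sum(~keep))


@dataclass(frozen=True)
class CouplingConfig:
    """Numerical settings of the coupled solver.

    mode                   "strong" (fixed point) or "weak" (one pass)
    epsilon                RMSRE tolerance on areas (strong mode)
    max_iterations         fixed-point iteration cap (failure -> error)
    averaged_active_stress single trans-mural u_fs instead of per-domain
    dt, T_end              time step and horizon (s)
    output_stride          probe sampling interval (s)
    under_relaxation       area update factor (1.0 = plain fixed point)
    friction               "explicit" (frozen at level n) or "implicit"
    junction               "static" or "total" pressure continuity
    P_ext_mmHg             external pressure on the outer wall surface
    """

    mode: str = "strong"
    epsilon: float = 1e-6
    max_iterations: int = 50
    averaged_active_stress: bool = False
    dt: float = 2.5e-4
    T_end: float = 5.0
    output_stride: float = 0.01
    under_relaxation: float = 1.0
    friction: str = "explicit"
    junction: str = "static"
    P_ext_mmHg: float = 10.0

    def __post_init__(self):
        if self.mode not in ("strong", "weak"):
            raise ValueError("mode must be 'strong' or 'weak'")
        if self.epsilon <= 0 or self.dt <= 0:
            raise ValueError("epsilon and dt must be > 0")
        if self.output_stride < self.dt:
            raise ValueError("output_stride must be >= dt")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


class CoupledSimulation:
    """Mutable state of one coupled run on a network.

    ``inlet_pressure`` is a callable t -> mmHg.  Probes default to the
    node nearest the axial midpoint of every segment.
    """

    def __init__(self, network, inlet_pressure, config: CouplingConfig,
                 signalling_params: SignallingParams,
                 passive: PassiveParams, contractile: ContractileParams,
                 fluid: FluidProperties | None = None):
        from .network import validate_topology
        issues = validate_topology(network)
        if issues:
            raise ValueError(f"invalid network: {issues}")
        self.network = network
        self.config = config
        self.inlet_pressure = inlet_pressure
        self.sig_params = signalling_params
        self.fluid_props = fluid or FluidProperties()

        self.mesh = build_mesh(network)
        n = self.mesh.n_nodes
        geoms = [network.segment(self.mesh.seg_of_node[i]).geometry
                 for i in range(n)]
        self.bank = WallBank(geoms, passive, contractile,
                             P_ext=config.P_ext_mmHg * MMHG,
                             averaged=config.averaged_active_stress)
        P0 = float(inlet_pressure(0.0)) * MMHG
        self.state = FluidState.initial(n, P0)
        self.signalling = SignallingState.zeros(n)
        # initial compliance snapshot at the load-free area
        self.bank.C_A = self.bank.compliance(
            np.full(n, P0), self.signalling.xi[:, 5], self.signalling.xi7,
            self.bank.A, self.bank.u_fs)
        self.t = 0.0
        self.iteration_log = []   # (t, iterations, final rmsre)

        self._outlet_spec = []
        for sid, node in zip(network.outlet_segments(),
                             self.mesh.outlet_nodes):
            o = network.outlets[sid]
            self._outlet_spec.append(
                (node, o["P_out_mmHg"] * MMHG, o["Z"]))

        # probe nodes at mid-length of each segment
        self.probe_nodes = {}
        for seg in network.segments:
            ids = self.mesh.seg_nodes[seg.id]
            z = self.mesh.z_of_node[ids]
            self.probe_nodes[seg.id] = int(ids[np.argmin(np.abs(z - seg.L / 2))])

    def _outlets(self, A, C_A):
        out = {}
        for node, P_out, Z in self._outlet_spec:
            if Z == "matched":
                z_val = float(matched_impedance(A[node], C_A[node],
                                                self.fluid_props))
            else:
                z_val = float(Z)
            out[node] = (P_out, z_val)
        return out

    def step(self):
        """Advance one time step (strong or weak per config)."""
        cfg = self.config
        dt = cfg.dt
        t_new = self.t + dt
        P_in = float(self.inlet_pressure(t_new)) * MMHG

        A_k = self.bank.A.copy()
        C_k = self.bank.C_A.copy()
        P_old_mmhg = self.state.P / MMHG
        n_pass = 1 if cfg.mode == "weak" else cfg.max_iterations
        converged = cfg.mode == "weak"
        r = np.nan
        for it in range(n_pass):
            P_new, Q_new = assemble_and_solve(
                self.mesh, self.state, A_k, C_k, dt, P_in,
                self._outlets(A_k, C_k), self.fluid_props,
                friction=cfg.friction, junction=cfg.junction)
            sig_new = step_signalling(self.signalling, P_new / MMHG, dt,
                                      self.sig_params, P_old=P_old_mmhg)
            A_new, u_new = self.bank.step(P_new, sig_new.xi[:, 5],
                                          sig_new.xi7, dt)
            C_new = self.bank.compliance(P_new, sig_new.xi[:, 5],
                                         sig_new.xi7, A_new, u_new)
            if cfg.mode == "weak":
                A_k, C_k = A_new, C_new
                break
            r = rmsre(A_new, A_k)
            w = cfg.under_relaxation
            A_k = (1.0 - w) * A_k + w * A_new
            C_k = (1.0 - w) * C_k + w * C_new
            if r < cfg.epsilon:
                converged = True
                break
        if not converged:
            raise RuntimeError(
                f"fixed-point coupling did not converge at t={t_new:.6f}: "
                f"RMSRE {r:.3e} after {cfg.max_iterations} iterations")
        self.iteration_log.append((t_new, it + 1, r))
        self.bank.commit(A_new, u_new)
        self.bank.C_A = C_new
        self.state = self.state.advance(P_new, Q_new)
        self.signalling = sig_new
        self.t = t_new
        return self

    def probe_sample(self):
        """Current values at every probe: dict seg_id -> dict."""
        out = {}
        for sid, node in self.probe_nodes.items():
            seg = self.network.segment(sid)
            A = self.bank.A[node]
            u = self.bank.u_fs[node]
            out[sid] = {
                "t_s": self.t,
                "z_cm": float(self.mesh.z_of_node[node]),
                "P_mmHg": self.state.P[node] / MMHG,
                "Q_ml_s": self.state.Q[node],
                "A_cm2": A,
                "d_i_um": 2e4 * np.sqrt(A / np.pi),
                "u_fs_mean": float(np.mean(u)),
                "xi": self.signalling.xi[node].copy(),
            }
        return out


def fsi_step(sim: CoupledSimulation, t=None, dt=None,
             config: CouplingConfig | None = None) -> CoupledSimulation:
    """Advance ``sim`` by one coupled step (strong or weak per its
    configuration); thin functional wrapper over
    :meth:`CoupledSimulation.step`."""
    if config is not None and config is not sim.config:
        sim.config = config
    return sim.step()


def run_simulation(sim: CoupledSimulation, T_end: float | None = None,
                   progress: bool = False):
    """Advance from the current time to ``T_end`` recording every
    ``output_stride``; returns a :class:`~myoflow.records.RunRecord`."""
    from .records import RunRecord

    cfg = sim.config
    T_end = cfg.T_end if T_end is None else T_end
    stride_steps = max(1, int(round(cfg.output_stride / cfg.dt)))
    n_steps = int(round((T_end - sim.t) / cfg.dt))

    samples = {sid: [] for sid in sim.probe_nodes}
    times = []

    def record():
        times.append(sim.t)
        for sid, vals in sim.probe_sample().items():
            samples[sid].append(vals)

    record()
    for k in range(n_steps):
        sim.step()
        if (k + 1) % stride_steps == 0:
            record()
        if progress and (k + 1) % max(1, n_steps // 20) == 0:
            print(f"  t = {sim.t:.3f} s ({100 * (k + 1) / n_steps:.0f}%)",
                  flush=True)
    return RunRecord.from_samples(times, samples, sim)
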