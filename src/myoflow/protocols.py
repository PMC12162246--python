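"""Pressure protocols, pharmacological condition presets and runners.

Protocols generate the luminal (or network-inlet) pressure as a
function of time: alternating two-level sequences, staircases of
sequential step increases, ramps, a periodic inlet signal with a
time-varying mean (the synthetic network stress-test input), or
tabulated signals from file.  Discontinuous level changes are smoothed
by linear transitions of configurable duration (1 s by default).

Condition presets modify the signalling parameters the way bath
interventions do in a pressure-myograph experiment: ``control`` is the
identity; ``diltiazem_30uM`` flattens the pressure-to-Ca2+ link (L-type
channel block leaves only a marginal stretch-operated influx);
``zero_ca`` removes extracellular Ca2+, forcing the Ca2+ level and LC20
phosphorylation to zero so the wall becomes exactly passive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .signalling import ChiLink, SignallingParams, SignallingState, \
    step_signalling
from .units import MMHG, UM
from .wall import ContractileParams, PassiveParams, WallBank, WallGeometry

__all__ = [
    "PressureProtocol",
    "ConditionPreset",
    "CONDITION_PRESETS",
    "make_pressure_signal",
    "apply_condition",
    "run_myograph",
    "grid_search_tau",
    "run_network_experiment",
    "network_summary",
]


@dataclass(frozen=True)
class PressureProtocol:
    """Piecewise-linear pressure signal plus optional periodic part.

    ``knots``: ((t_s, P_mmHg), ...) with strictly increasing times and
    positive pressures; between knots the signal is linear.  For the
    ``periodic_drift`` kind a sinusoid of ``amplitude_mmHg`` at
    ``frequency_Hz`` rides on the piecewise-linear mean.
    """

    kind: str
    knots: tuple
    amplitude_mmHg: float = 0.0
    frequency_Hz: float = 0.0
    transition_s: float = 1.0

    def __post_init__(self):
        t = np.array([k[0] for k in self.knots], dtype=float)
        p = np.array([k[1] for k in self.knots], dtype=float)
        if len(t) < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("protocol times must be strictly increasing")
        if np.any(p <= 0):
            raise ValueError("protocol pressures must be positive")

    @property
    def horizon(self) -> float:
        return float(self.knots[-1][0])

    # -- constructors ------------------------------------------------------

    @classmethod
    def alternating(cls, low: float = 10.0, high: float = 60.0,
                    hold_s: float = 300.0, n_cycles: int = 3,
                    transition_s: float = 1.0) -> "PressureProtocol":
        """Alternated two-level protocol low/high/low/... starting and
        ending at ``low``; each plateau lasts ``hold_s``."""
        knots = [(0.0, low)]
        t = hold_s
        for _ in range(n_cycles):
            for level in (high, low):
                knots.append((t, knots[-1][1]))
                knots.append((t + transition_s, level))
                t += hold_s + transition_s
        knots.append((t, knots[-1][1]))
        return cls("alternating", tuple(knots), transition_s=transition_s)

    @classmethod
    def staircase(cls, levels=tuple(range(10, 121, 10)),
                  hold_s: float = 300.0,
                  transition_s: float = 1.0) -> "PressureProtocol":
        """Sequential step increases, each level held ``hold_s``."""
        levels = tuple(levels)
        knots = [(0.0, float(levels[0]))]
        t = hold_s
        for level in levels[1:]:
            knots.append((t, knots[-1][1]))
            knots.append((t + transition_s, float(level)))
            t += hold_s + transition_s
        knots.append((t, knots[-1][1]))
        return cls("staircase", tuple(knots), transition_s=transition_s)

    @classmethod
    def ramp(cls, P0: float = 50.0, P1: float = 120.0,
             t_start: float = 120.0, t_end: float = 130.0,
             T_end: float = 360.0) -> "PressureProtocol":
        """Hold ``P0``, ramp linearly to ``P1`` over
        [t_start, t_end], hold to ``T_end``."""
        return cls("ramp", ((0.0, P0), (t_start, P0), (t_end, P1),
                            (T_end, P1)),
                   transition_s=t_end - t_start)

    @classmethod
    def periodic_drift(cls, mean_knots=((0.0, 66.0), (1.25, 84.0),
                                        (2.5, 62.0), (3.75, 78.0),
                                        (5.0, 70.0)),
                       amplitude_mmHg: float = 8.0,
                       frequency_Hz: float = 5.0) -> "PressureProtocol":
        """Periodic signal with slowly drifting mean: the synthetic
        network inlet used for the numerical-settings stress test
        (sinusoid at the rat heart rate riding on piecewise-linear
        drift)."""
        return cls("periodic_drift", tuple(mean_knots),
                   amplitude_mmHg=amplitude_mmHg,
                   frequency_Hz=frequency_Hz)

    @classmethod
    def from_file(cls, path) -> "PressureProtocol":
        """Tabulated signal: CSV with columns t_s, P_mmHg."""
        df = pd.read_csv(path, comment="#")
        knots = tuple((float(t), float(p))
                      for t, p in zip(df["t_s"], df["P_mmHg"]))
        return cls("from_file", knots)


def make_pressure_signal(protocol: PressureProtocol, t):
    """Evaluate the protocol pressure (mmHg) at time(s) ``t`` (s)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(t > protocol.horizon + 1e-9):
        raise ValueError(
            f"t outside protocol horizon [0, {protocol.horizon}]")
    tk = np.array([k[0] for k in protocol.knots])
    pk = np.array([k[1] for k in protocol.knots])
    p = np.interp(t, tk, pk)
    if protocol.kind == "periodic_drift":
        p = p + protocol.amplitude_mmHg \
            * np.sin(2.0 * np.pi * protocol.frequency_Hz * t)
    return float(p) if p.ndim == 0 else p


# ------------------------------------------------------- condition presets

@dataclass(frozen=True)
class ConditionPreset:
    """Named pharmacological/bath condition.

    ``chi_overrides`` maps link index -> replacement :class:`ChiLink`;
    ``load_free_Do_um`` optionally overrides the vessel's load-free
    outer diameter (different animals are used for different bath
    conditions in the reference experiments).
    """

    name: str
    chi_overrides: dict = field(default_factory=dict)
    load_free_Do_um: float | None = None
    notes: str = ""


CONDITION_PRESETS = {
    "control": ConditionPreset("control", notes="physiological saline bath"),
    "diltiazem_30uM": ConditionPreset(
        "diltiazem_30uM",
        chi_overrides={0: ChiLink("pressure", midpoint=40.0, slope=0.02,
                                  floor=0.05, ceiling=0.15)},
        load_free_Do_um=150.0,
        notes="L-type Ca2+ channel block: pressure retains only a "
              "marginal stretch-operated influence on Ca2+"),
    "zero_ca": ConditionPreset(
        "zero_ca",
        chi_overrides={0: ChiLink("pressure", midpoint=40.0, slope=0.08,
                                  floor=0.0, ceiling=0.0),
                       5: ChiLink("xi0", midpoint=0.55, slope=8.0,
                                  floor=0.0, ceiling=0.0)},
        load_free_Do_um=230.0,
        notes="extracellular Ca2+ removal: no Ca2+ signal and no LC20 "
              "phosphorylation, wall exactly passive"),
}


def apply_condition(preset, params: SignallingParams) -> SignallingParams:
    """Return the signalling parameters under the given condition
    (name or :class:`ConditionPreset`); ``control`` is the identity
    (the same object is returned unchanged)."""
    if isinstance(preset, str):
        try:
            preset = CONDITION_PRESETS[preset]
        except KeyError:
            raise ValueError(f"unknown condition preset {preset!r}") from None
    if not preset.chi_overrides:
        return params
    table = list(params.chi_table)
    for idx, link in preset.chi_overrides.items():
        table[idx] = link
    return replace(params, chi_table=tuple(table))


# ------------------------------------------------------------ myograph run

def run_myograph(geometry: WallGeometry, preset, protocol: PressureProtocol,
                 dt: float, sig_params: SignallingParams,
                 passive: PassiveParams, contractile: ContractileParams,
                 T_end: float | None = None, P_ext_mmHg: float = 0.0,
                 mode: str = "per-domain",
                 record_stride: float | None = None) -> pd.DataFrame:
    """Cannulated-vessel experiment: the wall model alone driven by the
    prescribed luminal pressure (no flow, same pressure at both ends).

    The preset's load-free diameter override, if any, rescales the
    geometry (keeping h_w).  Returns a DataFrame with columns
    t_s, P_mmHg, d_i_um, d_o_um, xi0..xi7, u_fs_mean, A_cm2.
    """
    if isinstance(preset, str):
        if preset not in CONDITION_PRESETS:
            raise ValueError(f"unknown condition preset {preset!r}")
        preset = CONDITION_PRESETS[preset]
    sig = apply_condition(preset, sig_params)
    geom = geometry
    if preset.load_free_Do_um is not None:
        geom = WallGeometry.from_outer_diameter(
            preset.load_free_Do_um * UM, geometry.h_w,
            k_omega=geometry.k_omega, lambda_z=geometry.lambda_z,
            n_CD=geometry.n_CD)

    T_end = protocol.horizon if T_end is None else T_end
    stride = max(1, int(round((record_stride or dt) / dt)))
    n_steps = int(round(T_end / dt))

    bank = WallBank([geom], passive, contractile,
                    P_ext=P_ext_mmHg * MMHG, averaged=(mode == "averaged"))
    sig_state = SignallingState.zeros(1)
    R_o2 = (geom.R_i + geom.H) ** 2

    rows = []
    def record(t, P_mmhg):
        A = bank.A[0]
        r_o = np.sqrt((R_o2 - geom.R_i**2)
                      / (geom.k_omega * geom.lambda_z) + A / np.pi)
        row = {"t_s": t, "P_mmHg": P_mmhg,
               "d_i_um": 2e4 * np.sqrt(A / np.pi), "d_o_um": 2e4 * r_o}
        for i in range(7):
            row[f"xi{i}"] = sig_state.xi[0, i]
        row["xi7"] = 1.0 - sig_state.xi[0, 6]
        row["u_fs_mean"] = float(np.mean(bank.u_fs[0]))
        row["A_cm2"] = A
        return row

    P_old = make_pressure_signal(protocol, 0.0)
    rows.append(record(0.0, P_old))
    for k in range(n_steps):
        t_new = (k + 1) * dt
        P_new = make_pressure_signal(protocol, min(t_new, protocol.horizon))
        sig_state = step_signalling(sig_state, P_new, dt, sig, P_old=P_old)
        A_new, u_new = bank.step(np.array([P_new * MMHG]),
                                 sig_state.xi[:, 5], sig_state.xi7, dt)
        bank.commit(A_new, u_new)
        if (k + 1) % stride == 0:
            rows.append(record(t_new, P_new))
        P_old = P_new
    return pd.DataFrame(rows)


def grid_search_tau(reference: pd.DataFrame, geometry: WallGeometry,
                    preset, protocol: PressureProtocol, dt: float,
                    sig_params: SignallingParams, passive: PassiveParams,
                    contractile: ContractileParams,
                    tau_c_values=(1.0, 5.0, 10.0, 30.0, 60.0),
                    tau_m_values=None, **myograph_kw) -> pd.DataFrame:
    """RMSRE table of simulated vs reference outer-diameter traces over
    the (tau_c, tau_m) grid.

    ``reference`` needs columns t_s and d_o_um.  Returns a DataFrame
    indexed by tau_c with one column per tau_m.
    """
    from .coupling import rmsre
    from .wall import TAU_M_REF

    if tau_m_values is None:
        tau_m_values = tuple(f * TAU_M_REF for f in (1e3, 1e2, 10.0, 1.0, 0.1))
    t_ref = reference["t_s"].to_numpy()
    d_ref = reference["d_o_um"].to_numpy()

    table = np.empty((len(tau_c_values), len(tau_m_values)))
    for i, tc in enumerate(tau_c_values):
        for j, tm in enumerate(tau_m_values):
            df = run_myograph(geometry, preset, protocol, dt,
                              sig_params.with_tau_c(tc), passive,
                              replace(contractile, tau_m=tm),
                              **myograph_kw)
            d_sim = np.interp(t_ref, df["t_s"].to_numpy(),
                              df["d_o_um"].to_numpy())
            table[i, j] = rmsre(d_sim, d_ref)
    return pd.DataFrame(table, index=list(tau_c_values),
                        columns=[f"{tm:.4e}" for tm in tau_m_values])


# ------------------------------------------------------ network experiments

def run_network_experiment(network, protocol: PressureProtocol, config,
                           sig_params: SignallingParams,
                           passive: PassiveParams,
                           contractile: ContractileParams,
                           presets=("control", "zero_ca"), fluid=None,
                           progress: bool = False) -> dict:
    """Coupled network runs under one or more condition presets.

    Returns ``{"records": {preset: RunRecord}, "summary": {...}}``; the
    summary holds per-generation steady diameters, the control/zero_ca
    diameter ratios and the G0 flow gain (steady final / pre-transient)
    when the protocol is a ramp.
    """
    from .coupling import CoupledSimulation, run_simulation

    records = {}
    for name in presets:
        sig = apply_condition(name, sig_params)
        sim = CoupledSimulation(
            network, lambda t: make_pressure_signal(protocol, t),
            config, sig, passive, contractile, fluid=fluid)
        if progress:
            print(f"[{name}]", flush=True)
        records[name] = run_simulation(sim, progress=progress)
        records[name].meta["preset"] = name
    return {"records": records,
            "summary": network_summary(records, network, protocol)}


def network_summary(records: dict, network, protocol) -> dict:
    """Steady-state summaries mirroring the network figures: final
    per-generation mid-vessel diameters, diameter ratios
    control / zero_ca, and G0 flow before/after the pressure change."""
    gens = network.generations()
    reps = {g: sids[0] for g, sids in gens.items()}
    out: dict = {"generations": {g: list(s) for g, s in gens.items()}}

    per_preset = {}
    for name, rec in records.items():
        entry = {"d_i_um_final": {}, "Q_ml_s_final": {}}
        for g, sid in reps.items():
            t, d = rec.trace(sid, "d_i_um")
            entry["d_i_um_final"][g] = float(d[-1])
            t, q = rec.trace(sid, "Q_ml_s")
            entry["Q_ml_s_final"][g] = float(q[-1])
        t0, q0 = rec.trace(reps[0], "Q_ml_s")
        if protocol.kind == "ramp":
            t_ramp = protocol.knots[1][0]
            pre = q0[t0 <= t_ramp]
            q_pre = float(pre[-1]) if len(pre) else float(q0[0])
            entry["Q_G0_pre"] = q_pre
            entry["Q_G0_final"] = float(q0[-1])
            # with P_in = P_out before the ramp the pre-surge flow is 0,
            # so the response is reported as an increase, not a ratio
            entry["Q_G0_increase"] = entry["Q_G0_final"] - q_pre
        per_preset[name] = entry
    out["presets"] = per_preset

    if "control" in records and "zero_ca" in records:
        out["d_ratio_control_over_zero_ca"] = {
            g: per_preset["control"]["d_i_um_final"][g]
            / per_preset["zero_ca"]["d_i_um_final"][g]
            for g in reps}
    return out
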