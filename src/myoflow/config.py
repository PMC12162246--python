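"""Configuration loading/validation and run comparison reports.

Configurations are YAML with explicit unit-suffixed keys.  Loading
applies defaults, validates every field (reporting the dotted field
path on failure) and returns a fully built :class:`SimulationConfig`
whose ``provenance`` map documents, for every defaulted value, where
the default comes from in plain language (reference study conditions
vs package choices).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .coupling import CouplingConfig, rmsre, rmsre_guarded
from .defaults import (default_contractile_params, default_passive_params,
                       default_signalling_params)
from .flow1d import FluidProperties
from .network import NetworkTopology, default_mca_tree, load_network
from .protocols import PressureProtocol
from .records import RunRecord
from .wall import TAU_M_REF

__all__ = ["SimulationConfig", "load_config", "dump_config", "compare_runs"]

_DEFAULTS = {
    "network": "mca_tree",
    "protocol": {"kind": "periodic_drift"},
    "preset": "control",
    "coupling": {
        "mode": "strong",
        "dt_s": 2.5e-4,
        "T_end_s": 5.0,
        "output_stride_s": 0.01,
        "epsilon": 1e-6,
        "max_iterations": 50,
        "averaged_active_stress": False,
        "under_relaxation": 1.0,
        "friction": "explicit",
        "junction": "static",
    },
    "fluid": {"rho_g_cm3": 1.04, "mu_poise": 0.05},
    "pressures": {"P_ext_mmHg": 10.0},
    "signalling": {"tau_c_s": 10.0},
    "wall": {"tau_m_s": 1e3 * TAU_M_REF},
    "output_dir": "out",
}

#: plain-language origin of each default the loader applies
_PROVENANCE = {
    "coupling.epsilon": "reference fsi coupling tolerance",
    "coupling.dt_s": "reference network time step (accuracy/cost optimum)",
    "fluid.rho_g_cm3": "reference blood density",
    "fluid.mu_poise": "reference blood viscosity",
    "pressures.P_ext_mmHg": "reference external (tissue) pressure",
    "signalling.tau_c_s": "identified signalling transduction constant",
    "wall.tau_m_s": "identified filament-sliding constant (1000x the "
                    "mouse-aorta reference value)",
    "network": "idealized MCA tree shipped with the package",
    "protocol": "synthetic variable-mean periodic inlet signal",
}


@dataclass
class SimulationConfig:
    """Fully validated run configuration with built component objects."""

    network: NetworkTopology
    protocol: PressureProtocol
    preset: str
    coupling: CouplingConfig
    fluid: FluidProperties
    sig_params: object
    passive: object
    contractile: object
    output_dir: str
    raw: dict = field(default_factory=dict, repr=False)
    provenance: dict = field(default_factory=dict, repr=False)


def _merge_defaults(doc: dict, base_dir: Path):
    merged = copy.deepcopy(_DEFAULTS)
    provenance = dict(_PROVENANCE)

    def merge(dst, src, path=""):
        for k, v in src.items():
            p = f"{path}.{k}" if path else k
            if k not in dst:
                raise ValueError(f"unknown config field {p!r}")
            if p == "protocol":
                # per-kind schema, validated when the protocol is built
                dst[k] = v
                provenance.pop(p, None)
            elif isinstance(dst[k], dict) and isinstance(v, dict):
                merge(dst[k], v, p)
            else:
                dst[k] = v
                provenance.pop(p, None)  # user-supplied, not a default
    merge(merged, doc or {})
    return merged, provenance


def _build_protocol(spec) -> PressureProtocol:
    if isinstance(spec, str):
        return PressureProtocol.from_file(spec)
    spec = dict(spec)
    kind = spec.pop("kind", "periodic_drift")
    try:
        if kind == "alternating":
            return PressureProtocol.alternating(
                low=spec.pop("low_mmHg", 10.0),
                high=spec.pop("high_mmHg", 60.0),
                hold_s=spec.pop("hold_s", 300.0),
                n_cycles=spec.pop("n_cycles", 3),
                transition_s=spec.pop("transition_s", 1.0))
        if kind == "staircase":
            return PressureProtocol.staircase(
                levels=tuple(spec.pop("levels_mmHg",
                                      tuple(range(10, 121, 10)))),
                hold_s=spec.pop("hold_s", 300.0),
                transition_s=spec.pop("transition_s", 1.0))
        if kind == "ramp":
            return PressureProtocol.ramp(
                P0=spec.pop("P0_mmHg", 50.0), P1=spec.pop("P1_mmHg", 120.0),
                t_start=spec.pop("t_start_s", 120.0),
                t_end=spec.pop("t_end_s", 130.0),
                T_end=spec.pop("T_end_s", 360.0))
        if kind == "periodic_drift":
            kw = {}
            if "mean_knots" in spec:
                kw["mean_knots"] = tuple(
                    (float(t), float(p)) for t, p in spec.pop("mean_knots"))
            kw["amplitude_mmHg"] = spec.pop("amplitude_mmHg", 8.0)
            kw["frequency_Hz"] = spec.pop("frequency_Hz", 5.0)
            return PressureProtocol.periodic_drift(**kw)
        if kind == "from_file":
            return PressureProtocol.from_file(spec.pop("path"))
        if kind == "knots":
            return PressureProtocol(
                "from_file",
                tuple((float(t), float(p)) for t, p in spec.pop("knots")),
                transition_s=spec.pop("transition_s", 1.0))
    finally:
        if spec:
            raise ValueError(
                f"protocol: unknown fields {sorted(spec)} for kind {kind!r}")
    raise ValueError(f"protocol.kind: unknown kind {kind!r}")


def load_config(source) -> SimulationConfig:
    """Load and validate a config from a YAML path, string or dict."""
    if isinstance(source, dict):
        doc, base_dir = source, Path.cwd()
    elif isinstance(source, Path) or "\n" not in str(source):
        path = Path(source)
        if not path.exists():
            raise ValueError(f"config file {path} does not exist")
        doc, base_dir = yaml.safe_load(path.read_text()) or {}, path.parent
    else:
        doc, base_dir = yaml.safe_load(str(source)) or {}, Path.cwd()

    merged, provenance = _merge_defaults(doc, base_dir)

    cp = merged["coupling"]
    for key, cond in [("dt_s", cp["dt_s"] > 0),
                      ("T_end_s", cp["T_end_s"] > 0),
                      ("epsilon", cp["epsilon"] > 0),
                      ("output_stride_s",
                       cp["output_stride_s"] >= cp["dt_s"])]:
        if not cond:
            raise ValueError(f"coupling.{key}: invalid value {cp[key]!r}")
    if merged["fluid"]["rho_g_cm3"] <= 0:
        raise ValueError("fluid.rho_g_cm3: must be > 0")
    if merged["fluid"]["mu_poise"] <= 0:
        raise ValueError("fluid.mu_poise: must be > 0")
    if merged["signalling"]["tau_c_s"] < 0:
        raise ValueError("signalling.tau_c_s: must be >= 0")
    if merged["wall"]["tau_m_s"] <= 0:
        raise ValueError("wall.tau_m_s: must be > 0")

    if merged["network"] == "mca_tree":
        network = default_mca_tree()
    else:
        net_path = Path(merged["network"])
        if not net_path.is_absolute():
            net_path = base_dir / net_path
        if not net_path.exists():
            raise ValueError(f"network: file {net_path} does not exist")
        network = load_network(net_path)

    protocol = _build_protocol(merged["protocol"])
    coupling = CouplingConfig(
        mode=cp["mode"], epsilon=cp["epsilon"],
        max_iterations=cp["max_iterations"],
        averaged_active_stress=cp["averaged_active_stress"],
        dt=cp["dt_s"], T_end=cp["T_end_s"],
        output_stride=cp["output_stride_s"],
        under_relaxation=cp["under_relaxation"],
        friction=cp["friction"], junction=cp["junction"],
        P_ext_mmHg=merged["pressures"]["P_ext_mmHg"])

    return SimulationConfig(
        network=network,
        protocol=protocol,
        preset=merged["preset"],
        coupling=coupling,
        fluid=FluidProperties(rho=merged["fluid"]["rho_g_cm3"],
                              mu=merged["fluid"]["mu_poise"]),
        sig_params=default_signalling_params(merged["signalling"]["tau_c_s"]),
        passive=default_passive_params(),
        contractile=default_contractile_params(merged["wall"]["tau_m_s"]),
        output_dir=merged["output_dir"],
        raw=merged,
        provenance=provenance,
    )


def dump_config(cfg: SimulationConfig, path=None) -> str:
    """Serialize the normalized configuration; load -> dump -> load is
    idempotent on the normalized document."""
    text = yaml.safe_dump(cfg.raw, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


# -------------------------------------------------------------- comparison

def _generation_of(vessel_id: str) -> str:
    return vessel_id.split("_")[0]


def compare_runs(ref: RunRecord, test: RunRecord, every: float = 0.01):
    """Per-generation RMSRE of mid-vessel flow and area traces.

    Both records are linearly resampled onto the common grid with
    spacing ``every`` (s).  Returns ``(table, summary)``: the table has
    one row per generation with Q and A RMSRE (flow uses the guarded
    RMSRE since flow may cross zero); the summary reports
    mean/min/max across generations with the extremal generation
    labels.
    """
    if set(ref.vessels()) != set(test.vessels()):
        raise ValueError("probe (vessel) sets differ between records")
    t0 = max(ref.data["t_s"].min(), test.data["t_s"].min())
    t1 = min(ref.data["t_s"].max(), test.data["t_s"].max())
    if t1 <= t0:
        raise ValueError("records have no overlapping time range")
    grid = np.arange(t0, t1 + 0.5 * every, every)

    def resample(rec, sid, col):
        t, v = rec.trace(sid, col)
        return np.interp(grid, t, v)

    gens: dict = {}
    for sid in ref.vessels():
        gens.setdefault(_generation_of(sid), []).append(sid)

    rows = []
    for gen in sorted(gens):
        q_errs, a_errs = [], []
        for sid in gens[gen]:
            q_ref = resample(ref, sid, "Q_ml_s")
            q_tst = resample(test, sid, "Q_ml_s")
            if np.allclose(q_ref, q_tst):
                q_errs.append(0.0)
            else:
                q_errs.append(rmsre_guarded(q_tst, q_ref)[0])
            a_errs.append(rmsre(resample(test, sid, "A_cm2"),
                                resample(ref, sid, "A_cm2")))
        rows.append({"generation": gen,
                     "Q_rmsre": float(np.mean(q_errs)),
                     "A_rmsre": float(np.mean(a_errs))})
    table = pd.DataFrame(rows).set_index("generation")

    summary = {}
    for col in ("Q_rmsre", "A_rmsre"):
        v = table[col]
        summary[col] = {
            "mean": float(v.mean()),
            "min": float(v.min()), "min_generation": str(v.idxmin()),
            "max": float(v.max()), "max_generation": str(v.idxmax()),
        }
    return table, summary
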