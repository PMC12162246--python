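"""Vascular network data model, validation and the idealized MCA tree.

A network is a set of vessel segments connected by directed junctions
(one parent, one or more daughters), with a single inlet segment and an
outlet (pressure + characteristic impedance) on every terminal segment.
The shipped generator builds the idealized symmetric middle-cerebral-
artery tree of four generations G0..G3 (1 + 2 + 4 + 8 = 15 segments):
daughter load-free diameters follow the parent-daughter area ratio
(d_child = d_parent sqrt(area_ratio / 2)) and wall thickness ratios
decrease along the tree as prescribed fractions of the G0 value.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .units import UM
from .wall import WallGeometry

__all__ = [
    "VesselSegment",
    "NetworkTopology",
    "build_idealized_mca_tree",
    "validate_topology",
    "load_network",
    "dump_network",
    "default_mca_tree",
]


@dataclass(frozen=True)
class VesselSegment:
    """One vessel: stretched length ``L`` (cm, accounting for lambda_z),
    load-free wall geometry, spatial discretization and condition
    preset reference."""

    id: str
    L: float
    geometry: WallGeometry
    elements: int = 2
    preset: str = "control"
    generation: int | None = None

    def __post_init__(self):
        if self.L <= 0:
            raise ValueError(f"segment {self.id}: L must be > 0")
        if self.elements < 1:
            raise ValueError(f"segment {self.id}: element count must be >= 1")


@dataclass
class NetworkTopology:
    """Segments + directed junctions + inlet/outlet closure.

    ``junctions`` is a list of ``(parent_id, [child_ids])``;
    ``outlets`` maps terminal segment id to
    ``{"P_out_mmHg": float, "Z": "matched" | float}``.
    """

    segments: list
    junctions: list
    inlet: str
    outlets: dict

    def segment(self, seg_id: str) -> VesselSegment:
        for s in self.segments:
            if s.id == seg_id:
                return s
        raise KeyError(seg_id)

    def outlet_segments(self) -> list:
        """Terminal segments in declaration order."""
        children = {c for _, cs in self.junctions for c in cs}
        parents = {p for p, _ in self.junctions}
        return [s.id for s in self.segments
                if s.id not in parents]

    def generations(self) -> dict:
        """Map generation index -> list of segment ids (for trees built
        with generation tags; falls back to distance from the inlet)."""
        if all(s.generation is not None for s in self.segments):
            gens: dict = {}
            for s in self.segments:
                gens.setdefault(s.generation, []).append(s.id)
            return dict(sorted(gens.items()))
        depth = {self.inlet: 0}
        frontier = [self.inlet]
        jmap = {p: cs for p, cs in self.junctions}
        while frontier:
            nxt = []
            for p in frontier:
                for c in jmap.get(p, []):
                    depth[c] = depth[p] + 1
                    nxt.append(c)
            frontier = nxt
        gens = {}
        for sid, d in depth.items():
            gens.setdefault(d, []).append(sid)
        return dict(sorted(gens.items()))


def build_idealized_mca_tree(
    g0_geometry: WallGeometry,
    lengths,
    area_ratio: float = 1.35,
    thickness_fractions=(0.9, 0.8, 0.7),
    elements: int = 2,
    P_out_mmHg: float = 50.0,
    Z="matched",
    preset: str = "control",
) -> NetworkTopology:
    """Symmetric binary tree of 4 generations branching from ``g0``.

    ``lengths``: stretched length (cm) per generation, length 4.
    Daughter diameters: d_child = d_parent sqrt(area_ratio / 2); wall
    thickness ratios of G1..G3 are the given fractions of G0's h_w.
    """
    if area_ratio <= 0:
        raise ValueError("area_ratio must be > 0")
    fr = tuple(thickness_fractions)
    if len(fr) != 3 or any(f <= 0 or f > 1 for f in fr):
        raise ValueError("thickness_fractions must be 3 values in (0, 1]")
    lengths = tuple(lengths)
    if len(lengths) != 4:
        raise ValueError("need one length per generation G0..G3")

    scale = np.sqrt(area_ratio / 2.0)
    h0 = g0_geometry.h_w
    segments = [replace(VesselSegment("G0", lengths[0], g0_geometry,
                                      elements, preset), generation=0)]
    junctions = []
    prev_ids = ["G0"]
    for g in range(1, 4):
        D_o = g0_geometry.D_o * scale**g
        geom = WallGeometry.from_outer_diameter(
            D_o, h0 * fr[g - 1],
            k_omega=g0_geometry.k_omega, lambda_z=g0_geometry.lambda_z,
            n_CD=g0_geometry.n_CD)
        new_ids = []
        for p_idx, parent in enumerate(prev_ids):
            kids = []
            for b in range(2):
                sid = f"G{g}_{2 * p_idx + b}"
                segments.append(VesselSegment(sid, lengths[g], geom,
                                              elements, preset,
                                              generation=g))
                kids.append(sid)
            junctions.append((parent, kids))
            new_ids.extend(kids)
        prev_ids = new_ids

    outlets = {sid: {"P_out_mmHg": float(P_out_mmHg), "Z": Z}
               for sid in prev_ids}
    return NetworkTopology(segments=segments, junctions=junctions,
                           inlet="G0", outlets=outlets)


def validate_topology(net: NetworkTopology) -> list:
    """Machine-readable diagnostics; empty list means the network is
    well-formed (connected, acyclic, single inlet, outlets complete,
    positive geometry)."""
    issues = []
    ids = [s.id for s in net.segments]
    if len(set(ids)) != len(ids):
        issues.append({"code": "duplicate-id",
                       "message": "duplicate segment ids"})
    id_set = set(ids)
    if net.inlet not in id_set:
        issues.append({"code": "missing-inlet",
                       "message": f"inlet segment {net.inlet!r} not found"})

    parent_count: dict = {i: 0 for i in ids}
    jmap: dict = {}
    for p, cs in net.junctions:
        for name in [p, *cs]:
            if name not in id_set:
                issues.append({"code": "unknown-segment",
                               "message": f"junction references {name!r}"})
        jmap.setdefault(p, []).extend(cs)
        for c in cs:
            if c in parent_count:
                parent_count[c] += 1
    for sid, cnt in parent_count.items():
        if sid == net.inlet:
            if cnt != 0:
                issues.append({"code": "inlet-has-parent",
                               "message": f"inlet {sid!r} is a daughter"})
        elif cnt == 0:
            issues.append({"code": "orphan",
                           "message": f"segment {sid!r} is unreachable "
                           "(no parent junction)"})
        elif cnt > 1:
            issues.append({"code": "multiple-parents",
                           "message": f"segment {sid!r} has {cnt} parents"})

    # cycle detection by DFS from every segment
    state: dict = {}
    def dfs(sid, path):
        state[sid] = 1
        for c in jmap.get(sid, []):
            if state.get(c) == 1:
                issues.append({"code": "cycle",
                               "message": "cycle detected: "
                               + " -> ".join(path + [c])})
                return True
            if state.get(c) is None and dfs(c, path + [c]):
                return True
        state[sid] = 2
        return False
    for sid in ids:
        if state.get(sid) is None:
            if dfs(sid, [sid]):
                break

    terminals = [sid for sid in ids if sid not in jmap]
    for sid in terminals:
        if sid not in net.outlets:
            issues.append({"code": "missing-outlet",
                           "message": f"terminal segment {sid!r} has no "
                           "outlet"})
    for sid in net.outlets:
        if sid in jmap:
            issues.append({"code": "outlet-on-internal",
                           "message": f"outlet on non-terminal {sid!r}"})

    for s in net.segments:
        if s.L <= 0 or s.geometry.R_i <= 0 or s.geometry.H <= 0:
            issues.append({"code": "bad-geometry",
                           "message": f"segment {s.id!r} has non-positive "
                           "geometry"})
    return issues


# ------------------------------------------------------------ serialization

def _segment_to_dict(s: VesselSegment) -> dict:
    g = s.geometry
    d = {
        "id": s.id,
        "L_cm": float(s.L),
        "R_i_um": float(g.R_i / UM),
        "H_um": float(g.H / UM),
        "Do_um": float(g.D_o / UM),
        "h_w": float(g.h_w),
        "k_omega": float(g.k_omega),
        "lambda_z": float(g.lambda_z),
        "elements": int(s.elements),
        "preset": s.preset,
    }
    if s.generation is not None:
        d["generation"] = int(s.generation)
    return d


def _segment_from_dict(d: dict) -> VesselSegment:
    kw = dict(k_omega=float(d.get("k_omega", 1.0)),
              lambda_z=float(d.get("lambda_z", 1.0)))
    if "R_i_um" in d and "H_um" in d:
        geom = WallGeometry(R_i=float(d["R_i_um"]) * UM,
                            H=float(d["H_um"]) * UM, **kw)
    elif "Do_um" in d and "h_w" in d:
        geom = WallGeometry.from_outer_diameter(
            float(d["Do_um"]) * UM, float(d["h_w"]), **kw)
    else:
        raise ValueError(
            f"segment {d.get('id')!r}: give (R_i_um, H_um) or (Do_um, h_w)")
    return VesselSegment(id=str(d["id"]), L=float(d["L_cm"]), geometry=geom,
                         elements=int(d.get("elements", 2)),
                         preset=str(d.get("preset", "control")),
                         generation=d.get("generation"))


def dump_network(net: NetworkTopology, path=None) -> str:
    """Serialize to YAML; returns the text (and writes ``path`` if
    given).  Dump -> parse -> dump is idempotent: the canonical
    geometry fields (R_i_um, H_um) round-trip exactly."""
    doc = {
        "segments": [_segment_to_dict(s) for s in net.segments],
        "junctions": [{"parent": p, "children": list(cs)}
                      for p, cs in net.junctions],
        "inlet": net.inlet,
        "outlets": {sid: {"P_out_mmHg": float(o["P_out_mmHg"]),
                          "Z": o["Z"] if o["Z"] == "matched"
                          else float(o["Z"])}
                    for sid, o in net.outlets.items()},
    }
    text = yaml.safe_dump(doc, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def load_network(source) -> NetworkTopology:
    """Parse a network from a YAML path or string."""
    if isinstance(source, Path) or (isinstance(source, str)
                                    and "\n" not in source):
        text = Path(source).read_text()
    else:
        text = str(source)
    doc = yaml.safe_load(text)
    net = NetworkTopology(
        segments=[_segment_from_dict(d) for d in doc["segments"]],
        junctions=[(j["parent"], list(j["children"]))
                   for j in doc.get("junctions", [])],
        inlet=str(doc["inlet"]),
        outlets={str(k): {"P_out_mmHg": float(v["P_out_mmHg"]),
                          "Z": v["Z"] if v["Z"] == "matched"
                          else float(v["Z"])}
                 for k, v in doc.get("outlets", {}).items()},
    )
    return net


def default_mca_tree(**overrides) -> NetworkTopology:
    """The idealized rat-MCA tree with the shipped morphometry
    (src/myoflow/data/mca_tree.yaml)."""
    path = Path(__file__).parent / "data" / "mca_tree.yaml"
    spec = yaml.safe_load(path.read_text())
    spec.update(overrides)
    g0 = WallGeometry.from_outer_diameter(
        spec["g0_Do_um"] * UM, spec["g0_h_w"],
        k_omega=spec.get("k_omega", 1.0),
        lambda_z=spec.get("lambda_z", 1.0))
    return build_idealized_mca_tree(
        g0,
        lengths=spec["lengths_cm"],
        area_ratio=spec["area_ratio"],
        thickness_fractions=tuple(spec["thickness_fractions"]),
        elements=spec.get("elements", 2),
        P_out_mmHg=spec.get("P_out_mmHg", 50.0),
        Z=spec.get("Z", "matched"),
    )
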