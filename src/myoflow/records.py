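"""Time-series records of simulation runs.

A :class:`RunRecord` holds uniformly sampled per-probe traces (one
probe per vessel, at mid-length by default) plus the metadata needed to
reproduce the run.  Serialization is plain text: one CSV per record
with unit-suffixed headers and floats at 17 significant digits (the
shortest round-trip precision of IEEE doubles), plus a JSON metadata
sidecar embedded as a header comment line.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["RunRecord"]

_XI_COLS = [f"xi{i}" for i in range(8)]


@dataclass
class RunRecord:
    """Per-probe time series and run metadata.

    ``data`` is a tidy DataFrame with columns
    ``t_s, vessel_id, z_cm, P_mmHg, Q_ml_s, d_i_um, u_fs_mean, A_cm2,
    xi0..xi7``; ``meta`` carries the configuration snapshot, iteration
    counts and code version.
    """

    data: pd.DataFrame
    meta: dict = field(default_factory=dict)

    @classmethod
    def from_samples(cls, times, samples, sim) -> "RunRecord":
        from . import __version__

        rows = []
        for sid, entries in samples.items():
            for e in entries:
                row = {"t_s": e["t_s"], "vessel_id": sid,
                       "z_cm": e["z_cm"],
                       "P_mmHg": e["P_mmHg"], "Q_ml_s": e["Q_ml_s"],
                       "d_i_um": e["d_i_um"], "u_fs_mean": e["u_fs_mean"],
                       "A_cm2": e["A_cm2"]}
                for i in range(7):
                    row[f"xi{i}"] = e["xi"][i]
                row["xi7"] = 1.0 - e["xi"][6]
                rows.append(row)
        df = pd.DataFrame(rows)
        iters = [n for _, n, _ in sim.iteration_log]
        meta = {
            "code_version": __version__,
            "dt_s": sim.config.dt,
            "mode": sim.config.mode,
            "epsilon": sim.config.epsilon,
            "averaged_active_stress": sim.config.averaged_active_stress,
            "output_stride_s": sim.config.output_stride,
            "friction": sim.config.friction,
            "P_ext_mmHg": sim.config.P_ext_mmHg,
            "total_steps": len(iters),
            "total_fixed_point_iterations": int(np.sum(iters)) if iters else 0,
            "max_fixed_point_iterations": int(np.max(iters)) if iters else 0,
        }
        return cls(data=df, meta=meta)

    def vessels(self) -> list:
        return list(dict.fromkeys(self.data["vessel_id"]))

    def trace(self, vessel_id: str, column: str):
        """(t, values) for one vessel and column."""
        sub = self.data[self.data["vessel_id"] == vessel_id]
        return sub["t_s"].to_numpy(), sub[column].to_numpy()

    # -- serialization -----------------------------------------------------

    def to_csv(self, path) -> None:
        """Write the record; metadata rides in a '# meta: ...' first
        line so one file reproduces the full object."""
        path = Path(path)
        buf = io.StringIO()
        buf.write("# meta: " + json.dumps(self.meta, sort_keys=True) + "\n")
        self.data.to_csv(buf, index=False, float_format="%.17g")
        path.write_text(buf.getvalue())

    @classmethod
    def from_csv(cls, path) -> "RunRecord":
        path = Path(path)
        with path.open() as fh:
            first = fh.readline()
            meta = json.loads(first[len("# meta: "):]) \
                if first.startswith("# meta: ") else {}
            df = pd.read_csv(fh, float_precision="round_trip")
        return cls(data=df, meta=meta)

    def resampled(self, every: float, columns=("Q_ml_s", "A_cm2")):
        """Linear resampling of each vessel's traces onto a common grid
        with spacing ``every`` (s); returns {vessel: {col: array}} plus
        the grid."""
        t0 = self.data["t_s"].min()
        t1 = self.data["t_s"].max()
        grid = np.arange(t0, t1 + 0.5 * every, every)
        out = {}
        for sid in self.vessels():
            sub = self.data[self.data["vessel_id"] == sid]
            t = sub["t_s"].to_numpy()
            out[sid] = {c: np.interp(grid, t, sub[c].to_numpy())
                        for c in columns}
        return grid, out
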