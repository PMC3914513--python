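"""Result writers: trace/report CSVs and VTK-style field snapshots.

All CSVs carry a header row with units embedded in the column names and
full floating-point precision, so re-running the same configuration
reproduces the files byte for byte.  Snapshots are legacy-ASCII VTK
rectilinear grids with cell data (T, V, Q, F), loadable by ParaView and
similar viewers; the third dimension is the (degenerate) azimuthal one.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .lethality import KineticsParams, log_reduction
from .mesh import AxisymMesh
from .scenarios import ScenarioResult, report_dataframe
from .simulate import SimulationTrace

TRACE_COLUMNS = (
    "time_s", "T_min_K", "T_max_K", "T_mean_K", "total_power_W",
    "voltage_V", "F_min_s", "log_reduction_min", "cold_cell_i", "cold_cell_j",
)


def trace_dataframe(trace: SimulationTrace) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time_s": trace.times,
            "T_min_K": trace.T_min,
            "T_max_K": trace.T_max,
            "T_mean_K": trace.T_mean,
            "total_power_W": trace.power,
            "voltage_V": trace.voltage,
            "F_min_s": trace.F_min,
            "log_reduction_min": trace.min_log_reduction,
            "cold_cell_i": trace.cold_cell[:, 0],
            "cold_cell_j": trace.cold_cell[:, 1],
        }
    )


def write_trace(trace: SimulationTrace, path: "str | Path") -> Path:
    """Write the per-step time series as CSV (one row per recorded time)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    trace_dataframe(trace).to_csv(path, index=False, float_format="%.17g")
    return path


def write_report(results: list[ScenarioResult], path: "str | Path") -> Path:
    """Write the scenario-suite report (one row per scenario) as CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    report_dataframe(results).to_csv(path, index=False, float_format="%.17g")
    return path


def write_snapshot(
    mesh: AxisymMesh,
    fields: dict[str, np.ndarray],
    path: "str | Path",
    title: str = "ohmicpast snapshot",
) -> Path:
    """Write cell fields on the (r, z) grid as a legacy-ASCII VTK file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    r_nodes, z_nodes = mesh.node_coordinates()
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET RECTILINEAR_GRID",
        f"DIMENSIONS {mesh.nr + 1} {mesh.nz + 1} 1",
        f"X_COORDINATES {mesh.nr + 1} double",
        " ".join(f"{v:.17g}" for v in r_nodes),
        f"Y_COORDINATES {mesh.nz + 1} double",
        " ".join(f"{v:.17g}" for v in z_nodes),
        "Z_COORDINATES 1 double",
        "0",
        f"CELL_DATA {mesh.n_cells}",
    ]
    for name, values in fields.items():
        values = np.asarray(values, dtype=float)
        if values.shape != (mesh.nr, mesh.nz):
            raise ValueError(f"field {name!r} does not match mesh")
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        # VTK cell ordering: x (radial index) fastest, then y (axial)
        for j in range(mesh.nz):
            lines.append(" ".join(f"{values[i, j]:.17g}" for i in range(mesh.nr)))
    path.write_text("\n".join(lines) + "\n")
    return path


def write_run_outputs(
    trace: SimulationTrace,
    kinetics: KineticsParams,
    out_dir: "str | Path",
    prefix: str = "",
) -> dict[str, Path]:
    """Write trace.csv plus every recorded snapshot and the final state."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {"trace": write_trace(trace, out / f"{prefix}trace.csv")}
    for t, fields in trace.snapshots.items():
        fields = dict(fields)
        fields["log_reduction"] = np.asarray(log_reduction(fields["F"], kinetics))
        written[f"snapshot_{t:010.3f}"] = write_snapshot(
            trace.mesh, fields, out / f"{prefix}snapshot_t{t:010.3f}s.vtk",
            title=f"t = {t:.3f} s",
        )
    final = {
        "T": trace.T_final,
        "V": trace.V_final,
        "Q": trace.Q_final,
        "F": trace.F_final,
        "log_reduction": np.asarray(log_reduction(trace.F_final, kinetics)),
    }
    written["final"] = write_snapshot(
        trace.mesh, final, out / f"{prefix}final.vtk",
        title=f"t = {trace.times[-1]:.3f} s (final)",
    )
    return written
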