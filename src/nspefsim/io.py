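"""Run outputs: legacy-ASCII VTK mesh/field export, CSV time series, and the
reproducibility manifest (config snapshot, seed, mesh statistics, output
checksums)."""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .meshing import SimMesh
from .solver import SimResult, SolverContext, field_magnitude


def write_vtk(path, mesh: SimMesh, cell_data: dict[str, np.ndarray] | None = None,
              point_data: dict[str, np.ndarray] | None = None) -> None:
    """Write the triangulation as legacy ASCII VTK (readable by ParaView)."""
    lines = ["# vtk DataFile Version 3.0", "nspefsim mesh", "ASCII",
             "DATASET UNSTRUCTURED_GRID",
             f"POINTS {mesh.n_nodes} double"]
    for x, y in mesh.nodes:
        lines.append(f"{x:.9e} {y:.9e} 0.0")
    m = mesh.n_triangles
    lines.append(f"CELLS {m} {4 * m}")
    for a, b, c in mesh.triangles:
        lines.append(f"3 {a} {b} {c}")
    lines.append(f"CELL_TYPES {m}")
    lines.extend(["5"] * m)  # VTK_TRIANGLE
    cell_data = {"region": mesh.region, **(cell_data or {})}
    lines.append(f"CELL_DATA {m}")
    for name, arr in cell_data.items():
        dtype = "int" if np.issubdtype(np.asarray(arr).dtype, np.integer) else "double"
        lines.append(f"SCALARS {name} {dtype} 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(f"{v}" for v in np.asarray(arr))
    if point_data:
        lines.append(f"POINT_DATA {mesh.n_nodes}")
        for name, arr in point_data.items():
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(f"{v:.9e}" for v in np.asarray(arr))
    Path(path).write_text("\n".join(lines) + "\n")


def membrane_csv(path, result: SimResult, which: str) -> None:
    """Long-format membrane time series: t, theta, V_m, N, r_pore, g_ep, A_frac."""
    mem = result.membranes[which]
    T, K = mem["V_m"].shape
    t = np.repeat(result.times, K)
    theta = np.tile(mem["theta"], T)
    df = pd.DataFrame({
        "t_s": t, "theta_rad": theta,
        "V_m_V": mem["V_m"].ravel(), "N_m2": mem["N"].ravel(),
        "r_pore_m": mem["r_pore"].ravel(), "g_ep_Sm2": mem["g_ep"].ravel(),
        "A_frac": mem["A_frac"].ravel(),
    })
    df.to_csv(path, index=False)


def poration_csv(path, result: SimResult, summaries: dict) -> None:
    cols = {"t_s": result.times}
    for name, summ in summaries.items():
        short = "outer" if name == "outer_membrane" else "inner"
        cols[f"S_{short}_m"] = summ.S
        cols[f"flux_{short}_ms"] = summ.flux
    pd.DataFrame(cols).to_csv(path, index=False)


def histogram_csv(path, hist) -> None:
    pd.DataFrame({"bin_lo_Vm": hist.bin_edges[:-1],
                  "bin_hi_Vm": hist.bin_edges[1:],
                  "area_fraction": hist.fraction}).to_csv(path, index=False)


def field_snapshot_vtk(path, ctx: SolverContext, psi: np.ndarray) -> None:
    E, _ = field_magnitude(ctx, psi)
    write_vtk(path, ctx.mesh, cell_data={"E_mag": E}, point_data={"psi": psi})


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(out_dir, config: dict, seed, mesh: SimMesh,
                   wall_time_s: float, extra: dict | None = None) -> Path:
    """Write manifest.json last, with checksums of every other output file."""
    out_dir = Path(out_dir)
    files = {p.name: _sha256(p) for p in sorted(out_dir.iterdir())
             if p.is_file() and p.name != "manifest.json"}
    doc = {
        "package": "nspefsim", "version": __version__,
        "seed": seed,
        "config": config,
        "mesh": {"n_nodes": mesh.n_nodes, "n_triangles": mesh.n_triangles,
                 "min_angle_deg": mesh.min_angle_deg,
                 "h_far": mesh.h_far, "h_membrane": mesh.h_membrane},
        "wall_time_s": wall_time_s,
        "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "files": files,
    }
    if extra:
        doc.update(extra)
    path = out_dir / "manifest.json"
    tmp = out_dir / "manifest.json.tmp"
    tmp.write_text(json.dumps(doc, indent=1))
    tmp.replace(path)
    return path
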