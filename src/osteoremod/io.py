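"""CSV, VTK and run-manifest output.

VTK files use the legacy ASCII unstructured-grid format (cell type 9,
quadrilateral), with the (r, z) plane written as (x, y, 0) coordinates.
CSV output is UTF-8 with a header row and '.' decimal separator, written
deterministically so re-running a configuration byte-reproduces it.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import Mesh


def write_vtk(path, mesh: Mesh, cell_data: dict | None = None,
              point_data: dict | None = None, title: str = "osteoremod field") -> None:
    """Write a legacy-ASCII VTK unstructured grid of the (r, z) section.

    ``cell_data`` maps names to per-element scalars (or (n, k) vectors);
    ``point_data`` likewise per node.
    """
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    for r, z in zip(mesh.node_r, mesh.node_z):
        lines.append(f"{r:.9g} {z:.9g} 0")
    lines.append(f"CELLS {mesh.n_elements} {5 * mesh.n_elements}")
    for cell in mesh.connectivity:
        lines.append("4 " + " ".join(str(int(i)) for i in cell))
    lines.append(f"CELL_TYPES {mesh.n_elements}")
    lines.extend(["9"] * mesh.n_elements)

    def _emit(block: dict, count: int, kind: str):
        lines.append(f"{kind} {count}")
        for name, values in block.items():
            arr = np.asarray(values, dtype=float)
            if arr.ndim == 1:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines.extend(f"{v:.9g}" for v in arr)
            else:
                lines.append(f"VECTORS {name} double")
                for row in arr:
                    x = row[0]
                    y = row[1] if arr.shape[1] > 1 else 0.0
                    z = row[2] if arr.shape[1] > 2 else 0.0
                    lines.append(f"{x:.9g} {y:.9g} {z:.9g}")

    if cell_data:
        _emit(cell_data, mesh.n_elements, "CELL_DATA")
    if point_data:
        _emit(point_data, mesh.n_nodes, "POINT_DATA")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def timeseries_frame(result) -> pd.DataFrame:
    """Per-snapshot summary of a run as a DataFrame."""
    return pd.DataFrame(
        {
            "time_days": result.times,
            "mean_density": result.mean_density,
            "front_radius_mm": result.front_radius,
            "global_ob_activity": result.global_activity_ob,
            "global_oc_activity": result.global_activity_oc,
        }
    )


def write_run_outputs(result, out_dir) -> dict:
    """Write the time-series CSV, field VTKs and the JSON run manifest.

    Returns a manifest dict (also saved as ``manifest.json``) echoing every
    resolved parameter value of the run.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ts = timeseries_frame(result)
    ts.to_csv(out / "timeseries.csv", index=False, float_format="%.10g")

    mesh = result.mesh
    write_vtk(
        out / "final_state.vtk",
        mesh,
        cell_data={
            "density": result.final_state.density,
            "density_initial": result.initial_density,
            "sed_mJ_mm3": result.final_state.energy.sed,
            "activity_ob": result.final_state.activity_ob,
            "activity_oc": result.final_state.activity_oc,
        },
    )

    from .metrics import front_report, radial_average_profile

    radii, prof = radial_average_profile(result.final_state.density, mesh)
    pd.DataFrame({"radius_mm": radii, "density": prof}).to_csv(
        out / "final_profile.csv", index=False, float_format="%.10g"
    )

    manifest = {
        "config": _as_jsonable(result.config),
        "load_scale": result.load_scale,
        "homeostatic_energy_mJ": result.homeostatic_energy,
        "mean_density_change_pct": result.mean_density_change_pct,
        "mass_formed_mg": result.mass_ledger.formed,
        "mass_resorbed_mg": result.mass_ledger.resorbed,
        "mass_net_mg": result.mass_ledger.net,
        "final_front_radius_mm": result.front_radius[-1]
        if np.isfinite(result.front_radius[-1]) else None,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest


def _as_jsonable(obj):
    if obj is None:
        return None
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: _as_jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)
        }
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _as_jsonable(v) for k, v in obj.items()}
    return obj
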