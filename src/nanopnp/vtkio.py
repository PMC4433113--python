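"""Minimal legacy-VTK (ASCII) writer for mesh and field inspection.

Writes the axisymmetric (r, z) triangulation as an unstructured grid with
optional point data (e.g. voltage) and cell data (region labels,
concentrations).  The files open in ParaView/VisIt; z is mapped to the VTK
y axis and r to x.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .mesh import Mesh


def write_vtk(
    mesh: Mesh,
    path: str | Path,
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
) -> None:
    """Write the mesh (and any nodal/cell fields) as a legacy VTK file."""
    path = Path(path)
    lines = [
        "# vtk DataFile Version 3.0",
        "nanopnp axisymmetric mesh (x=r, y=z)",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    for r, z in mesh.nodes:
        lines.append(f"{r:.9e} {z:.9e} 0.0")
    lines.append(f"CELLS {mesh.n_triangles} {4 * mesh.n_triangles}")
    for t in mesh.triangles:
        lines.append(f"3 {t[0]} {t[1]} {t[2]}")
    lines.append(f"CELL_TYPES {mesh.n_triangles}")
    lines.extend(["5"] * mesh.n_triangles)

    cell_data = dict(cell_data or {})
    cell_data.setdefault("region", mesh.region)
    lines.append(f"CELL_DATA {mesh.n_triangles}")
    for name, values in cell_data.items():
        values = np.asarray(values, dtype=float)
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(f"{v:.9e}" for v in values)

    if point_data:
        lines.append(f"POINT_DATA {mesh.n_nodes}")
        for name, values in point_data.items():
            values = np.asarray(values, dtype=float)
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(f"{v:.9e}" for v in values)

    path.write_text("\n".join(lines) + "\n")


def cell_field_on_mesh(
    mesh: Mesh, cell_quads: np.ndarray, values: np.ndarray, fill: float = np.nan
) -> np.ndarray:
    """Expand a per-liquid-cell (quad) field to all triangles for export."""
    out = np.full(mesh.n_triangles, fill)
    out[2 * np.asarray(cell_quads)] = values
    out[2 * np.asarray(cell_quads) + 1] = values
    return out
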