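"""Plain-text output: legacy-ASCII VTK unstructured grids and per-element
CSV tables.

The CSV element table is the exchange schema shared by the solver and the
synthetic field generator, so the exposure pipeline cannot distinguish
solved from synthetic fields.  Columns (units in the header):

    element_id, layer, r_mm, z_mm, volume_mm3, roi, sigma_vm_kPa, eps_eff
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .meshing import Mesh

__all__ = ["element_table", "write_element_table", "read_element_table", "write_vtk"]

ELEMENT_COLUMNS = ["element_id", "layer", "r_mm", "z_mm", "volume_mm3", "roi", "sigma_vm_kPa", "eps_eff"]


def element_table(mesh: Mesh, sigma_vm: np.ndarray, eps_eff: np.ndarray) -> pd.DataFrame:
    """Tidy per-element results table for a mesh and scalar field pair."""
    cen = mesh.centroids()
    return pd.DataFrame(
        {
            "element_id": np.arange(mesh.n_elements),
            "layer": mesh.layer_tag.astype(str),
            "r_mm": cen[:, 0],
            "z_mm": cen[:, 1],
            "volume_mm3": mesh.element_volume,
            "roi": mesh.roi_mask.astype(int),
            "sigma_vm_kPa": np.asarray(sigma_vm, dtype=float),
            "eps_eff": np.asarray(eps_eff, dtype=float),
        }
    )


def write_element_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, columns=ELEMENT_COLUMNS, float_format="%.10g")


def read_element_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(ELEMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"element table {path}: missing column(s) {sorted(missing)}")
    return df


def write_vtk(
    mesh: Mesh,
    path: str | Path,
    point_data: Mapping[str, np.ndarray] | None = None,
    cell_data: Mapping[str, np.ndarray] | None = None,
) -> None:
    """Write the mesh and fields as a legacy-ASCII VTK unstructured grid.

    Quadratic triangles are emitted as VTK cell type 22; axisymmetric (r, z)
    coordinates are written as (x, y, 0).  Vector point data must have shape
    (n_nodes, 2) (padded with a zero third component), scalars (n,).
    """
    lines = [
        "# vtk DataFile Version 3.0",
        "tissuemech axisymmetric solution",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    for r, z in mesh.nodes:
        lines.append(f"{r:.10g} {z:.10g} 0")
    ne = mesh.n_elements
    lines.append(f"CELLS {ne} {7 * ne}")
    for conn in mesh.elements:
        lines.append("6 " + " ".join(str(int(c)) for c in conn))
    lines.append(f"CELL_TYPES {ne}")
    lines.extend(["22"] * ne)

    if point_data:
        lines.append(f"POINT_DATA {mesh.n_nodes}")
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            if arr.ndim == 2:
                lines.append(f"VECTORS {name} double")
                for row in arr:
                    lines.append(f"{row[0]:.10g} {row[1]:.10g} 0")
            else:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines.extend(f"{v:.10g}" for v in arr)
    if cell_data:
        lines.append(f"CELL_DATA {ne}")
        for name, arr in cell_data.items():
            arr = np.asarray(arr)
            if arr.dtype.kind in "OU":
                codes, uniq = pd.factorize(arr)
                lines.append(f"SCALARS {name} int 1")
                lines.append("LOOKUP_TABLE default")
                lines.extend(str(int(c)) for c in codes)
            else:
                kind = "int" if arr.dtype.kind in "bi" else "double"
                lines.append(f"SCALARS {name} {kind} 1")
                lines.append("LOOKUP_TABLE default")
                lines.extend(f"{v:.10g}" if kind == "double" else str(int(v)) for v in arr)
    Path(path).write_text("\n".join(lines) + "\n")
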