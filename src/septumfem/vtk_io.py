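"""Minimal legacy-ASCII VTK unstructured-grid writer for meshes and fields."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .geometry import LabeledMesh


def write_vtk(path: str | Path, mesh: LabeledMesh,
              point_data: dict[str, np.ndarray] | None = None,
              cell_data: dict[str, np.ndarray] | None = None) -> None:
    """Write the midplane mesh (z = 0) with optional scalar fields."""
    nodes = mesh.nodes
    tris = mesh.triangles
    lines = ["# vtk DataFile Version 3.0", "septumfem unstructured grid", "ASCII",
             "DATASET UNSTRUCTURED_GRID", f"POINTS {len(nodes)} double"]
    for x, y in nodes:
        lines.append(f"{x:.9g} {y:.9g} 0")
    lines.append(f"CELLS {len(tris)} {4 * len(tris)}")
    for a, b, c in tris:
        lines.append(f"3 {a} {b} {c}")
    lines.append(f"CELL_TYPES {len(tris)}")
    lines.extend(["5"] * len(tris))

    def scalar_block(name: str, arr: np.ndarray) -> list[str]:
        out = [f"SCALARS {name} double 1", "LOOKUP_TABLE default"]
        out.extend(f"{v:.9g}" for v in np.asarray(arr, float))
        return out

    if point_data:
        lines.append(f"POINT_DATA {len(nodes)}")
        for name, arr in point_data.items():
            lines.extend(scalar_block(name, arr))
    if cell_data:
        lines.append(f"CELL_DATA {len(tris)}")
        for name, arr in cell_data.items():
            lines.extend(scalar_block(name, arr))
    Path(path).write_text("\n".join(lines) + "\n")
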