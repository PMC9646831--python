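"""Minimal legacy-ASCII VTK unstructured-grid writer (no external deps)."""

from __future__ import annotations

import numpy as np

_VTK_TRIANGLE = 5
_VTK_QUAD = 9


def write_vtk(
    path,
    mesh,
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
    title: str = "sacflow output",
) -> None:
    """Write a mesh plus nodal/cell fields as a legacy ASCII .vtk file.

    Vector fields are passed as (n, 2) arrays and padded to 3-D; scalar
    fields as flat arrays.
    """
    pts = np.asarray(mesh.points, dtype=float)
    cells = np.asarray(mesh.cells, dtype=int)
    npts, ncells = len(pts), len(cells)
    ctype = _VTK_QUAD if cells.shape[1] == 4 else _VTK_TRIANGLE
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write(f"{title}\nASCII\nDATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {npts} double\n")
        for x, y in pts:
            f.write(f"{x:.10e} {y:.10e} 0.0\n")
        k = cells.shape[1]
        f.write(f"CELLS {ncells} {ncells * (k + 1)}\n")
        for row in cells:
            f.write(f"{k} " + " ".join(map(str, row)) + "\n")
        f.write(f"CELL_TYPES {ncells}\n")
        f.write("\n".join([str(ctype)] * ncells) + "\n")

        def emit(block: dict[str, np.ndarray], n: int, kind: str) -> None:
            f.write(f"{kind} {n}\n")
            for name, arr in block.items():
                arr = np.asarray(arr)
                if arr.ndim == 2 and arr.shape[1] == 2:
                    f.write(f"VECTORS {name} double\n")
                    for vx, vy in arr:
                        f.write(f"{vx:.10e} {vy:.10e} 0.0\n")
                else:
                    f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    for v in np.asarray(arr, dtype=float).ravel():
                        f.write(f"{v:.10e}\n")

        if point_data:
            emit(point_data, npts, "POINT_DATA")
        if cell_data:
            emit(cell_data, ncells, "CELL_DATA")
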