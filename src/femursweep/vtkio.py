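"""Minimal legacy-VTK (ASCII) unstructured-grid I/O for tetrahedral meshes.

Only what this package needs: POINTS, CELLS of type 10 (linear tetrahedra),
and scalar CELL_DATA / POINT_DATA arrays. Files written here open in
ParaView and read back losslessly (to float64 text precision).
"""

from __future__ import annotations

import numpy as np

from .mesh import TetMesh

__all__ = ["write_vtk", "read_vtk"]

_VTK_TET = 10


def write_vtk(path, mesh: TetMesh, cell_data: dict | None = None,
              point_data: dict | None = None) -> None:
    """Write a tet mesh with optional per-element / per-node scalar arrays."""
    cell_data = dict(cell_data or {})
    if mesh.region_label is not None and "region_label" not in cell_data:
        cell_data["region_label"] = mesh.region_label
    n, m = mesh.n_nodes, mesh.n_elements
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nfemursweep tetrahedral mesh\n")
        fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {n} double\n")
        np.savetxt(fh, mesh.nodes, fmt="%.17g")
        fh.write(f"CELLS {m} {5 * m}\n")
        cells = np.column_stack([np.full(m, 4, dtype=np.int64), mesh.tets])
        np.savetxt(fh, cells, fmt="%d")
        fh.write(f"CELL_TYPES {m}\n")
        np.savetxt(fh, np.full(m, _VTK_TET, dtype=np.int64), fmt="%d")
        if cell_data:
            fh.write(f"CELL_DATA {m}\n")
            _write_arrays(fh, cell_data, m)
        if point_data:
            fh.write(f"POINT_DATA {n}\n")
            _write_arrays(fh, point_data, n)


def _write_arrays(fh, arrays: dict, expected: int) -> None:
    for name, arr in arrays.items():
        arr = np.asarray(arr)
        if arr.shape[0] != expected:
            raise ValueError(f"array {name!r} has wrong length")
        if np.issubdtype(arr.dtype, np.integer):
            fh.write(f"SCALARS {name} int 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, arr.astype(np.int64), fmt="%d")
        else:
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, arr.astype(float), fmt="%.17g")


def read_vtk(path):
    """Read a legacy ASCII unstructured grid of tetrahedra.

    Returns ``(mesh, cell_data, point_data)``. A ``region_label`` cell array,
    if present, is attached to the mesh.
    """
    with open(path) as fh:
        tokens = fh.read().split()
    i = 0

    def expect(word):
        nonlocal i
        while tokens[i].upper() != word:
            i += 1
        i += 1

    expect("POINTS")
    n = int(tokens[i]); i += 2  # skip dtype
    nodes = np.array(tokens[i:i + 3 * n], dtype=float).reshape(n, 3)
    i += 3 * n
    expect("CELLS")
    m = int(tokens[i]); total = int(tokens[i + 1]); i += 2
    # `total` counts every integer in the cell list, including the leading
    # node count of each cell (5 per tetrahedron)
    raw = np.array(tokens[i:i + total], dtype=np.int64)
    i += total
    cells = raw.reshape(m, 5)
    if not np.all(cells[:, 0] == 4):
        raise ValueError("only linear tetrahedra (4-node cells) are supported")
    expect("CELL_TYPES")
    i += 1 + m  # count + values
    cell_data: dict = {}
    point_data: dict = {}
    current = None
    while i < len(tokens):
        word = tokens[i].upper()
        if word == "CELL_DATA":
            current, size = cell_data, m
            i += 2
        elif word == "POINT_DATA":
            current, size = point_data, n
            i += 2
        elif word == "SCALARS" and current is not None:
            name, dtype = tokens[i + 1], tokens[i + 2]
            i += 3
            if tokens[i].isdigit():  # optional component count
                i += 1
            if tokens[i].upper() == "LOOKUP_TABLE":
                i += 2
            vals = np.array(tokens[i:i + size],
                            dtype=np.int64 if dtype in ("int", "long") else float)
            current[name] = vals
            i += size
        else:
            i += 1
    mesh = TetMesh(nodes=nodes, tets=cells[:, 1:])
    if "region_label" in cell_data:
        mesh.region_label = cell_data["region_label"].astype(int)
    return mesh, cell_data, point_data
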