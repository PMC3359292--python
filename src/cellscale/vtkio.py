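"""Minimal legacy-VTK (ASCII) unstructured-grid reader and writer.

Supports exactly the subset the pipeline exchanges: hexahedral cells
(``VTK_HEXAHEDRON``, type 12), point-data vectors/scalars (e.g. a
``displacement`` field) and cell-data scalars (region labels, fringe
metrics).  Both the classic ``CELLS n size`` layout and the VTK>=9
``OFFSETS/CONNECTIVITY`` layout are read.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .mesh import HexMesh

__all__ = ["UnsupportedCellTypeError", "read_vtk", "write_vtk"]

VTK_HEXAHEDRON = 12


class UnsupportedCellTypeError(ValueError):
    """Raised when a VTK file contains non-hexahedral cells."""


def _tokens(path):
    with open(path) as fh:
        for line in fh:
            yield from line.split()


def read_vtk(path) -> tuple[HexMesh, dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Read a legacy ASCII unstructured grid.

    Returns ``(mesh, point_data, cell_data)``.  Raises
    :class:`UnsupportedCellTypeError` if any cell is not a linear hexahedron.
    """
    toks = _tokens(path)
    points = None
    connectivity = None
    cell_types = None
    point_data: dict[str, np.ndarray] = {}
    cell_data: dict[str, np.ndarray] = {}
    section = None  # which data block attributes attach to
    n_points = n_cells = 0

    def take(n):
        return np.array([float(next(toks)) for _ in range(n)])

    while True:
        try:
            tok = next(toks)
        except StopIteration:
            break
        key = tok.upper()
        if key == "DATASET":
            kind = next(toks).upper()
            if kind != "UNSTRUCTURED_GRID":
                raise ValueError(f"unsupported VTK dataset {kind!r}")
        elif key == "POINTS":
            n_points = int(next(toks))
            next(toks)  # dtype
            points = take(3 * n_points).reshape(n_points, 3)
        elif key == "CELLS":
            n_cells = int(next(toks))
            size = int(next(toks))
            raw = take(size).astype(np.int64)
            if n_cells and raw[0] == 0 and size == n_cells:
                # VTK >= 9 writes CELLS n_offsets n_offsets / OFFSETS ... CONNECTIVITY ...
                raise ValueError("OFFSETS/CONNECTIVITY layout with split arrays not supported")
            connectivity = raw
        elif key == "OFFSETS":
            next(toks)  # dtype
            offsets = take(n_cells).astype(np.int64)
            connectivity = ("offsets", offsets)
        elif key == "CONNECTIVITY":
            next(toks)  # dtype
            offsets = connectivity[1]
            conn = take(int(offsets[-1])).astype(np.int64)
            connectivity = ("split", offsets, conn)
        elif key == "CELL_TYPES":
            n = int(next(toks))
            cell_types = take(n).astype(np.int64)
        elif key == "POINT_DATA":
            n = int(next(toks))
            section = ("point", n)
        elif key == "CELL_DATA":
            n = int(next(toks))
            section = ("cell", n)
        elif key in ("SCALARS", "VECTORS"):
            name = next(toks)
            next(toks)  # dtype
            where, n = section
            if key == "SCALARS":
                # optional numComp then LOOKUP_TABLE <name>
                peek = next(toks)
                ncomp = 1
                if peek.upper() != "LOOKUP_TABLE":
                    ncomp = int(peek)
                    next(toks)  # LOOKUP_TABLE
                next(toks)  # table name
                data = take(n * ncomp)
                data = data if ncomp == 1 else data.reshape(n, ncomp)
            else:
                data = take(3 * n).reshape(n, 3)
            (point_data if where == "point" else cell_data)[name] = data
        elif key == "FIELD":
            next(toks)  # field name
            n_arrays = int(next(toks))
            where, n = section if section else ("point", n_points)
            for _ in range(n_arrays):
                name = next(toks)
                ncomp = int(next(toks))
                ntup = int(next(toks))
                next(toks)  # dtype
                data = take(ncomp * ntup)
                data = data if ncomp == 1 else data.reshape(ntup, ncomp)
                (point_data if where == "point" else cell_data)[name] = data
        # silently skip header comment tokens / ASCII keyword
    if points is None or connectivity is None or cell_types is None:
        raise ValueError(f"{path}: incomplete unstructured grid")
    if np.any(cell_types != VTK_HEXAHEDRON):
        bad = sorted(set(int(t) for t in cell_types if t != VTK_HEXAHEDRON))
        raise UnsupportedCellTypeError(
            f"{path}: only VTK_HEXAHEDRON (12) cells supported, found types {bad}"
        )
    if isinstance(connectivity, tuple):
        offsets = connectivity[1]
        conn = connectivity[2]
        counts = np.diff(np.concatenate([[0], offsets]))
        if np.any(counts != 8):
            raise UnsupportedCellTypeError("cells with node count != 8")
        elements = conn.reshape(-1, 8)
    else:
        raw = connectivity.reshape(len(cell_types), 9)
        if np.any(raw[:, 0] != 8):
            raise UnsupportedCellTypeError("cells with node count != 8")
        elements = raw[:, 1:]
    mesh = HexMesh(nodes=points, elements=elements)
    return mesh, point_data, cell_data


def write_vtk(
    path,
    mesh: HexMesh,
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
    title: str = "cellscale output",
) -> None:
    """Write a legacy ASCII unstructured grid with optional attached data."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(title[:255] + "\n")
        fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        np.savetxt(fh, mesh.nodes, fmt="%.17g")
        fh.write(f"CELLS {mesh.n_elements} {9 * mesh.n_elements}\n")
        cells = np.column_stack(
            [np.full(mesh.n_elements, 8, dtype=np.int64), mesh.elements]
        )
        np.savetxt(fh, cells, fmt="%d")
        fh.write(f"CELL_TYPES {mesh.n_elements}\n")
        np.savetxt(fh, np.full(mesh.n_elements, VTK_HEXAHEDRON), fmt="%d")
        for where, data in (("POINT_DATA", point_data), ("CELL_DATA", cell_data)):
            if not data:
                continue
            n = mesh.n_nodes if where == "POINT_DATA" else mesh.n_elements
            fh.write(f"{where} {n}\n")
            for name, arr in data.items():
                arr = np.asarray(arr)
                if arr.ndim == 2 and arr.shape == (n, 3):
                    fh.write(f"VECTORS {name} double\n")
                    np.savetxt(fh, arr, fmt="%.17g")
                elif arr.ndim == 1 and arr.shape == (n,):
                    fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    np.savetxt(fh, arr, fmt="%.17g")
                elif arr.ndim == 3 and arr.shape == (n, 3, 3):
                    fh.write(f"FIELD tensors_{name} 1\n{name} 9 {n} double\n")
                    np.savetxt(fh, arr.reshape(n, 9), fmt="%.17g")
                else:
                    raise ValueError(
                        f"cannot write array {name!r} with shape {arr.shape} as {where}"
                    )
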