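"""Hexahedral mesh container shared by the macro and micro scales."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hexkernel import batch_volumes

__all__ = ["HexMesh", "structured_hex_grid"]


@dataclass
class HexMesh:
    """Nodes, hex connectivity and named element sets.

    Attributes
    ----------
    nodes : (n, 3) float array of nodal positions.
    elements : (ne, 8) int array, VTK hexahedron node ordering.
    element_sets : mapping of set name to int array of element indices.
    """

    nodes: np.ndarray
    elements: np.ndarray
    element_sets: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=np.int64)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise ValueError(f"nodes must be (n, 3), got {self.nodes.shape}")
        if self.elements.ndim != 2 or self.elements.shape[1] != 8:
            raise ValueError(f"elements must be (ne, 8), got {self.elements.shape}")
        if self.elements.size and (
            self.elements.min() < 0 or self.elements.max() >= len(self.nodes)
        ):
            raise ValueError("element connectivity references missing nodes")
        for name, ids in self.element_sets.items():
            ids = np.asarray(ids, dtype=np.int64)
            if ids.size and (ids.min() < 0 or ids.max() >= len(self.elements)):
                raise ValueError(f"element set {name!r} references missing elements")
            self.element_sets[name] = ids

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def element_coords(self, positions: np.ndarray | None = None) -> np.ndarray:
        """Per-element ``(ne, 8, 3)`` nodal coordinates.

        ``positions`` defaults to the mesh's own nodes; pass deformed nodal
        positions to gather the deformed configuration instead.
        """
        pos = self.nodes if positions is None else np.asarray(positions, dtype=float)
        return pos[self.elements]

    def element_centroids(self, positions: np.ndarray | None = None) -> np.ndarray:
        return self.element_coords(positions).mean(axis=1)

    def element_volumes(
        self, positions: np.ndarray | None = None, rule: str = "centroid"
    ) -> np.ndarray:
        return batch_volumes(self.element_coords(positions), rule=rule)

    def set_ids(self, name: str) -> np.ndarray:
        try:
            return self.element_sets[name]
        except KeyError:
            raise KeyError(
                f"element set {name!r} not found; available: {sorted(self.element_sets)}"
            ) from None


def structured_hex_grid(
    shape: tuple[int, int, int],
    lengths: tuple[float, float, float],
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> HexMesh:
    """Regular grid of ``nx x ny x nz`` hex elements on a box.

    Node numbering is x-fastest; elements follow the VTK hexahedron ordering.
    """
    nx, ny, nz = shape
    if min(nx, ny, nz) < 1:
        raise ValueError("grid must have at least one element per direction")
    lx, ly, lz = lengths
    xs = np.linspace(origin[0], origin[0] + lx, nx + 1)
    ys = np.linspace(origin[1], origin[1] + ly, ny + 1)
    zs = np.linspace(origin[2], origin[2] + lz, nz + 1)
    Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return i + (nx + 1) * (j + (ny + 1) * k)

    i, j, k = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    i, j, k = (a.transpose(2, 1, 0).ravel() for a in (i, j, k))  # z-major order
    elements = np.column_stack(
        [
            nid(i, j, k),
            nid(i + 1, j, k),
            nid(i + 1, j + 1, k),
            nid(i, j + 1, k),
            nid(i, j, k + 1),
            nid(i + 1, j, k + 1),
            nid(i + 1, j + 1, k + 1),
            nid(i, j + 1, k + 1),
        ]
    )
    return HexMesh(nodes=nodes, elements=elements)
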