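"""Macro-scale solution input and deformation-gradient extraction.

A converged macro FE state is a hex mesh plus undeformed and deformed nodal
positions.  From it, per-element deformation gradients are sampled either at
the element centroid or at the eight Gauss points; elements whose gradient
departs from identity by more than a threshold in any component are the ones
that warrant a micro-scale model.  The within-element variation of the eight
Gauss-point tensors quantifies the aliasing incurred by centroid-only
sampling.

File formats: legacy ASCII VTK unstructured grids (optionally carrying a
``displacement`` point-data vector) or CSV node/element tables
(``nodes.csv``: id,x,y,z; ``elements.csv``: id,n0..n7[,set]; comma-separated,
header row, 0-based node indices).  Macro coordinates are in mm; the
deformation gradient is dimensionless.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import hexkernel
from .mesh import HexMesh
from .vtkio import UnsupportedCellTypeError, read_vtk

__all__ = [
    "MacroState",
    "DeformationGradientRecord",
    "read_macro_state",
    "element_deformation_gradients",
    "filter_deforming_elements",
    "variation_residual",
    "records_to_dataframe",
    "write_records_csv",
]

logger = logging.getLogger(__name__)

_GAUSS = hexkernel.GAUSS8_POINTS
_CENTROID = np.zeros((1, 3))


@dataclass
class MacroState:
    """One macro mesh with its undeformed and deformed nodal positions."""

    mesh: HexMesh
    undeformed: np.ndarray
    deformed: np.ndarray

    def __post_init__(self) -> None:
        self.undeformed = np.asarray(self.undeformed, dtype=float)
        self.deformed = np.asarray(self.deformed, dtype=float)
        n = self.mesh.n_nodes
        for name, arr in (("undeformed", self.undeformed), ("deformed", self.deformed)):
            if arr.shape != (n, 3):
                raise ValueError(
                    f"{name} positions shape {arr.shape} does not match mesh ({n} nodes)"
                )

    @property
    def displacement(self) -> np.ndarray:
        return self.deformed - self.undeformed


@dataclass
class DeformationGradientRecord:
    """Deformation gradient(s) sampled on one element.

    ``tensors`` has shape ``(1, 3, 3)`` for the ``centroid`` scheme or
    ``(8, 3, 3)`` for ``gauss8``.  ``deviation`` is the maximum absolute
    componentwise departure from the identity over all sampled tensors.
    """

    element_id: int
    scheme: str
    tensors: np.ndarray
    deviation: float = field(init=False)

    def __post_init__(self) -> None:
        self.tensors = np.asarray(self.tensors, dtype=float)
        expected = {"centroid": 1, "gauss8": 8}[self.scheme]
        if self.tensors.shape != (expected, 3, 3):
            raise ValueError(
                f"scheme {self.scheme!r} expects {expected} tensors, "
                f"got shape {self.tensors.shape}"
            )
        self.deviation = float(np.abs(self.tensors - np.eye(3)).max())

    @property
    def F(self) -> np.ndarray:
        """Centroid tensor (or the mean of the Gauss tensors for gauss8)."""
        return self.tensors[0] if self.scheme == "centroid" else self.tensors.mean(axis=0)


def _read_csv_mesh(mesh_source) -> tuple[HexMesh, np.ndarray]:
    src = Path(mesh_source)
    if src.is_dir():
        nodes_path, elems_path = src / "nodes.csv", src / "elements.csv"
    else:  # a nodes.csv path; elements.csv expected alongside
        nodes_path, elems_path = src, src.parent / "elements.csv"
    nodes_df = pd.read_csv(nodes_path)
    elems_df = pd.read_csv(elems_path)
    nodes_df = nodes_df.sort_values("id")
    if not np.array_equal(nodes_df["id"].to_numpy(), np.arange(len(nodes_df))):
        raise ValueError(f"{nodes_path}: node ids must be contiguous from 0")
    nodes = nodes_df[["x", "y", "z"]].to_numpy(dtype=float)
    conn_cols = [f"n{i}" for i in range(8)]
    missing = [c for c in conn_cols if c not in elems_df.columns]
    if missing:
        raise ValueError(f"{elems_path}: missing connectivity columns {missing}")
    elems_df = elems_df.sort_values("id")
    elements = elems_df[conn_cols].to_numpy(dtype=np.int64)
    sets: dict[str, np.ndarray] = {}
    if "set" in elems_df.columns:
        sets = {
            str(name): np.flatnonzero((elems_df["set"] == name).to_numpy())
            for name in elems_df["set"].unique()
        }
    mesh = HexMesh(nodes=nodes, elements=elements, element_sets=sets)
    return mesh, nodes


def _read_deformed_csv(path, undeformed: np.ndarray) -> np.ndarray:
    df = pd.read_csv(path).sort_values("id")
    if len(df) != len(undeformed):
        raise ValueError(
            f"{path}: {len(df)} rows but mesh has {len(undeformed)} nodes"
        )
    if {"ux", "uy", "uz"}.issubset(df.columns):
        return undeformed + df[["ux", "uy", "uz"]].to_numpy(dtype=float)
    if {"x", "y", "z"}.issubset(df.columns):
        return df[["x", "y", "z"]].to_numpy(dtype=float)
    raise ValueError(f"{path}: expected columns ux,uy,uz or x,y,z")


def read_macro_state(mesh_source, deformed_source=None) -> MacroState:
    """Load a macro state from VTK or CSV sources.

    ``mesh_source`` supplies the mesh and undeformed positions.  The deformed
    positions come from, in order of precedence: a ``displacement``
    point-data vector inside the VTK file, ``deformed_source`` (a CSV of
    positions/displacements or a second VTK whose points are the deformed
    positions), or — if neither is given — the undeformed positions
    (identity deformation).
    """
    mesh_source = Path(mesh_source)
    if mesh_source.suffix.lower() == ".vtk":
        mesh, point_data, _ = read_vtk(mesh_source)
        undeformed = mesh.nodes
        deformed = None
        if "displacement" in point_data:
            disp = np.asarray(point_data["displacement"], dtype=float)
            if disp.shape != undeformed.shape:
                raise ValueError(
                    f"{mesh_source}: displacement shape {disp.shape} mismatches mesh"
                )
            deformed = undeformed + disp
    else:
        mesh, undeformed = _read_csv_mesh(mesh_source)
        deformed = None

    if deformed_source is not None:
        deformed_source = Path(deformed_source)
        if deformed_source.suffix.lower() == ".vtk":
            dmesh, _, _ = read_vtk(deformed_source)
            if dmesh.n_nodes != mesh.n_nodes:
                raise ValueError("deformed VTK node count mismatches mesh")
            deformed = dmesh.nodes
        else:
            deformed = _read_deformed_csv(deformed_source, undeformed)
    if deformed is None:
        deformed = undeformed.copy()
    state = MacroState(mesh=mesh, undeformed=undeformed, deformed=deformed)
    logger.info(
        "read macro state: %d nodes, %d hex elements, sets=%s",
        mesh.n_nodes,
        mesh.n_elements,
        sorted(mesh.element_sets) or "none",
    )
    return state


def element_deformation_gradients(
    state: MacroState, set_name: str | None = None, scheme: str = "centroid"
) -> list[DeformationGradientRecord]:
    """Per-element deformation gradients for an element set.

    ``scheme='centroid'`` samples at the element centroid; ``'gauss8'`` at the
    eight 2x2x2 Gauss points (natural coordinates ±1/sqrt(3)).  Inverted
    elements raise rather than being silently skipped.
    """
    if scheme not in ("centroid", "gauss8"):
        raise ValueError(f"unknown sampling scheme {scheme!r}")
    ids = (
        np.arange(state.mesh.n_elements)
        if set_name is None
        else state.mesh.set_ids(set_name)
    )
    if ids.size == 0:
        return []
    points = _CENTROID if scheme == "centroid" else _GAUSS
    X = state.mesh.element_coords(state.undeformed)[ids]
    x = state.mesh.element_coords(state.deformed)[ids]
    F = hexkernel.batch_deformation_gradients(X, x, points)  # (n, npts, 3, 3)
    return [
        DeformationGradientRecord(element_id=int(eid), scheme=scheme, tensors=F[i])
        for i, eid in enumerate(ids)
    ]


def filter_deforming_elements(
    records: list[DeformationGradientRecord], tol: float = 1e-3
) -> list[DeformationGradientRecord]:
    """Keep elements whose F departs from identity by more than ``tol``.

    The criterion is componentwise: ``max_ij |F_ij - delta_ij| > tol`` over
    every sampled tensor.  Elements below the threshold are mechanically
    quiescent and do not warrant a micro-scale model.
    """
    if tol <= 0:
        raise ValueError("deformation threshold must be positive")
    return [r for r in records if r.deviation > tol]


def variation_residual(record: DeformationGradientRecord) -> float:
    """Within-element variation of the eight Gauss-point tensors.

    For every unique pair among the eight tensors, the componentwise absolute
    differences are summed into a scalar; the maximum over the 28 pairs is
    returned.  A large value flags an element whose centroid sample aliases
    the deformation actually spanning the element.
    """
    if record.scheme != "gauss8":
        raise ValueError("variation residual requires the gauss8 sampling scheme")
    T = record.tensors
    i, j = np.triu_indices(len(T), k=1)
    return float(np.abs(T[i] - T[j]).sum(axis=(1, 2)).max())


def records_to_dataframe(records: list[DeformationGradientRecord]) -> pd.DataFrame:
    """Tabulate records: element id, the 9 centroid/mean components, deviation."""
    rows = []
    for r in records:
        F = r.F
        row = {"element_id": r.element_id, "scheme": r.scheme}
        for a in range(3):
            for b in range(3):
                row[f"F{a + 1}{b + 1}"] = F[a, b]
        row["deviation"] = r.deviation
        rows.append(row)
    return pd.DataFrame(rows)


def write_records_csv(records, path) -> None:
    records_to_dataframe(records).to_csv(path, index=False)
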