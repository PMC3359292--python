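"""Cell and region deformation metrics from a micro-scale solution.

The metric set mirrors what is measurable on cells in experiments:

* volumetric strain of a cell, ``(V_def - V_und) / V_und`` summed over its
  elements;
* change in aspect ratio from the ellipsoid of best fit: the unit-density
  moment-of-inertia tensor is assembled from element centroids and volumes,
  its principal moments are inverted to solid-ellipsoid semi-axes
  ``a >= b >= c``, and the deformed minus undeformed axis ratios
  (major-minor, major-middle, middle-minor) are reported;
* effective (von Mises) scalars of the Cauchy stress and Green-Lagrange
  strain and the maximum shear strain, volume-averaged over an element set
  with deformed element volumes as weights.

Element volumes use the centroid Jacobian rule (``8 det J(0)``) in both
configurations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fe_solver import MicroSolution
from .hexkernel import batch_volumes

__all__ = [
    "MetricsRecord",
    "EllipsoidFitError",
    "volumetric_strain",
    "inertia_tensor",
    "ellipsoid_axes",
    "aspect_ratio_change",
    "effective_scalar",
    "max_shear",
    "volume_averaged_metric",
    "compute_metrics",
    "metrics_to_dataframe",
]


class EllipsoidFitError(ValueError):
    """Raised when principal moments admit no real solid-ellipsoid axes."""


def _set_coords(solution: MicroSolution, element_set, deformed: bool):
    mesh = solution.model.mesh
    ids = mesh.set_ids(element_set) if isinstance(element_set, str) else np.asarray(
        element_set, dtype=np.int64
    )
    if ids.size == 0:
        raise ValueError(f"element set {element_set!r} is empty")
    positions = solution.deformed_positions if deformed else mesh.nodes
    return ids, positions[mesh.elements[ids]]


def volumetric_strain(solution: MicroSolution, element_set) -> float:
    """``(sum V_def - sum V_und) / sum V_und`` over one element set."""
    _, X = _set_coords(solution, element_set, deformed=False)
    _, x = _set_coords(solution, element_set, deformed=True)
    v0 = batch_volumes(X).sum()
    v1 = batch_volumes(x).sum()
    return float((v1 - v0) / v0)


def inertia_tensor(coords: np.ndarray) -> tuple[np.ndarray, float]:
    """Unit-density moment-of-inertia tensor of a set of hex elements.

    Element volumes are lumped at element centroids; the tensor is taken
    about the set's volume centroid (hence invariant to translation).

    Parameters
    ----------
    coords : (ne, 8, 3) nodal coordinates of the set's elements in the
        configuration of interest.

    Returns
    -------
    (I, volume): the 3x3 symmetric tensor and the set volume (the "mass" at
    unit density).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.size == 0:
        raise ValueError("empty element set")
    vols = batch_volumes(coords)
    cents = coords.mean(axis=1)
    m = vols.sum()
    center = (vols[:, None] * cents).sum(axis=0) / m
    r = cents - center
    r2 = (r**2).sum(axis=1)
    I = np.einsum("e,ij->ij", vols * r2, np.eye(3)) - np.einsum(
        "e,ei,ej->ij", vols, r, r
    )
    return I, float(m)


def ellipsoid_axes(inertia: np.ndarray, volume: float) -> np.ndarray:
    """Semi-axes ``a >= b >= c`` of the solid ellipsoid matching an inertia tensor.

    For a solid ellipsoid of mass ``m`` the principal moment about the axis
    with semi-axis ``a`` is ``m (b^2 + c^2) / 5`` — the longest axis carries
    the smallest moment.  Inverting, with principal moments in descending
    order ``lam1 >= lam2 >= lam3``,

        a^2 = (5 / 2m) (lam1 + lam2 - lam3)
        b^2 = (5 / 2m) (lam1 + lam3 - lam2)
        c^2 = (5 / 2m) (lam2 + lam3 - lam1)

    Raises :class:`EllipsoidFitError` when a radicand is non-positive (no
    real ellipsoid fits the moments).
    """
    inertia = np.asarray(inertia, dtype=float)
    lam = np.linalg.eigvalsh(inertia)[::-1]  # descending
    if np.any(lam <= 0):
        raise EllipsoidFitError("principal moments must be positive")
    s = 2.5 / volume
    sq = np.array(
        [
            s * (lam[0] + lam[1] - lam[2]),
            s * (lam[0] + lam[2] - lam[1]),
            s * (lam[1] + lam[2] - lam[0]),
        ]
    )
    if np.any(sq <= 0):
        raise EllipsoidFitError(f"infeasible principal moments {lam}")
    return np.sqrt(sq)


def _aspect_ratios(coords: np.ndarray) -> np.ndarray:
    I, m = inertia_tensor(coords)
    a, b, c = ellipsoid_axes(I, m)
    return np.array([a / c, a / b, b / c])  # major-minor, major-middle, middle-minor


def aspect_ratio_change(solution: MicroSolution, element_set) -> np.ndarray:
    """Deformed minus undeformed aspect ratios ``(maj-min, maj-mid, mid-min)``."""
    _, X = _set_coords(solution, element_set, deformed=False)
    _, x = _set_coords(solution, element_set, deformed=True)
    return _aspect_ratios(x) - _aspect_ratios(X)


def effective_scalar(tensor: np.ndarray) -> float | np.ndarray:
    """Effective (von Mises) value of a symmetric stress or strain tensor.

    ``sqrt(((p1-p2)^2 + (p2-p3)^2 + (p1-p3)^2) / 2)`` over the principal
    values; non-negative, zero iff the tensor is hydrostatic.  Batched input
    ``(m, 3, 3)`` is supported.
    """
    t = np.asarray(tensor, dtype=float)
    single = t.ndim == 2
    p = np.linalg.eigvalsh(t.reshape(-1, 3, 3))
    out = np.sqrt(
        0.5
        * (
            (p[:, 0] - p[:, 1]) ** 2
            + (p[:, 1] - p[:, 2]) ** 2
            + (p[:, 0] - p[:, 2]) ** 2
        )
    )
    return float(out[0]) if single else out


def max_shear(tensor: np.ndarray) -> float | np.ndarray:
    """Maximum shear value ``(p1 - p3) / 2`` of a symmetric tensor (batched ok)."""
    t = np.asarray(tensor, dtype=float)
    single = t.ndim == 2
    p = np.linalg.eigvalsh(t.reshape(-1, 3, 3))
    out = 0.5 * (p[:, 2] - p[:, 0])
    return float(out[0]) if single else out


def volume_averaged_metric(
    solution: MicroSolution, element_set, values: np.ndarray
) -> float:
    """Average per-element ``values`` over a set, weighted by deformed volumes."""
    ids, x = _set_coords(solution, element_set, deformed=True)
    v = batch_volumes(x)
    values = np.asarray(values, dtype=float)
    vals = values[ids] if len(values) == solution.model.mesh.n_elements else values
    if len(vals) != len(ids):
        raise ValueError("values length matches neither the mesh nor the set")
    return float((v * vals).sum() / v.sum())


@dataclass
class MetricsRecord:
    """Deformation metrics of one micro solve.

    ``cells`` maps cell set name to that cell's metric dict; ``regions``
    holds the volume-averaged scalars for the ECM and PCM sets.
    """

    cells: dict[str, dict[str, float]]
    regions: dict[str, dict[str, float]]
    provenance: dict = field(default_factory=dict)


_REGION_METRICS = ("effective_strain", "effective_stress", "max_shear_strain")


def _region_averages(solution: MicroSolution, element_set) -> dict[str, float]:
    eff_strain = effective_scalar(solution.green_strain)
    eff_stress = effective_scalar(solution.cauchy)
    shear = max_shear(solution.green_strain)
    return {
        "effective_strain": volume_averaged_metric(solution, element_set, eff_strain),
        "effective_stress": volume_averaged_metric(solution, element_set, eff_stress),
        "max_shear_strain": volume_averaged_metric(solution, element_set, shear),
    }


def compute_metrics(solution: MicroSolution) -> MetricsRecord:
    """Full metric set of a converged solution.

    Per cell: volumetric strain, the three aspect-ratio changes, and
    volume-averaged effective strain, effective stress and maximum shear
    strain.  Per region (ECM, PCM): the volume-averaged scalars.
    """
    if not solution.converged:
        raise ValueError("metrics require a converged solution")
    model = solution.model
    cells: dict[str, dict[str, float]] = {}
    for name in model.cell_set_names:
        ids = model.mesh.element_sets.get(name)
        if ids is None or ids.size == 0:
            continue
        dar = aspect_ratio_change(solution, name)
        cells[name] = {
            "volumetric_strain": volumetric_strain(solution, name),
            "dAR_maj_min": float(dar[0]),
            "dAR_maj_mid": float(dar[1]),
            "dAR_mid_min": float(dar[2]),
            **_region_averages(solution, name),
        }
    regions: dict[str, dict[str, float]] = {}
    for region in ("ECM", "PCM"):
        ids = model.mesh.element_sets.get(region)
        if ids is not None and ids.size:
            regions[region] = _region_averages(solution, region)
    return MetricsRecord(
        cells=cells, regions=regions, provenance=dict(model.provenance)
    )


def metrics_to_dataframe(records: list[MetricsRecord]) -> pd.DataFrame:
    """One row per cell per micro model; region averages repeated per row."""
    rows = []
    for rec in records:
        base = {f"prov_{k}": v for k, v in rec.provenance.items()
                if np.isscalar(v) or isinstance(v, str)}
        for region, vals in rec.regions.items():
            base.update({f"{region}_{k}": v for k, v in vals.items()})
        for cell, vals in rec.cells.items():
            rows.append({"cell_id": cell, **vals, **base})
    return pd.DataFrame(rows)
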