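"""Batch orchestration: one micro model per deforming macro element.

Every micro job is independent — it receives a deformation gradient, builds
boundary conditions, solves, and post-processes — so the batch is
embarrassingly parallel.  A failed micro solve is recorded in the manifest
and skipped; it never aborts the batch.  Results are returned as a tidy
table (one row per cell per micro model) that is invariant to the worker
count and job execution order.

Summary analyses: through-origin linear regression of micro metrics against
macro effective strain (global and per cell), quartile summaries, and the
material sensitivity protocol (reference vs uniformly scaled vs softened
PCM).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .fe_solver import SolverSettings, apply_boundary_conditions, solve_static
from .macro_io import (
    DeformationGradientRecord,
    MacroState,
    element_deformation_gradients,
    filter_deforming_elements,
)
from .metrics import compute_metrics, effective_scalar, metrics_to_dataframe
from .microgen import (
    MaterialTable,
    MicroModel,
    assign_materials,
    build_micro_mesh,
    default_material_table,
    place_chondrons,
)
from .vtkio import write_vtk

__all__ = [
    "BatchManifest",
    "RegressionResult",
    "MicroConfig",
    "run_batch",
    "regress_through_origin",
    "per_cell_regressions",
    "quartile_summary",
    "sensitivity_study",
    "export_fringe",
    "macro_effective_strain",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MicroConfig:
    """Micro-model template for a batch.

    One chondron geometry (fixed by ``geometry_seed``) is reused for every
    macro element, so differences between rows reflect the passed
    deformation gradients alone.
    """

    n_cells: int = 1
    resolution: int = 50
    geometry_seed: int | None = 11
    deformation_tol: float = 1e-3
    material_scale: float = 1.0

    def build(self, table: MaterialTable | None = None) -> MicroModel:
        geom = place_chondrons(self.n_cells, seed=self.geometry_seed)
        model = build_micro_mesh(geom, resolution=self.resolution)
        table = table or default_material_table()
        if self.material_scale != 1.0:
            table = table.scaled(self.material_scale)
        return assign_materials(model, table)


@dataclass
class BatchManifest:
    """Job bookkeeping for one batch run."""

    run_id: str
    config: dict
    jobs: list[dict] = field(default_factory=list)

    @property
    def n_converged(self) -> int:
        return sum(1 for j in self.jobs if j["status"] == "converged")

    @property
    def n_failed(self) -> int:
        return sum(1 for j in self.jobs if j["status"] == "failed")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))


@dataclass(frozen=True)
class RegressionResult:
    """Least-squares line through the origin."""

    slope: float
    ssr: float
    n: int


def macro_effective_strain(F: np.ndarray) -> float:
    """Effective (von Mises) Green-Lagrange strain of a deformation gradient."""
    F = np.asarray(F, dtype=float)
    E = 0.5 * (F.T @ F - np.eye(3))
    return float(effective_scalar(E))


def _run_job(model: MicroModel, element_id: int, F: np.ndarray,
             settings: SolverSettings):
    bcs = apply_boundary_conditions(model.mesh, F)
    job_model = model.with_provenance(
        element_id=int(element_id),
        macro_effective_strain=macro_effective_strain(F),
        **{f"F{a + 1}{b + 1}": float(F[a, b]) for a in range(3) for b in range(3)},
    )
    try:
        sol = solve_static(job_model, bcs, settings)
    except Exception as exc:  # containment: a broken job must not kill the pool
        logger.exception("micro job for element %d raised", element_id)
        return element_id, "failed", {"reason": repr(exc)}, None
    if not sol.converged:
        return element_id, "failed", dict(sol.diagnostics), None
    record = compute_metrics(sol)
    return element_id, "converged", {}, record


def run_batch(
    state: MacroState,
    set_name: str | None,
    micro: MicroConfig,
    workers: int = 1,
    settings: SolverSettings | None = None,
    material_table: MaterialTable | None = None,
    manifest_path=None,
) -> tuple[BatchManifest, pd.DataFrame]:
    """Solve one micro model per deforming element of ``set_name``.

    Configuration errors (missing sets, missing materials) raise before any
    job starts; per-job failures are contained.  Returns the manifest and
    the results table sorted by ``(element_id, cell_id)``.
    """
    if workers < 1:
        raise ValueError("workers must be >= 1")
    settings = settings or SolverSettings()
    records = element_deformation_gradients(state, set_name, scheme="centroid")
    deforming = filter_deforming_elements(records, tol=micro.deformation_tol)
    model = micro.build(material_table)  # raises on bad config before any job

    config = {
        "set_name": set_name,
        "micro": asdict(micro),
        "n_jobs": len(deforming),
        "workers": workers,
    }
    run_id = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    manifest = BatchManifest(run_id=run_id, config=config)

    jobs = [(r.element_id, r.F) for r in deforming]
    if workers == 1:
        outputs = [_run_job(model, eid, F, settings) for eid, F in jobs]
    else:
        outputs = Parallel(n_jobs=workers, backend="loky")(
            delayed(_run_job)(model, eid, F, settings) for eid, F in jobs
        )

    metric_records = []
    for eid, status, info, record in outputs:
        manifest.jobs.append({"element_id": int(eid), "status": status,
                              "info": {k: v for k, v in info.items()
                                       if k in ("reason", "failed_at_load_fraction")}})
        if record is not None:
            metric_records.append(record)
    table = metrics_to_dataframe(metric_records)
    if len(table):
        table = table.sort_values(["prov_element_id", "cell_id"]).reset_index(drop=True)
    if manifest_path is not None:
        manifest.to_json(manifest_path)
    logger.info("batch %s: %d converged, %d failed of %d jobs",
                run_id, manifest.n_converged, manifest.n_failed, len(manifest.jobs))
    return manifest, table


def regress_through_origin(x, y) -> RegressionResult:
    """Least-squares slope of ``y = s x`` (line constrained through the origin).

    ``slope = sum(x y) / sum(x^2)``; ``ssr`` is the sum of squared residuals
    about the fitted line.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or x.size != y.size:
        raise ValueError("x and y must be equal-length and non-empty")
    sxx = float(np.dot(x, x))
    if sxx == 0.0:
        raise ValueError("all x are zero: through-origin slope undefined")
    slope = float(np.dot(x, y)) / sxx
    ssr = float(np.sum((y - slope * x) ** 2))
    return RegressionResult(slope=slope, ssr=ssr, n=int(x.size))


def per_cell_regressions(
    table: pd.DataFrame,
    x_col: str = "prov_macro_effective_strain",
    y_col: str = "dAR_maj_min",
) -> dict:
    """One through-origin regression per cell id; summary of the slopes.

    Returns ``{"per_cell": {cell_id: RegressionResult}, "min": .., "avg": ..,
    "max": ..}`` where the scalars summarize the slopes.  Cells with an empty
    or missing id are excluded with a warning.
    """
    per_cell: dict[str, RegressionResult] = {}
    for cell_id, group in table.groupby("cell_id"):
        if not isinstance(cell_id, str) or not cell_id:
            logger.warning("excluding %d rows with empty cell id", len(group))
            continue
        per_cell[cell_id] = regress_through_origin(group[x_col], group[y_col])
    if not per_cell:
        raise ValueError("no valid cell ids in results table")
    slopes = np.array([r.slope for r in per_cell.values()])
    return {
        "per_cell": per_cell,
        "min": float(slopes.min()),
        "avg": float(slopes.mean()),
        "max": float(slopes.max()),
    }


def quartile_summary(values) -> tuple[float, float, float, float, float]:
    """``(min, Q1, median, Q3, max)`` with linear interpolation between order
    statistics (numpy's ``linear`` quantile method)."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("quartile summary of empty sample")
    q = np.quantile(v, [0.0, 0.25, 0.5, 0.75, 1.0], method="linear")
    return tuple(float(t) for t in q)


SENSITIVITY_CASES = ("reference", "scaled10", "pcm10")


def sensitivity_study(
    micro: MicroConfig,
    cases=SENSITIVITY_CASES,
    settings: SolverSettings | None = None,
) -> dict:
    """Material sensitivity of cell strain amplification.

    The construct is loaded by a 10% nominal compression with
    volume-preserving lateral expansion (``F = diag(0.9^-1/2, 0.9^-1/2,
    0.9)``) under three material tables: the reference, the reference
    uniformly scaled by 10 (stiffness ratios preserved), and the reference
    with the PCM stiffness divided by 10.  For each case the per-cell ratio
    of cell to ECM volume-averaged effective strain is reported with its
    quartile summary.
    """
    lam = 0.9
    F = np.diag([lam**-0.5, lam**-0.5, lam])
    base = default_material_table()
    tables = {
        "reference": base,
        "scaled10": base.scaled(10.0),
        "pcm10": base.with_scaled_region("PCM", 0.1),
    }
    settings = settings or SolverSettings()
    out: dict[str, dict] = {}
    for case in cases:
        model = micro.build(tables[case])
        bcs = apply_boundary_conditions(model.mesh, F)
        sol = solve_static(model, bcs, settings)
        if not sol.converged:
            out[case] = {"status": "failed", "diagnostics": sol.diagnostics}
            continue
        rec = compute_metrics(sol)
        ecm = rec.regions["ECM"]["effective_strain"]
        if ecm == 0.0:
            raise ZeroDivisionError("ECM effective strain is zero: ratio undefined")
        ratios = [c["effective_strain"] / ecm for c in rec.cells.values()]
        cell_strains = [c["effective_strain"] for c in rec.cells.values()]
        out[case] = {
            "status": "converged",
            "ratios": ratios,
            "cell_effective_strains": cell_strains,
            "ecm_effective_strain": ecm,
            "quartiles": quartile_summary(ratios),
        }
    return out


def export_fringe(
    state: MacroState,
    values: dict[int, float] | pd.Series,
    name: str,
    path,
    sentinel: float = np.nan,
) -> None:
    """Write a per-element metric as VTK cell data on the macro mesh.

    Elements without a computed value receive ``sentinel``; their count is
    logged.
    """
    if isinstance(values, pd.Series):
        values = values.to_dict()
    arr = np.full(state.mesh.n_elements, sentinel, dtype=float)
    for eid, v in values.items():
        arr[int(eid)] = float(v)
    n_missing = state.mesh.n_elements - len(values)
    if n_missing:
        logger.info("fringe %s: %d of %d elements carry the sentinel value",
                    name, n_missing, state.mesh.n_elements)
    write_vtk(path, state.mesh, point_data={"displacement": state.displacement},
              cell_data={name: arr})
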