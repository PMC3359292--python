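"""Displacement-driven static finite-strain solver for the micro construct.

The micro model is loaded purely through prescribed displacements on the
block faces, ``u(X) = (F - I) X``, where ``F`` is the macro element's
deformation gradient.  Materials are uncoupled Mooney-Rivlin solids,

    W = c1 (I1bar - 3) + c2 (I2bar - 3) + (K/2) (ln J)^2,

with the isochoric invariants ``I1bar = J^{-2/3} tr(B)``,
``I2bar = J^{-4/3} (tr(B)^2 - tr(B^2)) / 2``.  The equilibrium equations are
solved with Newton-Raphson under incremental load steps, with an optional
backtracking line search.

Element technology: trilinear hexahedra with selective reduced integration
(mean dilatation) — the isochoric stress and tangent are integrated at the
eight Gauss points while the volumetric terms are integrated at the element
centroid only.  This removes the volumetric locking that full integration
exhibits at the near-incompressible ECM (Poisson ratio ~0.48) and the high
``K/c1`` ratio of the cells.

Linear solves use a direct sparse factorization below a size threshold and
GMRES with a diagonally-scaled incomplete-LU preconditioner above it; the
preconditioner is reused across Newton iterations, load steps and repeated
solves of the same model, and refreshed lazily when its quality degrades.

Mechanical non-convergence never raises: it is reported through the
solution's ``status`` so that a batch of independent micro models keeps
running when one of them fails.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import hexkernel
from .mesh import HexMesh
from .microgen import ChondronGeometry, Material, MaterialTable, MicroModel

__all__ = [
    "BoundaryConditionSet",
    "SolverSettings",
    "MicroSolution",
    "apply_boundary_conditions",
    "cauchy_stress",
    "strain_energy_density",
    "solve_static",
    "uniform_micro_model",
]

logger = logging.getLogger(__name__)

# Voigt pair ordering (engineering-shear convention): 11, 22, 33, 12, 23, 13.
_VI = np.array([0, 1, 2, 0, 1, 0])
_VJ = np.array([0, 1, 2, 1, 2, 2])


# ---------------------------------------------------------------------------
# Constitutive model
# ---------------------------------------------------------------------------

def _kinematics(F: np.ndarray):
    J = np.linalg.det(F)
    B = F @ np.swapaxes(F, -1, -2)
    return J, B


def strain_energy_density(F, material: Material) -> np.ndarray:
    """Stored energy per unit reference volume (MPa)."""
    F = np.asarray(F, dtype=float)
    single = F.ndim == 2
    F = F.reshape(-1, 3, 3)
    J, B = _kinematics(F)
    if np.any(J <= 0):
        raise ValueError("det F must be positive")
    Bbar = J[:, None, None] ** (-2.0 / 3.0) * B
    I1b = np.trace(Bbar, axis1=1, axis2=2)
    I2b = 0.5 * (I1b**2 - np.trace(Bbar @ Bbar, axis1=1, axis2=2))
    W = (
        material.c1 * (I1b - 3.0)
        + material.c2 * (I2b - 3.0)
        + 0.5 * material.K * np.log(J) ** 2
    )
    return float(W[0]) if single else W


def _kirchhoff_iso(F, c1, c2):
    """Isochoric Kirchhoff stress, batched.  ``c1``, ``c2``: (m,) or scalars."""
    J, B = _kinematics(F)
    Bbar = J[:, None, None] ** (-2.0 / 3.0) * B
    I1b = np.trace(Bbar, axis1=1, axis2=2)
    c1 = np.broadcast_to(np.asarray(c1, float), J.shape)
    c2 = np.broadcast_to(np.asarray(c2, float), J.shape)
    taubar = (
        2.0 * (c1 + c2 * I1b)[:, None, None] * Bbar
        - 2.0 * c2[:, None, None] * (Bbar @ Bbar)
    )
    tr = np.trace(taubar, axis1=1, axis2=2)
    tau_iso = taubar - (tr / 3.0)[:, None, None] * np.eye(3)
    return J, Bbar, taubar, tau_iso


def cauchy_stress(F, material: Material) -> np.ndarray:
    """Cauchy stress (MPa) of the uncoupled Mooney-Rivlin model.

    Symmetric; zero at ``F = I``.  Accepts a single ``(3, 3)`` tensor or a
    batch ``(m, 3, 3)``.
    """
    F = np.asarray(F, dtype=float)
    single = F.ndim == 2
    F = F.reshape(-1, 3, 3)
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise ValueError("det F must be positive")
    J, _, _, tau_iso = _kirchhoff_iso(F, material.c1, material.c2)
    tau = tau_iso + (material.K * np.log(J))[:, None, None] * np.eye(3)
    sigma = tau / J[:, None, None]
    return sigma[0] if single else sigma


def _voigt_outer(A, B):
    """(m,3,3) x (m,3,3) -> Voigt (m,6,6) of the dyad A (x) B."""
    a = A[:, _VI, _VJ]
    b = B[:, _VI, _VJ]
    return a[:, :, None] * b[:, None, :]


def _voigt_odot(A):
    """Voigt (m,6,6) of (A (.) A)_ijkl = (A_ik A_jl + A_il A_jk) / 2."""
    i, j = _VI[:, None], _VJ[:, None]
    k, l = _VI[None, :], _VJ[None, :]
    return 0.5 * (A[:, i, k] * A[:, j, l] + A[:, i, l] * A[:, j, k])


_EYE6 = np.diag([1.0, 1.0, 1.0, 0.5, 0.5, 0.5])  # symmetric 4th identity
_IDYAD = np.zeros((6, 6))
_IDYAD[:3, :3] = 1.0  # I (x) I


def _tangent_iso(F, c1, c2):
    """Isochoric Kirchhoff stress and spatial tangent (Voigt), batched.

    Returns ``(J, tau_iso, C_iso)`` with ``C_iso`` of shape (m, 6, 6), the
    push-forward elasticity tensor consistent with the Lie derivative of the
    isochoric Kirchhoff stress.
    """
    J, Bbar, taubar, tau_iso = _kirchhoff_iso(F, c1, c2)
    m = len(J)
    tr_taubar = np.trace(taubar, axis1=1, axis2=2)
    eyeb = np.broadcast_to(np.eye(3), (m, 3, 3))
    P6 = _EYE6 - _IDYAD / 3.0
    C = (2.0 / 3.0) * tr_taubar[:, None, None] * P6
    C -= (2.0 / 3.0) * (_voigt_outer(tau_iso, eyeb) + _voigt_outer(eyeb, tau_iso))
    c2 = np.broadcast_to(np.asarray(c2, float), J.shape)
    if np.any(c2 != 0.0):
        # fictitious modulus c~ = 4 c2 [Bbar (x) Bbar - Bbar (.) Bbar],
        # deviatorically projected on both legs: P : c~ : P.  Contraction over
        # a symmetric index pair in plain-component Voigt carries weight 2 on
        # the shear entries (W).
        Ct = 4.0 * c2[:, None, None] * (_voigt_outer(Bbar, Bbar) - _voigt_odot(Bbar))
        W = np.diag([1.0, 1.0, 1.0, 2.0, 2.0, 2.0])
        PW = P6 @ W
        C += np.einsum("IA,eAB,BJ->eIJ", PW, Ct, PW.T, optimize=True)
    return J, tau_iso, C


def _tangent_vol(F, K):
    """Volumetric Kirchhoff stress and spatial tangent (Voigt), batched."""
    J = np.linalg.det(F)
    K = np.broadcast_to(np.asarray(K, float), J.shape)
    lnJ = np.log(J)
    tau_vol = (K * lnJ)[:, None, None] * np.eye(3)
    # U = (K/2) ln^2 J:  J(U' + J U'') = K,  2 J U' = 2 K ln J
    C = K[:, None, None] * _IDYAD - (2.0 * K * lnJ)[:, None, None] * _EYE6
    return J, tau_vol, C


# ---------------------------------------------------------------------------
# Boundary conditions
# ---------------------------------------------------------------------------

@dataclass
class BoundaryConditionSet:
    """Prescribed nodal displacements.

    ``displacements`` may contain NaN components, meaning that component is
    left free (used for mixed conditions such as unconfined compression);
    the all-face affine conditions produced by
    :func:`apply_boundary_conditions` prescribe every component.
    """

    node_ids: np.ndarray
    displacements: np.ndarray

    def __post_init__(self) -> None:
        self.node_ids = np.asarray(self.node_ids, dtype=np.int64).ravel()
        self.displacements = np.asarray(self.displacements, dtype=float).reshape(-1, 3)
        if len(self.node_ids) != len(self.displacements):
            raise ValueError("node_ids and displacements length mismatch")
        if len(np.unique(self.node_ids)) != len(self.node_ids):
            raise ValueError("duplicate nodes in boundary condition set")

    def dof_arrays(self, n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
        """Expand to full ``(n, 3)`` mask and value arrays."""
        if self.node_ids.size and self.node_ids.max() >= n_nodes:
            raise ValueError("boundary condition references missing node")
        mask = np.zeros((n_nodes, 3), dtype=bool)
        values = np.zeros((n_nodes, 3))
        pres = ~np.isnan(self.displacements)
        mask[self.node_ids] = pres
        values[self.node_ids] = np.where(pres, self.displacements, 0.0)
        return mask, values


def boundary_nodes(mesh: HexMesh, tol: float = 1e-9) -> np.ndarray:
    """Indices of nodes on the six faces of the mesh's bounding box."""
    lo = mesh.nodes.min(axis=0)
    hi = mesh.nodes.max(axis=0)
    span = np.maximum(hi - lo, 1.0)
    on_face = (
        (np.abs(mesh.nodes - lo) < tol * span) | (np.abs(mesh.nodes - hi) < tol * span)
    ).any(axis=1)
    return np.flatnonzero(on_face)


def apply_boundary_conditions(mesh: HexMesh, F: np.ndarray) -> BoundaryConditionSet:
    """Affine displacements ``u = (F - I) X`` for every face node of the block."""
    F = np.asarray(F, dtype=float)
    if F.shape != (3, 3):
        raise ValueError("F must be a 3x3 tensor")
    if np.linalg.det(F) <= 0:
        raise ValueError("F must have positive determinant")
    ids = boundary_nodes(mesh)
    u = mesh.nodes[ids] @ (F - np.eye(3)).T
    return BoundaryConditionSet(node_ids=ids, displacements=u)


# ---------------------------------------------------------------------------
# Solver
# ---------------------------------------------------------------------------

@dataclass
class SolverSettings:
    """Newton/load-step controls.

    ``n_steps`` equal load increments; convergence when the free-DOF residual
    norm falls below ``tol`` times the step's initial residual (with a small
    absolute floor).
    """

    n_steps: int = 10
    tol: float = 1e-6
    max_iterations: int = 25
    line_search: bool = True
    linear_solver: str = "auto"  # auto | direct | ilu-gmres
    direct_threshold: int = 15_000
    linear_rtol: float = 1e-4
    gmres_restart: int = 100
    gmres_maxiter: int = 10
    ilu_drop_tol: float = 2e-3
    ilu_fill_factor: float = 5.0
    ilu_refresh_iters: int = 200
    min_step_fraction: float = 1.0 / 1024.0

    def __post_init__(self) -> None:
        if self.tol <= 0 or self.linear_rtol <= 0:
            raise ValueError("tolerances must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")


@dataclass
class MicroSolution:
    """Converged (or failed) state of one micro solve.

    Per-element tensors are centroid values on the converged configuration.
    ``status`` is ``"converged"`` or ``"failed"``; diagnostics carry the
    residual history and linear-solver bookkeeping either way.
    """

    model: MicroModel
    displacement: np.ndarray
    status: str
    diagnostics: dict = field(default_factory=dict)
    F: np.ndarray | None = None
    green_strain: np.ndarray | None = None
    cauchy: np.ndarray | None = None

    @property
    def converged(self) -> bool:
        return self.status == "converged"

    @property
    def deformed_positions(self) -> np.ndarray:
        return self.model.mesh.nodes + self.displacement


def uniform_micro_model(mesh: HexMesh, material: Material) -> MicroModel:
    """Wrap a plain mesh as a single-region (all-ECM) micro model."""
    geometry = ChondronGeometry(
        block_edge=float(np.max(mesh.nodes.max(axis=0) - mesh.nodes.min(axis=0))),
        centers=np.zeros((0, 3)),
    )
    labels = np.full(mesh.n_elements, "ECM", dtype="<U8")
    mesh.element_sets.setdefault("ECM", np.arange(mesh.n_elements))
    table = MaterialTable({"ECM": material})
    return MicroModel(mesh=mesh, geometry=geometry, labels=labels, materials=table)


_ILU_CACHE: dict = {}


class _LinearSolver:
    """Direct or ILU-preconditioned GMRES solve of the reduced Newton system.

    The tangent is symmetrically diagonal-scaled before the incomplete
    factorization (the cell/ECM stiffness contrast spans a factor ~40).  The
    ILU is built once and reused across Newton iterations and load steps; it
    is refreshed lazily when GMRES starts needing too many inner iterations.
    """

    def __init__(self, settings: SolverSettings, nfree: int, cache_key=None):
        mode = settings.linear_solver
        if mode == "auto":
            mode = "direct" if nfree <= settings.direct_threshold else "ilu-gmres"
        self.mode = mode
        self.settings = settings
        self.cache_key = (
            None
            if cache_key is None
            else (cache_key, settings.ilu_drop_tol, settings.ilu_fill_factor)
        )
        self._ilu = _ILU_CACHE.get(self.cache_key) if self.cache_key else None
        self.n_factor = 0
        self.n_inner_iters = 0

    def _store(self):
        if self.cache_key is not None:
            while len(_ILU_CACHE) >= 2:  # keep at most two models' factors
                _ILU_CACHE.pop(next(iter(_ILU_CACHE)))
            _ILU_CACHE[self.cache_key] = self._ilu

    def _drop(self):
        self._ilu = None
        if self.cache_key is not None:
            _ILU_CACHE.pop(self.cache_key, None)

    def solve(self, K: sp.csr_matrix, rhs: np.ndarray) -> np.ndarray | None:
        if self.mode == "direct":
            self.n_factor += 1
            return spla.splu(K.tocsc()).solve(rhs)
        s = self.settings
        d = np.sqrt(K.diagonal())
        if np.any(d <= 0) or not np.all(np.isfinite(d)):
            return None
        Dinv = sp.diags(1.0 / d)
        Ks = (Dinv @ K @ Dinv).tocsr()
        bs = rhs / d
        for _ in range(2):
            if self._ilu is None:
                try:
                    self._ilu = spla.spilu(
                        Ks.tocsc(),
                        drop_tol=s.ilu_drop_tol,
                        fill_factor=s.ilu_fill_factor,
                        permc_spec="MMD_AT_PLUS_A",
                        diag_pivot_thresh=0.0,
                        options=dict(SymmetricMode=True),
                    )
                except RuntimeError:
                    return None
                self.n_factor += 1
                self._store()
            M = spla.LinearOperator(Ks.shape, self._ilu.solve)
            iters = [0]

            def cb(_):
                iters[0] += 1

            x, info = spla.gmres(
                Ks,
                bs,
                rtol=s.linear_rtol,
                atol=0.0,
                restart=s.gmres_restart,
                maxiter=s.gmres_maxiter,
                M=M,
                callback=cb,
                callback_type="pr_norm",
            )
            self.n_inner_iters += iters[0]
            if info == 0:
                if iters[0] > s.ilu_refresh_iters:
                    self._drop()  # refresh before the next solve
                return x / d
            self._drop()  # stale preconditioner: rebuild and retry once
        return None


_PATTERN_CACHE: dict = {}


class _Assembler:
    """Vectorized SRI assembly of internal force and tangent."""

    def __init__(self, mesh: HexMesh, materials: list[Material]):
        self.mesh = mesh
        self.X = mesh.element_coords()  # (ne, 8, 3)
        ne = mesh.n_elements
        self.c1 = np.array([m.c1 for m in materials])
        self.c2 = np.array([m.c2 for m in materials])
        self.K = np.array([m.K for m in materials])
        if len(self.c1) != ne:
            raise ValueError("one material per element required")
        self.dN_gauss = np.stack(
            [hexkernel.shape_gradients(g) for g in hexkernel.GAUSS8_POINTS]
        )  # (8, 8, 3)
        self.dN_cent = hexkernel.shape_gradients((0.0, 0.0, 0.0))  # (8, 3)
        dofs = (3 * mesh.elements[:, :, None] + np.arange(3)).reshape(ne, 24)
        self.edofs = dofs
        self.ndof = 3 * mesh.n_nodes
        # fixed sparsity pattern: map every element-matrix entry to its slot
        # in the assembled CSR arrays once, then assembly is a bincount;
        # cached because batches reuse one mesh for many solves
        key = (hash(mesh.elements.tobytes()), self.ndof)
        cached = _PATTERN_CACHE.get(key)
        if cached is None:
            rows = np.repeat(dofs, 24, axis=1).ravel()
            cols = np.tile(dofs, (1, 24)).ravel()
            keys = rows.astype(np.int64) * self.ndof + cols
            uniq, inverse = np.unique(keys, return_inverse=True)
            csr_indices = (uniq % self.ndof).astype(np.int32)
            counts = np.bincount((uniq // self.ndof).astype(np.int64),
                                 minlength=self.ndof)
            csr_indptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int32)
            cached = (inverse, len(uniq), csr_indices, csr_indptr)
            _PATTERN_CACHE.clear()  # keep at most one mesh's pattern
            _PATTERN_CACHE[key] = cached
        self._slot, self._nnz, self._csr_indices, self._csr_indptr = cached

    # -- kinematic helpers ---------------------------------------------------
    def _point_state(self, x, dN):
        """Current-config gradients and F at one natural point for all elements.

        Returns (gradN (ne,8,3), detj (ne,), F (ne,3,3)) or None if tangled.
        """
        j_def = np.einsum("eai,ab->eib", x, dN, optimize=True)
        detj = np.linalg.det(j_def)
        if np.any(detj <= 0.0):
            return None
        J_ref = np.einsum("eai,ab->eib", self.X, dN, optimize=True)
        inv_jdef = np.linalg.inv(j_def)
        gradN = np.einsum("ab,ebi->eai", dN, inv_jdef, optimize=True)
        F = j_def @ np.linalg.inv(J_ref)
        return gradN, detj, F

    def states(self, u: np.ndarray):
        """Kinematic state at the 8 Gauss points and the centroid, or None."""
        x = self.X + u.reshape(-1, 3)[self.mesh.elements]
        gauss = []
        for dN in self.dN_gauss:
            st = self._point_state(x, dN)
            if st is None:
                return None
            gauss.append(st)
        cent = self._point_state(x, self.dN_cent)
        if cent is None:
            return None
        return gauss, cent

    # -- force and stiffness -------------------------------------------------
    def internal_force(self, states) -> np.ndarray:
        gauss, cent = states
        ne = self.mesh.n_elements
        f = np.zeros((ne, 8, 3))
        for gradN, detj, F in gauss:
            J, _, _, tau_iso = _kirchhoff_iso(F, self.c1, self.c2)
            sigma = tau_iso / J[:, None, None]
            f += np.einsum("eij,eaj,e->eai", sigma, gradN, detj, optimize=True)
        gradN, detj, F = cent
        J, tau_vol, _ = _tangent_vol(F, self.K)
        sigma = tau_vol / J[:, None, None]
        f += 8.0 * np.einsum("eij,eaj,e->eai", sigma, gradN, detj, optimize=True)
        fvec = np.zeros(self.ndof)
        np.add.at(fvec, self.edofs.ravel(), f.reshape(ne, 24).ravel())
        return fvec

    @staticmethod
    def _bmatrix(gradN):
        """Engineering-strain B matrix, (ne, 6, 24)."""
        ne = gradN.shape[0]
        B = np.zeros((ne, 6, 24))
        gx, gy, gz = gradN[:, :, 0], gradN[:, :, 1], gradN[:, :, 2]
        B[:, 0, 0::3] = gx
        B[:, 1, 1::3] = gy
        B[:, 2, 2::3] = gz
        B[:, 3, 0::3] = gy
        B[:, 3, 1::3] = gx
        B[:, 4, 1::3] = gz
        B[:, 4, 2::3] = gy
        B[:, 5, 0::3] = gz
        B[:, 5, 2::3] = gx
        return B

    def _point_stiffness(self, out, gradN, detj, sigma, Cvoigt, weight):
        """Accumulate one integration point's K contribution into ``out``."""
        B = self._bmatrix(gradN)
        w = (weight * detj)[:, None, None]
        CB = (w * Cvoigt) @ B  # (ne, 6, 24) batched GEMM
        out += B.transpose(0, 2, 1) @ CB
        s = gradN @ (w * sigma)  # (ne, 8, 3)
        G = s @ gradN.transpose(0, 2, 1)  # (ne, 8, 8)
        for d in range(3):
            out[:, d::3, d::3] += G

    def tangent(self, states) -> sp.csr_matrix:
        gauss, cent = states
        ne = self.mesh.n_elements
        Ke = np.zeros((ne, 24, 24))
        for gradN, detj, F in gauss:
            J, tau_iso, C = _tangent_iso(F, self.c1, self.c2)
            Jinv = 1.0 / J
            self._point_stiffness(
                Ke, gradN, detj, tau_iso * Jinv[:, None, None],
                C * Jinv[:, None, None], 1.0,
            )
        gradN, detj, F = cent
        J, tau_vol, C = _tangent_vol(F, self.K)
        Jinv = 1.0 / J
        self._point_stiffness(
            Ke, gradN, detj, tau_vol * Jinv[:, None, None],
            C * Jinv[:, None, None], 8.0,
        )
        data = np.bincount(self._slot, weights=Ke.ravel(), minlength=self._nnz)
        return sp.csr_matrix(
            (data, self._csr_indices, self._csr_indptr),
            shape=(self.ndof, self.ndof),
        )


def solve_static(
    model: MicroModel,
    bcs: BoundaryConditionSet,
    settings: SolverSettings | None = None,
) -> MicroSolution:
    """Solve the displacement-driven static problem.

    Newton-Raphson under ``settings.n_steps`` equal load increments.  On
    mechanical non-convergence (including element inversion during
    iteration), returns a solution with ``status='failed'`` and diagnostics —
    the caller's batch continues.  Structural problems (missing materials,
    unconstrained boundary) raise.
    """
    settings = settings or SolverSettings()
    mesh = model.mesh
    materials = model.element_materials()
    asm = _Assembler(mesh, materials)

    mask, values = bcs.dof_arrays(mesh.n_nodes)
    bnodes = boundary_nodes(mesh)
    if not mask[bnodes].all(axis=1).any():
        # not all-face affine conditions: require at least some constraint
        if not mask.any():
            raise ValueError("no prescribed displacements: rigid modes unconstrained")
    free = ~mask.ravel()
    nfree = int(free.sum())
    mat_key = (
        hash(asm.c1.tobytes()) ^ hash(asm.c2.tobytes()) ^ hash(asm.K.tobytes()),
        hash(mesh.elements.tobytes()),
        hash(mask.tobytes()),
    )
    lin = _LinearSolver(settings, nfree, cache_key=mat_key)

    u = np.zeros(3 * mesh.n_nodes)
    values_flat = np.where(mask, values, 0.0).ravel()
    pres_flat = mask.ravel()
    history: list[dict] = []
    t0 = time.perf_counter()
    diag = {"nfree": nfree, "linear_solver": lin.mode, "residual_history": history}

    def fail(reason, t):
        diag.update(
            {"reason": reason, "failed_at_load_fraction": t,
             "wall_time": time.perf_counter() - t0,
             "n_factorizations": lin.n_factor, "linear_iterations": lin.n_inner_iters}
        )
        logger.warning("micro solve failed at load fraction %.4f: %s", t, reason)
        return MicroSolution(
            model=model, displacement=u.reshape(-1, 3), status="failed",
            diagnostics=diag,
        )

    # Incremental loading with an adaptive step: each increment is driven
    # through the tangent (predictor solves K_ff du = -(R_f + K_fp du_p), so
    # the prescribed boundary motion is extended smoothly into the interior),
    # then corrected by Newton at fixed prescribed values.  An increment that
    # tangles elements or fails to converge is halved and retried.
    t = 0.0
    dt_nominal = 1.0 / settings.n_steps
    dt = dt_nominal
    dt_min = dt_nominal * settings.min_step_fraction
    states = asm.states(u)
    if states is None:
        raise ValueError("undeformed mesh contains inverted elements")
    while t < 1.0 - 1e-12:
        dt = min(dt, 1.0 - t)
        # predictor from the last converged state
        R = asm.internal_force(states)
        K = asm.tangent(states)
        du_p = np.where(pres_flat, dt * values_flat, 0.0)
        rhs = -(R[free] + (K @ du_p)[free])
        delta = lin.solve(_reduce(K, free), rhs)
        if delta is None:
            return fail("linear solver failure", t)
        u_trial = u + du_p
        u_trial[free] += delta
        tstates = asm.states(u_trial)
        if tstates is None:
            if dt / 2.0 < dt_min:
                return fail("element inversion (step below minimum)", t)
            dt /= 2.0
            continue
        # corrector: Newton at fixed prescribed displacements
        res_hist: list[float] = []
        history.append({"load_fraction": t + dt, "residuals": res_hist})
        converged = False
        for _ in range(settings.max_iterations):
            R = asm.internal_force(tstates)
            rnorm = float(np.linalg.norm(R[free]))
            res_hist.append(rnorm)
            force_scale = max(float(np.linalg.norm(R)), 1e-30)
            if rnorm <= settings.tol * force_scale:
                converged = True
                break
            K = asm.tangent(tstates)
            delta = lin.solve(_reduce(K, free), -R[free])
            if delta is None:
                return fail("linear solver failure", t + dt)
            step_vec = np.zeros_like(u_trial)
            step_vec[free] = delta
            alpha, accepted = 1.0, False
            best = None
            for _ in range(8 if settings.line_search else 1):
                cand = u_trial + alpha * step_vec
                cstates = asm.states(cand)
                if cstates is not None:
                    if best is None:
                        best = (cand, cstates)
                    if not settings.line_search:
                        accepted = True
                    else:
                        cnorm = float(np.linalg.norm(asm.internal_force(cstates)[free]))
                        if cnorm < rnorm or cnorm <= settings.tol * force_scale:
                            accepted = True
                    if accepted:
                        u_trial, tstates = cand, cstates
                        break
                alpha *= 0.5
            if not accepted:
                if best is None:
                    break  # inversion at every step length: substep
                u_trial, tstates = best  # accept shortest untangled step
        if converged:
            u, states = u_trial, tstates
            t += dt
            if len(res_hist) <= 4:
                dt = min(dt * 2.0, dt_nominal)
        else:
            if dt / 2.0 < dt_min:
                return fail("Newton did not converge (step below minimum)", t)
            dt /= 2.0

    # converged: per-element centroid outputs
    x = asm.X + u.reshape(-1, 3)[mesh.elements]
    F = hexkernel.batch_deformation_gradients(asm.X, x, np.zeros((1, 3)))[:, 0]
    E = 0.5 * (np.swapaxes(F, 1, 2) @ F - np.eye(3))
    J, _, _, tau_iso = _kirchhoff_iso(F, asm.c1, asm.c2)
    tau = tau_iso + (asm.K * np.log(J))[:, None, None] * np.eye(3)
    sigma = tau / J[:, None, None]
    diag.update(
        {"wall_time": time.perf_counter() - t0, "n_factorizations": lin.n_factor,
         "linear_iterations": lin.n_inner_iters}
    )
    return MicroSolution(
        model=model,
        displacement=u.reshape(-1, 3),
        status="converged",
        diagnostics=diag,
        F=F,
        green_strain=E,
        cauchy=sigma,
    )


def _reduce(K: sp.csr_matrix, free: np.ndarray) -> sp.csr_matrix:
    """Extract the free-free block of the tangent."""
    idx = np.flatnonzero(free)
    return K[idx][:, idx].tocsr()
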