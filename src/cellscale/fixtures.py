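"""Synthetic macro states and canonical micro load cases.

No public repository carries the joint-scale FE solution this pipeline was
designed around, so every stage is exercised against synthetic macro states
whose deformation fields are known in closed form: the mesh is a hex slab,
the deformed nodal positions are an analytic map ``x(X)`` applied to the
nodes, and the exact deformation gradient ``F(X)`` is available at any point
for error measurement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .fe_solver import BoundaryConditionSet
from .macro_io import MacroState
from .mesh import HexMesh, structured_hex_grid

__all__ = [
    "AnalyticDeformation",
    "affine_deformation",
    "uniaxial_deformation",
    "simple_shear_deformation",
    "bending_deformation",
    "combined_deformation",
    "synthetic_macro_solution",
    "canonical_micro_cases",
]


@dataclass(frozen=True)
class AnalyticDeformation:
    """Closed-form deformation: map ``x(X)`` and exact gradient ``F(X)``.

    Both callables accept an ``(n, 3)`` array.  ``gradient`` returns
    ``(n, 3, 3)``; ``det F > 0`` must hold on the fixture domain (checked on
    a sample grid by :func:`synthetic_macro_solution`).
    """

    name: str
    map: Callable[[np.ndarray], np.ndarray]
    gradient: Callable[[np.ndarray], np.ndarray]


def affine_deformation(F0, translation=(0.0, 0.0, 0.0)) -> AnalyticDeformation:
    """Homogeneous deformation ``x = F0 X + c``; F is F0 everywhere."""
    F0 = np.asarray(F0, dtype=float)
    c = np.asarray(translation, dtype=float)
    if np.linalg.det(F0) <= 0:
        raise ValueError("affine map must have det F0 > 0")
    return AnalyticDeformation(
        name="affine",
        map=lambda X: X @ F0.T + c,
        gradient=lambda X: np.broadcast_to(F0, (len(X), 3, 3)).copy(),
    )


def uniaxial_deformation(stretch: float, axis: int = 2,
                         volume_preserving: bool = True) -> AnalyticDeformation:
    """Uniaxial stretch along one axis, laterally expanded to preserve volume."""
    lam = np.ones(3)
    lam[axis] = stretch
    if volume_preserving:
        lam[[a for a in range(3) if a != axis]] = stretch**-0.5
    return affine_deformation(np.diag(lam))


def simple_shear_deformation(gamma: float, plane: tuple[int, int] = (0, 2)
                             ) -> AnalyticDeformation:
    """Simple shear ``x_i += gamma * X_j`` for ``(i, j) = plane``; det F = 1."""
    F0 = np.eye(3)
    F0[plane] = gamma
    return affine_deformation(F0)


def bending_deformation(curvature: float) -> AnalyticDeformation:
    """Pure bending of a slab about the y-axis with curvature ``kappa``.

    Material lines along x are bent into arcs of radius ``1/kappa - y``:

        x = (1/kappa - Y) sin(kappa X),  y = 1/kappa - (1/kappa - Y) cos(kappa X)

    so ``det F = 1 - kappa Y``, positive while the slab stays thinner than
    the bend radius.  The gradient varies smoothly through the slab, giving
    centroid sampling a genuine discretization error that shrinks under mesh
    refinement.
    """
    if curvature == 0.0:
        return affine_deformation(np.eye(3))
    k = curvature

    def _map(X):
        theta = k * X[:, 0]
        rho = 1.0 / k - X[:, 1]
        x = X.copy()
        x[:, 0] = rho * np.sin(theta)
        x[:, 1] = 1.0 / k - rho * np.cos(theta)
        return x

    def _grad(X):
        theta = k * X[:, 0]
        rho = 1.0 / k - X[:, 1]
        F = np.broadcast_to(np.eye(3), (len(X), 3, 3)).copy()
        F[:, 0, 0] = rho * k * np.cos(theta)
        F[:, 0, 1] = -np.sin(theta)
        F[:, 1, 0] = rho * k * np.sin(theta)
        F[:, 1, 1] = np.cos(theta)
        return F

    return AnalyticDeformation(name="bending", map=_map, gradient=_grad)


def combined_deformation(F0, curvature: float) -> AnalyticDeformation:
    """Affine map composed with the bending field."""
    aff = affine_deformation(F0)
    bend = bending_deformation(curvature)

    def _map(X):
        return aff.map(bend.map(X))

    def _grad(X):
        return aff.gradient(X) @ bend.gradient(X)

    return AnalyticDeformation(name="combined", map=_map, gradient=_grad)


def synthetic_macro_solution(
    shape: tuple[int, int, int],
    lengths: tuple[float, float, float],
    deformation: AnalyticDeformation,
    set_name: str = "slab",
) -> tuple[MacroState, AnalyticDeformation]:
    """Hex slab whose deformed positions follow an analytic map.

    Returns the macro state together with the deformation, whose
    ``gradient`` is the oracle for extracted F fields.  Raises if the map
    tangles the mesh (non-positive det F at any node).
    """
    mesh = structured_hex_grid(shape, lengths)
    mesh.element_sets[set_name] = np.arange(mesh.n_elements)
    F = deformation.gradient(mesh.nodes)
    if np.any(np.linalg.det(F) <= 0.0):
        raise ValueError(f"deformation {deformation.name!r} tangles the fixture domain")
    deformed = deformation.map(mesh.nodes)
    state = MacroState(mesh=mesh, undeformed=mesh.nodes, deformed=deformed)
    return state, deformation


@dataclass(frozen=True)
class MicroLoadCase:
    """A named micro-scale load protocol.

    ``kind='affine'`` prescribes all six faces via the deformation gradient
    ``F``; ``kind='mixed'`` prescribes only the z-faces (nominal strain
    ``nominal``) and leaves the lateral faces traction-free — the unconfined
    compression protocol used for mesh convergence, with two corner nodes
    pinned in-plane to remove rigid modes.
    """

    name: str
    kind: str
    F: np.ndarray | None = None
    nominal: float | None = None

    def boundary_conditions(self, mesh: HexMesh) -> BoundaryConditionSet:
        from .fe_solver import apply_boundary_conditions

        if self.kind == "affine":
            return apply_boundary_conditions(mesh, self.F)
        # mixed: z faces prescribed, lateral free
        lo = mesh.nodes.min(axis=0)
        hi = mesh.nodes.max(axis=0)
        span = hi - lo
        z = mesh.nodes[:, 2]
        tol = 1e-9 * max(span[2], 1.0)
        ids = np.flatnonzero((np.abs(z - lo[2]) < tol) | (np.abs(z - hi[2]) < tol))
        disp = np.full((len(ids), 3), np.nan)
        disp[:, 2] = self.nominal * (mesh.nodes[ids, 2] - lo[2])
        # pin in-plane rigid translations/rotation at two bottom corners
        c0 = int(np.argmin(np.linalg.norm(mesh.nodes - lo, axis=1)))
        c1 = int(np.argmin(np.linalg.norm(mesh.nodes - [hi[0], lo[1], lo[2]], axis=1)))
        for nid, comps in ((c0, (0, 1)), (c1, (1,))):
            where = np.flatnonzero(ids == nid)
            if where.size:
                disp[where[0], list(comps)] = 0.0
        return BoundaryConditionSet(node_ids=ids, displacements=disp)


def canonical_micro_cases() -> list[MicroLoadCase]:
    """The standard micro load protocols (deterministic, no randomness).

    * ``unconfined_compression_30``: -30% nominal z-strain with free lateral
      expansion (mixed boundary conditions);
    * ``volume_preserving_compression_10``: 10% nominal z-compression with
      volume-preserving lateral expansion, all faces prescribed (det F = 1);
    * ``simple_shear_10``: simple shear of 0.1 in the x-z plane, all faces
      prescribed.
    """
    lam = 0.9
    F_vp = np.diag([lam**-0.5, lam**-0.5, lam])
    F_shear = np.eye(3)
    F_shear[0, 2] = 0.1
    return [
        MicroLoadCase(name="unconfined_compression_30", kind="mixed", nominal=-0.30),
        MicroLoadCase(name="volume_preserving_compression_10", kind="affine", F=F_vp),
        MicroLoadCase(name="simple_shear_10", kind="affine", F=F_shear),
    ]
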