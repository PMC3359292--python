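"""Trilinear 8-node hexahedron mathematics.

Everything downstream of the macro solution rests on the isoparametric
formulation: each hexahedral element is mapped to the bi-unit reference cube
``[-1, 1]^3`` where interpolation and integration are carried out.  This
module provides the shape functions, their natural-coordinate gradients, the
Jacobian of the reference-to-global map, the deformation gradient obtained by
composing the maps of the undeformed and deformed configurations, and element
volumes.

Node ordering follows the VTK ``VTK_HEXAHEDRON`` convention: the bottom face
``zeta = -1`` counter-clockwise ``(-1,-1,-1), (1,-1,-1), (1,1,-1), (-1,1,-1)``
then the top face ``zeta = +1`` in the same order.  Any consistent ordering
yields the same deformation gradient; this one interoperates directly with
legacy-VTK meshes.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "NATURAL_CORNERS",
    "GAUSS8_POINTS",
    "InvertedElementError",
    "OutOfDomainError",
    "shape_values",
    "shape_gradients",
    "jacobian",
    "deformation_gradient",
    "element_volume",
    "batch_jacobians",
    "batch_deformation_gradients",
    "batch_volumes",
]

#: Natural coordinates of the eight corner nodes (VTK hexahedron ordering).
NATURAL_CORNERS = np.array(
    [
        [-1.0, -1.0, -1.0],
        [1.0, -1.0, -1.0],
        [1.0, 1.0, -1.0],
        [-1.0, 1.0, -1.0],
        [-1.0, -1.0, 1.0],
        [1.0, -1.0, 1.0],
        [1.0, 1.0, 1.0],
        [-1.0, 1.0, 1.0],
    ]
)

#: 2x2x2 Gauss quadrature points (each with unit weight on the bi-unit cube).
GAUSS8_POINTS = NATURAL_CORNERS / np.sqrt(3.0)

_DOMAIN_TOL = 1e-12


class InvertedElementError(ValueError):
    """Raised when an element's Jacobian determinant is non-positive."""


class OutOfDomainError(ValueError):
    """Raised when a natural point lies outside the bi-unit cube."""


def _check_point(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.shape != (3,):
        raise ValueError(f"natural point must have shape (3,), got {p.shape}")
    if np.any(np.abs(p) > 1.0 + _DOMAIN_TOL):
        raise OutOfDomainError(f"natural point {p} outside [-1, 1]^3")
    return p


def shape_values(p) -> np.ndarray:
    """Trilinear shape function values ``N_a(p)`` for the eight nodes.

    The weights form a partition of unity and interpolate: ``N_a`` is one at
    node ``a``'s natural corner and zero at the other seven.
    """
    p = _check_point(p)
    return np.prod(1.0 + NATURAL_CORNERS * p, axis=1) / 8.0


def shape_gradients(p) -> np.ndarray:
    """Gradients ``dN_a / d(xi, eta, zeta)`` as an ``(8, 3)`` array.

    The eight gradient vectors sum to zero (constant fields are reproduced
    exactly).
    """
    p = _check_point(p)
    xi = NATURAL_CORNERS
    terms = 1.0 + xi * p  # (8, 3)
    grads = np.empty((8, 3))
    grads[:, 0] = xi[:, 0] * terms[:, 1] * terms[:, 2] / 8.0
    grads[:, 1] = terms[:, 0] * xi[:, 1] * terms[:, 2] / 8.0
    grads[:, 2] = terms[:, 0] * terms[:, 1] * xi[:, 2] / 8.0
    return grads


def jacobian(coords, p) -> np.ndarray:
    """Jacobian ``J_iA = d x_i / d xi_A`` of the isoparametric map at ``p``.

    ``coords`` is the ``(8, 3)`` array of nodal positions.  ``det J`` is the
    local ratio of global to natural volume; a non-positive determinant means
    the element is tangled.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (8, 3):
        raise ValueError(f"element coords must have shape (8, 3), got {coords.shape}")
    J = coords.T @ shape_gradients(p)
    if np.linalg.det(J) <= 0.0:
        raise InvertedElementError(
            f"non-positive Jacobian determinant ({np.linalg.det(J):.3e}) at {p}"
        )
    return J


def deformation_gradient(undeformed, deformed, p=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Deformation gradient ``F = (dx/dxi)(dX/dxi)^-1`` at natural point ``p``.

    Composes the deformed-configuration map with the inverse of the
    undeformed-configuration map; exact for affine deformations at any ``p``.
    """
    J_ref = jacobian(undeformed, p)
    deformed = np.asarray(deformed, dtype=float)
    J_def = deformed.T @ shape_gradients(p)
    F = J_def @ np.linalg.inv(J_ref)
    if np.linalg.det(F) <= 0.0:
        raise InvertedElementError("deformation gradient has non-positive determinant")
    return F


def element_volume(coords, rule: str = "centroid") -> float:
    """Volume of a hexahedral element.

    ``rule='centroid'`` evaluates ``8 * det J`` at the element centroid (the
    isoparametric cube has volume 8); this one-point rule is exact whenever
    ``det J`` is constant (any parallelepiped).  ``rule='gauss8'`` integrates
    ``det J`` with 2x2x2 Gauss quadrature, exact for any untangled trilinear
    hex.
    """
    coords = np.asarray(coords, dtype=float)
    if rule == "centroid":
        return 8.0 * float(np.linalg.det(jacobian(coords, (0.0, 0.0, 0.0))))
    if rule == "gauss8":
        vol = 0.0
        for g in GAUSS8_POINTS:
            vol += float(np.linalg.det(jacobian(coords, g)))
        return vol
    raise ValueError(f"unknown volume rule {rule!r}")


# ---------------------------------------------------------------------------
# Batched forms.  These operate on (ne, 8, 3) stacks of element coordinates
# and are the workhorses of the macro extraction and the micro solver.
# ---------------------------------------------------------------------------

def batch_jacobians(coords: np.ndarray, dN: np.ndarray) -> np.ndarray:
    """Jacobians for a stack of elements at one natural point.

    Parameters
    ----------
    coords : (ne, 8, 3) nodal positions.
    dN : (8, 3) shape gradients at the evaluation point.

    Returns
    -------
    (ne, 3, 3) Jacobian matrices (no positivity check; callers inspect dets).
    """
    return np.einsum("eai,ab->eib", coords, dN, optimize=True)


def batch_deformation_gradients(
    undeformed: np.ndarray, deformed: np.ndarray, points: np.ndarray
) -> np.ndarray:
    """Deformation gradients for a stack of elements at several points.

    Returns an ``(ne, npts, 3, 3)`` array; raises
    :class:`InvertedElementError` naming the first offending element if a
    reference Jacobian is singular or ``det F <= 0``.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    dNs = np.stack([shape_gradients(p) for p in points])  # (npts, 8, 3)
    J_ref = np.einsum("eai,pab->epib", undeformed, dNs, optimize=True)
    J_def = np.einsum("eai,pab->epib", deformed, dNs, optimize=True)
    det_ref = np.linalg.det(J_ref)
    if np.any(det_ref <= 0.0):
        bad = int(np.argwhere(det_ref <= 0.0)[0][0])
        raise InvertedElementError(
            f"singular reference Jacobian in element {bad} (det={det_ref.min():.3e})"
        )
    F = J_def @ np.linalg.inv(J_ref)
    det_F = np.linalg.det(F)
    if np.any(det_F <= 0.0):
        bad = int(np.argwhere(det_F <= 0.0)[0][0])
        raise InvertedElementError(
            f"non-positive det F in element {bad} (det={det_F.min():.3e})"
        )
    return F


def batch_volumes(coords: np.ndarray, rule: str = "centroid") -> np.ndarray:
    """Volumes of a stack of elements, ``(ne,)``."""
    if rule == "centroid":
        dN = shape_gradients((0.0, 0.0, 0.0))
        dets = np.linalg.det(batch_jacobians(coords, dN))
        if np.any(dets <= 0.0):
            bad = int(np.argmin(dets))
            raise InvertedElementError(f"inverted element {bad} (det={dets[bad]:.3e})")
        return 8.0 * dets
    if rule == "gauss8":
        vols = np.zeros(coords.shape[0])
        for g in GAUSS8_POINTS:
            dets = np.linalg.det(batch_jacobians(coords, shape_gradients(g)))
            if np.any(dets <= 0.0):
                bad = int(np.argmin(dets))
                raise InvertedElementError(
                    f"inverted element {bad} (det={dets[bad]:.3e})"
                )
            vols += dets
        return vols
    raise ValueError(f"unknown volume rule {rule!r}")
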