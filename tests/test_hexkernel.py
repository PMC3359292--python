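"""Isoparametric hexahedron math against hand values and FD oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cellscale import hexkernel as hk

natural_points = st.tuples(
    *(st.floats(-1.0, 1.0, allow_nan=False) for _ in range(3))
)


class TestShapeFunctions:
    def test_centroid_weights_are_uniform(self):
        assert np.allclose(hk.shape_values((0, 0, 0)), 1.0 / 8.0, atol=1e-15)

    @pytest.mark.parametrize("node", range(8))
    def test_interpolation_at_corners(self, node):
        w = hk.shape_values(hk.NATURAL_CORNERS[node])
        expected = np.zeros(8)
        expected[node] = 1.0
        assert np.allclose(w, expected, atol=1e-15)

    def test_hand_evaluated_point(self):
        # at (0.5, 0, 0): nodes on xi=+1 get (1.5/2)(1/2)(1/2)=0.1875,
        # nodes on xi=-1 get 0.0625
        w = hk.shape_values((0.5, 0.0, 0.0))
        plus = hk.NATURAL_CORNERS[:, 0] > 0
        assert np.allclose(w[plus], 0.1875)
        assert np.allclose(w[~plus], 0.0625)

    def test_out_of_range_point_rejected(self):
        with pytest.raises(hk.OutOfDomainError):
            hk.shape_values((1.2, 0.0, 0.0))
        with pytest.raises(hk.OutOfDomainError):
            hk.shape_gradients((0.0, -1.5, 0.0))

    @given(natural_points)
    def test_partition_of_unity_and_gradient_closure(self, p):
        assert abs(hk.shape_values(p).sum() - 1.0) < 1e-14
        assert np.abs(hk.shape_gradients(p).sum(axis=0)).max() < 1e-14

    def test_partition_of_unity_bulk(self, rng):
        pts = rng.uniform(-1, 1, size=(1000, 3))
        for p in pts:
            assert abs(hk.shape_values(p).sum() - 1.0) < 1e-14
            w = hk.shape_values(p)
            # nodal interpolation of coordinates reproduces the point
            assert np.abs(w @ hk.NATURAL_CORNERS - p).max() < 1e-14

    def test_centroid_gradients(self):
        g = hk.shape_gradients((0, 0, 0))
        assert np.allclose(np.abs(g), 1.0 / 8.0)
        assert np.allclose(g, hk.NATURAL_CORNERS / 8.0)

    def test_gradients_match_finite_differences(self, rng):
        h = 1e-6
        for p in rng.uniform(-0.99, 0.99, size=(20, 3)):
            g = hk.shape_gradients(p)
            for d in range(3):
                pp, pm = p.copy(), p.copy()
                pp[d] += h
                pm[d] -= h
                fd = (hk.shape_values(pp) - hk.shape_values(pm)) / (2 * h)
                assert np.abs(g[:, d] - fd).max() < 1e-8


class TestJacobian:
    def test_axis_aligned_box(self, rng):
        a, b, c = 2.0, 3.0, 0.5
        coords = (hk.NATURAL_CORNERS + 1.0) / 2.0 * [a, b, c]
        for p in rng.uniform(-1, 1, size=(5, 3)):
            J = hk.jacobian(coords, p)
            assert np.allclose(J, np.diag([a / 2, b / 2, c / 2]), atol=1e-14)

    def test_unit_cube_determinant(self):
        coords = (hk.NATURAL_CORNERS + 1.0) / 2.0
        assert np.isclose(np.linalg.det(hk.jacobian(coords, (0.3, -0.2, 0.9))), 1 / 8)

    def test_inverted_element_flagged(self):
        coords = (hk.NATURAL_CORNERS + 1.0) / 2.0
        coords = coords * [1, 1, -1]  # reflected through z=0: negative det
        with pytest.raises(hk.InvertedElementError):
            hk.jacobian(coords, (0, 0, 0))

    def test_warped_hex_matches_position_map_fd(self, rng):
        from conftest import warped_hex

        coords = warped_hex(rng)
        h = 1e-6
        for p in rng.uniform(-0.9, 0.9, size=(5, 3)):
            J = hk.jacobian(coords, p)
            for d in range(3):
                pp, pm = p.copy(), p.copy()
                pp[d] += h
                pm[d] -= h
                xd = (hk.shape_values(pp) - hk.shape_values(pm)) @ coords / (2 * h)
                assert np.abs(J[:, d] - xd).max() < 1e-7


class TestDeformationGradient:
    def test_identity_when_undeformed(self, rng):
        from conftest import warped_hex

        coords = warped_hex(rng)
        F = hk.deformation_gradient(coords, coords, (0.2, -0.4, 0.7))
        assert np.allclose(F, np.eye(3), atol=1e-13)

    def test_affine_exactness(self, rng):
        from conftest import warped_hex

        coords = warped_hex(rng)
        for _ in range(10):
            F0 = np.eye(3) + 0.3 * rng.standard_normal((3, 3))
            if np.linalg.det(F0) <= 0.2:
                continue
            deformed = coords @ F0.T + rng.standard_normal(3)
            for p in rng.uniform(-1, 1, size=(3, 3)):
                F = hk.deformation_gradient(coords, deformed, p)
                assert np.abs(F - F0).max() < 1e-12

    def test_trilinear_warp_matches_fd_oracle(self, rng):
        from conftest import warped_hex

        X = warped_hex(rng)
        x = warped_hex(rng, scale=0.2)
        h = 1e-6
        for p in rng.uniform(-0.9, 0.9, size=(4, 3)):
            F = hk.deformation_gradient(X, x, p)
            Jx = np.zeros((3, 3))
            JX = np.zeros((3, 3))
            for d in range(3):
                pp, pm = p.copy(), p.copy()
                pp[d] += h
                pm[d] -= h
                dw = hk.shape_values(pp) - hk.shape_values(pm)
                Jx[:, d] = dw @ x / (2 * h)
                JX[:, d] = dw @ X / (2 * h)
            assert np.abs(F - Jx @ np.linalg.inv(JX)).max() < 1e-6

    def test_rigid_motion_properties(self, rng):
        from conftest import warped_hex
        from scipy.spatial.transform import Rotation

        X = warped_hex(rng)
        x = warped_hex(rng, scale=0.2)
        p = (0.1, -0.3, 0.5)
        F = hk.deformation_gradient(X, x, p)
        # translations of either configuration leave F unchanged
        assert np.allclose(hk.deformation_gradient(X + 5.0, x, p), F, atol=1e-12)
        assert np.allclose(hk.deformation_gradient(X, x + [1, -2, 3], p), F,
                           atol=1e-12)
        # rotating the deformed configuration left-multiplies F
        R = Rotation.from_rotvec([0.3, -0.5, 0.8]).as_matrix()
        F_rot = hk.deformation_gradient(X, x @ R.T, p)
        assert np.allclose(F_rot, R @ F, atol=1e-12)


def _tet_volume(a, b, c, d):
    return abs(np.linalg.det(np.array([b - a, c - a, d - a]))) / 6.0


def _hex_volume_by_tets(coords):
    """Volume of a planar-faced hex by decomposition into six tetrahedra."""
    tets = [(0, 1, 3, 4), (1, 2, 3, 6), (1, 3, 4, 6),
            (3, 4, 6, 7), (1, 4, 5, 6)]
    return sum(_tet_volume(*(coords[i] for i in t)) for t in tets)


class TestElementVolume:
    def test_unit_cube_both_rules(self):
        coords = (hk.NATURAL_CORNERS + 1.0) / 2.0
        assert np.isclose(hk.element_volume(coords, "centroid"), 1.0)
        assert np.isclose(hk.element_volume(coords, "gauss8"), 1.0)

    def test_tet_decomposition_oracle_on_cube(self):
        coords = (hk.NATURAL_CORNERS + 1.0) / 2.0
        assert np.isclose(_hex_volume_by_tets(coords), 1.0)

    def test_parallelepiped_centroid_rule_exact(self, rng):
        M = np.eye(3) + 0.4 * rng.standard_normal((3, 3))
        while np.linalg.det(M) < 0.2:
            M = np.eye(3) + 0.4 * rng.standard_normal((3, 3))
        coords = ((hk.NATURAL_CORNERS + 1.0) / 2.0) @ M.T
        exact = abs(np.linalg.det(M))
        assert np.isclose(hk.element_volume(coords, "centroid"), exact, rtol=1e-12)
        assert np.isclose(hk.element_volume(coords, "gauss8"), exact, rtol=1e-12)

    def test_planar_faced_frustum(self):
        # truncated pyramid: top face shrunk but planar; det J varies, so the
        # one-point centroid rule is only approximate while gauss8 is exact
        coords = (hk.NATURAL_CORNERS + 1.0) / 2.0
        top = coords[:, 2] > 0.5
        coords = coords.copy()
        coords[top, :2] = 0.5 + (coords[top, :2] - 0.5) * 0.6
        v_tet = _hex_volume_by_tets(coords)
        v_g8 = hk.element_volume(coords, "gauss8")
        v_c = hk.element_volume(coords, "centroid")
        assert abs(v_g8 - v_tet) < 1e-10
        assert abs(v_c - v_tet) > 1e-4  # quantified centroid-rule bias

    def test_gauss8_matches_dense_quadrature(self, rng):
        from conftest import warped_hex
        from numpy.polynomial.legendre import leggauss

        coords = warped_hex(rng)
        pts, wts = leggauss(3)
        dense = 0.0
        for i, wi in zip(pts, wts):
            for j, wj in zip(pts, wts):
                for k, wk in zip(pts, wts):
                    J = hk.jacobian(coords, (i, j, k))
                    dense += wi * wj * wk * np.linalg.det(J)
        assert np.isclose(hk.element_volume(coords, "gauss8"), dense, rtol=1e-12)

    def test_batch_volumes_match_scalar(self, rng):
        from conftest import warped_hex

        stack = np.stack([warped_hex(rng) for _ in range(5)])
        for rule in ("centroid", "gauss8"):
            batch = hk.batch_volumes(stack, rule)
            scalar = [hk.element_volume(c, rule) for c in stack]
            assert np.allclose(batch, scalar, rtol=1e-13)
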