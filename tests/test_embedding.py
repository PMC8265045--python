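"""Material embedding, transfer, fiducial alignment, organ placement."""

import numpy as np
import pytest

from anatscaffold import (
    Bulge,
    MaterialPoint,
    deform_mesh,
    element_jacobian,
    embed_points,
    eval_field,
    fiducial_transform,
    place_organ,
    transfer_points,
)
from anatscaffold.fitting import flat_params, flat_weights
from conftest import identity_cube


@pytest.fixture()
def bulged_cube():
    """Identity cube smoothly deformed by a Gaussian bulge (exact chain rule)."""
    mesh = identity_cube()
    return deform_mesh(mesh, Bulge(amplitude=0.15, sigma=0.8, center=(0.3, 0.4, 0.2)))


class TestEmbed:
    def test_point_at_node_is_corner(self):
        mesh = identity_cube()
        [ep] = embed_points(mesh, "coordinates", [(1.0, 1.0, 0.0)], mode="surface")
        assert ep.residual == pytest.approx(0.0, abs=1e-12)
        assert ep.mp.xi == pytest.approx((1.0, 1.0, 0.0), abs=1e-9)
        assert not ep.off_mesh

    def test_interior_point_of_identity_cube(self):
        mesh = identity_cube()
        [ep] = embed_points(mesh, "coordinates", [(0.25, 0.5, 0.75)], mode="volume")
        assert ep.mp.xi == pytest.approx((0.25, 0.5, 0.75), abs=1e-9)
        assert ep.residual < 1e-10

    def test_deformed_cube_matches_grid_inversion_oracle(self, bulged_cube):
        rng = np.random.default_rng(21)
        true_mps = [tuple(rng.uniform(0.05, 0.95, 3)) for _ in range(20)]
        pts = np.array(
            [eval_field(bulged_cube, "coordinates", MaterialPoint(1, xi)) for xi in true_mps]
        )
        embedded = embed_points(bulged_cube, "coordinates", pts, mode="volume")
        # dense 51^3 grid oracle
        n = 51
        g = np.linspace(0, 1, n)
        xi_grid = np.stack(np.meshgrid(g, g, g, indexing="ij"), axis=-1).reshape(-1, 3)
        W = flat_weights(xi_grid, (0, 0, 0))
        P = flat_params(bulged_cube, 1, "coordinates")
        X = W @ P.T
        for ep, p, true_xi in zip(embedded, pts, true_mps):
            assert ep.residual < 1e-8
            k = int(np.argmin(np.linalg.norm(X - p, axis=1)))
            oracle_xi = xi_grid[k]
            assert np.max(np.abs(np.array(ep.mp.xi) - oracle_xi)) < 1.0 / (n - 1)
            assert np.max(np.abs(np.array(ep.mp.xi) - true_xi)) < 1e-8

    def test_outside_point_flagged_off_mesh(self):
        mesh = identity_cube()
        [ep] = embed_points(mesh, "coordinates", [(2.0, 0.5, 0.5)], mode="volume")
        assert ep.off_mesh
        assert ep.residual == pytest.approx(1.0, abs=1e-8)


class TestTransfer:
    def test_same_mesh_round_trip(self, bulged_cube):
        rng = np.random.default_rng(22)
        pts = np.array(
            [
                eval_field(bulged_cube, "coordinates", MaterialPoint(1, tuple(xi)))
                for xi in rng.uniform(0.1, 0.9, size=(10, 3))
            ]
        )
        embedded = embed_points(bulged_cube, "coordinates", pts, mode="volume")
        out, errors = transfer_points(embedded, bulged_cube, "coordinates")
        assert not errors
        for (label, q), p in zip(out, pts):
            assert np.linalg.norm(q - p) < 1e-9

    def test_fitted_to_generic_round_trip(self, bulged_cube):
        """Cells observed in the deformed configuration map back to the
        reference configuration and re-embed at the same material point."""
        generic = identity_cube()
        rng = np.random.default_rng(23)
        true_mps = [tuple(rng.uniform(0.1, 0.9, 3)) for _ in range(10)]
        observed = np.array(
            [eval_field(bulged_cube, "coordinates", MaterialPoint(1, xi)) for xi in true_mps]
        )
        embedded = embed_points(bulged_cube, "coordinates", observed, mode="volume")
        generic_pts, errors = transfer_points(embedded, generic, "coordinates")
        assert not errors
        re_embedded = embed_points(
            generic, "coordinates", np.array([p for _, p in generic_pts]), mode="volume"
        )
        for ep, true_xi in zip(re_embedded, true_mps):
            assert np.max(np.abs(np.array(ep.mp.xi) - true_xi)) < 1e-6

    def test_missing_element_reported(self, bulged_cube):
        from anatscaffold import EmbeddedPoint, Mesh

        other = identity_cube()
        ep = EmbeddedPoint("c1", "", MaterialPoint(99, (0.5, 0.5, 0.5)), 0.0)
        out, errors = transfer_points([ep], other)
        assert out == []
        assert len(errors) == 1 and "99" in errors[0]


class TestFiducialTransform:
    src = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0.3, 0.2, 0.9]])

    def test_scale_and_translation(self):
        dst = 2.0 * self.src + np.array([1.0, 0.0, 0.0])
        xf, rms = fiducial_transform(self.src, dst)
        assert xf.scale == pytest.approx(2.0, abs=1e-12)
        np.testing.assert_allclose(xf.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(xf.translation, (1, 0, 0), atol=1e-12)
        assert rms == pytest.approx(0.0, abs=1e-12)

    def test_pure_rotation_recovered(self):
        from scipy.spatial.transform import Rotation

        R = Rotation.from_rotvec([0.3, -0.5, 0.8]).as_matrix()
        dst = self.src @ R.T
        xf, rms = fiducial_transform(self.src, dst)
        assert xf.scale == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(xf.rotation, R, atol=1e-10)
        assert rms < 1e-12

    def test_noisy_pairs_match_grid_search(self):
        """3-pair toy with in-plane rotation about z: brute-force search
        over (angle, scale) agrees with the closed form to ~1e-3."""
        rng = np.random.default_rng(31)
        src = np.array([[0, 0, 0], [1, 0, 0], [0, 1.3, 0]])
        ang_true, s_true = 0.4, 1.2
        R = np.array(
            [[np.cos(ang_true), -np.sin(ang_true), 0],
             [np.sin(ang_true), np.cos(ang_true), 0], [0, 0, 1]]
        )
        dst = s_true * src @ R.T + np.array([0.5, -0.2, 0.0])
        dst[:, :2] += 0.02 * rng.standard_normal((3, 2))
        xf, rms = fiducial_transform(src, dst)

        best = None
        for ang in np.arange(0.0, 0.8, 5e-4):
            Rg = np.array(
                [[np.cos(ang), -np.sin(ang), 0], [np.sin(ang), np.cos(ang), 0],
                 [0, 0, 1]]
            )
            for s in np.arange(1.0, 1.4, 5e-4):
                t = dst.mean(axis=0) - s * Rg @ src.mean(axis=0)
                err = np.sqrt(np.mean(np.sum((s * src @ Rg.T + t - dst) ** 2, axis=1)))
                if best is None or err < best[0]:
                    best = (err, ang, s)
        err_g, ang_g, s_g = best
        got_ang = np.arctan2(xf.rotation[1, 0], xf.rotation[0, 0])
        assert abs(got_ang - ang_g) < 1.5e-3
        assert abs(xf.scale - s_g) < 1.5e-3
        assert rms <= err_g + 1e-9

    def test_collinear_rejected(self):
        src = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        with pytest.raises(ValueError, match="collinear"):
            fiducial_transform(src, src + 1.0)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            fiducial_transform(self.src[:2], self.src[:2])


class TestPlaceOrgan:
    def _pairs(self):
        return [
            (MaterialPoint(1, (0, 0, 0)), MaterialPoint(1, (0, 0, 0))),
            (MaterialPoint(1, (1, 0, 0)), MaterialPoint(1, (1, 0, 0))),
            (MaterialPoint(1, (0, 1, 0)), MaterialPoint(1, (0, 1, 0))),
            (MaterialPoint(1, (0.5, 0.5, 1)), MaterialPoint(1, (0.5, 0.5, 1))),
        ]

    def test_identity_pairs_leave_organ_unchanged(self):
        organ = identity_cube()
        placed, xf, rms = place_organ(organ, identity_cube(), self._pairs())
        assert rms < 1e-12
        for nid, node in organ.nodes.items():
            np.testing.assert_allclose(
                placed.nodes[nid].params["coordinates"], node.params["coordinates"],
                atol=1e-12,
            )

    def test_translated_body_translates_organ(self):
        organ = identity_cube()
        body = identity_cube(offset=(3.0, -1.0, 2.0))
        placed, xf, rms = place_organ(organ, body, self._pairs())
        assert rms < 1e-12
        np.testing.assert_allclose(xf.translation, (3, -1, 2), atol=1e-12)
        for nid, node in organ.nodes.items():
            np.testing.assert_allclose(
                placed.nodes[nid].params["coordinates"][0, :, 0],
                node.params["coordinates"][0, :, 0] + np.array([3.0, -1.0, 2.0]),
                atol=1e-12,
            )

    def test_fiducial_residual_bounded_by_transform_rms(self):
        rng = np.random.default_rng(41)
        organ = identity_cube()
        body = identity_cube()
        for node in body.nodes.values():
            node.params["coordinates"][0, :, 0] += 0.05 * rng.standard_normal(3)
        pairs = self._pairs()
        placed, xf, rms = place_organ(organ, body, pairs)
        for organ_mp, body_mp in pairs:
            placed_pt = eval_field(placed, "coordinates", organ_mp)
            body_pt = eval_field(body, "coordinates", body_mp)
            assert np.linalg.norm(placed_pt - body_pt) <= 2 * rms + 1e-12

    def test_jacobians_rotate_and_scale(self):
        """After placement, element Jacobians equal s R J within 1e-9."""
        organ = identity_cube()
        body = identity_cube()
        for node in body.nodes.values():  # body = organ scaled by 1.7 + rotated 90deg
            blk = node.params["coordinates"][0]
            R = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
            blk[:, 0] = 1.7 * R @ blk[:, 0]
            for s in (1, 2, 4):
                blk[:, s] = 1.7 * R @ blk[:, s]
        placed, xf, rms = place_organ(organ, body, self._pairs())
        assert rms < 1e-9
        mp = MaterialPoint(1, (0.3, 0.6, 0.2))
        J0, _ = element_jacobian(organ, "coordinates", mp)
        J1, _ = element_jacobian(placed, "coordinates", mp)
        np.testing.assert_allclose(J1, xf.scale * xf.rotation @ J0, atol=1e-9)
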