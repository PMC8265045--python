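"""Projection and regularised fitting."""

import numpy as np
import pytest

from anatscaffold import (
    ContourDataset,
    Contour,
    FitConfig,
    FitError,
    MaterialPoint,
    eval_field,
    fit,
    project_dataset,
    project_point,
    solve_linear_fit,
)
from anatscaffold.fitting import Projection, flat_weights, project_points
from anatscaffold.hermite import AnnotationGroup
from conftest import curved_square_2d, flat_square_2d, identity_cube, two_shared_cubes


def grid_oracle(mesh, eid, point, n=201):
    """Dense xi-grid closest-point search on one 2D element."""
    u = np.linspace(0.0, 1.0, n)
    uu, vv = np.meshgrid(u, u, indexing="ij")
    xis = np.column_stack([uu.ravel(), vv.ravel()])
    W = flat_weights(xis, (0, 0))
    from anatscaffold.fitting import flat_params

    P = flat_params(mesh, eid, "coordinates")
    X = W @ P.T
    d = np.linalg.norm(X - point, axis=1)
    k = int(np.argmin(d))
    return xis[k], d[k]


class TestProjection:
    def test_point_at_node_projects_to_corner(self):
        mesh = identity_cube()
        pr = project_point(mesh, "coordinates", (1.0, 0.0, 0.0))
        assert pr.distance == pytest.approx(0.0, abs=1e-12)
        assert pr.mp.xi == pytest.approx((1.0, 0.0, 0.0), abs=1e-9)

    def test_flat_square_above_center(self):
        mesh = flat_square_2d()
        pr = project_point(mesh, "coordinates", (0.5, 0.5, 1.0))
        assert pr.distance == pytest.approx(1.0, abs=1e-10)
        assert pr.mp.xi == pytest.approx((0.5, 0.5), abs=1e-8)

    @pytest.mark.parametrize("builder", [flat_square_2d, curved_square_2d])
    def test_matches_dense_grid_oracle(self, builder):
        mesh = builder()
        rng = np.random.default_rng(11)
        pts = rng.uniform(-0.3, 1.3, size=(100, 3))
        grid_res = np.sqrt(2.0) / 200  # oracle xi resolution in physical units ~O(h)
        for p in pts:
            pr = project_point(mesh, "coordinates", p)
            _, d_oracle = grid_oracle(mesh, 1, p)
            assert pr.distance <= d_oracle + 1e-12
            assert abs(pr.distance - d_oracle) < grid_res

    def test_equidistant_tie_breaks_to_lower_element_id(self):
        mesh = two_shared_cubes()
        pr = project_point(mesh, "coordinates", (1.0, 0.5, 2.0))  # above shared face
        assert pr.mp.element_id == 1

    def test_dataset_restricted_to_annotated_group(self):
        mesh = two_shared_cubes()
        mesh.add_group(AnnotationGroup(term="left region", elements={1}))
        mesh.add_group(AnnotationGroup(term="right region", elements={2}))
        # nearer to element 2 but annotated as the left region
        ds = ContourDataset(
            contours=[
                Contour("left region", "", False, np.array([[1.9, 0.5, 0.5],
                                                            [1.8, 0.4, 0.5]]))
            ]
        )
        projs = project_dataset(mesh, "coordinates", ds, FitConfig())
        assert all(p.mp.element_id == 1 for p in projs)

    def test_dataset_sampled_from_surface_has_zero_distance(self, mouse_colon):
        from anatscaffold import sample_contours

        ds = sample_contours(mouse_colon, rings_per_element=1, points_per_ring=4,
                             noise_sd=0.0, seed=0)
        projs = project_dataset(mouse_colon, "coordinates", ds, FitConfig())
        assert max(p.distance for p in projs) < 1e-8

    def test_empty_dataset_rejected(self, mouse_colon):
        with pytest.raises(Exception):
            project_dataset(mouse_colon, "coordinates", ContourDataset(), FitConfig())


def _with_fitted(mesh):
    m = mesh.copy()
    m.declare_field("fitted", 3)
    for n in m.nodes.values():
        n.params["fitted"] = n.params["coordinates"].copy()
    return m


def _sample_mps(mesh, rng, n, surface_axis=None):
    eids = sorted(mesh.elements)
    out = []
    for _ in range(n):
        eid = eids[int(rng.integers(len(eids)))]
        xi = rng.uniform(0, 1, size=3)
        if surface_axis is not None:
            xi[surface_axis] = 1.0
        out.append(MaterialPoint(eid, tuple(xi)))
    return out


class TestLinearSolve:
    def test_self_projections_leave_parameters_unchanged(self, mouse_colon):
        m = _with_fitted(mouse_colon)
        rng = np.random.default_rng(0)
        projs = [
            Projection(i, mp, 0.0, 1.0, eval_field(m, "coordinates", mp))
            for i, mp in enumerate(_sample_mps(m, rng, 200))
        ]
        solve_linear_fit(m, "fitted", projs, FitConfig())
        for nid, node in mouse_colon.nodes.items():
            np.testing.assert_allclose(
                m.nodes[nid].params["fitted"], node.params["coordinates"], atol=1e-9
            )

    def test_translation_recovered_exactly(self, mouse_colon):
        """Dense surface sampling translated by (1,0,0): both penalties are
        translation-invariant, so the fitted field is reference + t."""
        m = _with_fitted(mouse_colon)
        t = np.array([1.0, 0.0, 0.0])
        rng = np.random.default_rng(1)
        projs = [
            Projection(i, mp, 0.0, 1.0, eval_field(m, "coordinates", mp) + t)
            for i, mp in enumerate(_sample_mps(m, rng, 600, surface_axis=2))
        ]
        solve_linear_fit(m, "fitted", projs, FitConfig())
        expect = np.zeros((3, 8))
        expect[:, 0] = t
        worst = max(
            np.max(np.abs(m.nodes[nid].params["fitted"][0]
                          - node.params["coordinates"][0] - expect))
            for nid, node in mouse_colon.nodes.items()
        )
        assert worst < 1e-8

    def test_affine_recovered_without_penalties(self, mouse_colon):
        """Volume sampling of an affine-transformed copy, lambda=beta=0:
        the unique least-squares solution is the affine map of the nodal
        parameters (Hermite interpolation commutes with affine maps)."""
        rng = np.random.default_rng(2)
        A = np.eye(3) + 0.1 * rng.standard_normal((3, 3))
        b = rng.standard_normal(3) * 2.0
        m = _with_fitted(mouse_colon)
        projs = [
            Projection(i, mp, 0.0, 1.0, A @ eval_field(m, "coordinates", mp) + b)
            for i, mp in enumerate(_sample_mps(m, rng, 4000))
        ]
        cfg = FitConfig(lambda_strain=0.0, beta_smooth=0.0)
        solve_linear_fit(m, "fitted", projs, cfg)
        for nid, node in mouse_colon.nodes.items():
            ref = node.params["coordinates"][0]
            want = ref.copy()
            want[:, 0] = A @ ref[:, 0] + b
            want[:, 1:] = A @ ref[:, 1:]
            got = m.nodes[nid].params["fitted"][0]
            scale = max(1.0, np.max(np.abs(want)))
            assert np.max(np.abs(got - want)) / scale < 1e-6

    def test_single_point_single_free_node_interpolates(self):
        mesh = _with_fitted(identity_cube())
        target = np.array([0.2, 0.1, -0.3])
        projs = [Projection(0, MaterialPoint(1, (0.0, 0.0, 0.0)), 0.0, 1.0, target)]
        cfg = FitConfig(lambda_strain=0.0, beta_smooth=0.0,
                        free_nodes={1}, free_slots={0})
        solve_linear_fit(mesh, "fitted", projs, cfg)
        got = eval_field(mesh, "fitted", MaterialPoint(1, (0.0, 0.0, 0.0)))
        np.testing.assert_allclose(got, target, atol=1e-10)

    def test_underdetermined_without_penalties_raises(self):
        mesh = _with_fitted(identity_cube())
        projs = [Projection(0, MaterialPoint(1, (0.5, 0.5, 0.5)), 0.0, 1.0,
                            np.array([0.5, 0.5, 0.5]))]
        with pytest.raises(FitError, match="lambda_strain"):
            solve_linear_fit(mesh, "fitted", projs,
                             FitConfig(lambda_strain=0.0, beta_smooth=0.0))

    def test_strong_strain_limit_is_reference_plus_translation(self, mouse_colon):
        """lambda -> infinity pins all derivatives to the reference; the
        remaining null direction of the strain penalty is a translation."""
        rng = np.random.default_rng(3)
        t = np.array([0.4, -0.2, 0.7])
        m = _with_fitted(mouse_colon)
        mps = _sample_mps(m, rng, 500)
        projs = [
            Projection(
                i, mp, 0.0, 1.0,
                eval_field(m, "coordinates", mp) + t + 0.05 * rng.standard_normal(3),
            )
            for i, mp in enumerate(mps)
        ]
        cfg = FitConfig(lambda_strain=1e8, beta_smooth=0.0, strain_mode="reference")
        solve_linear_fit(m, "fitted", projs, cfg)
        shifts = np.array(
            [
                m.nodes[nid].params["fitted"][0, :, 0]
                - node.params["coordinates"][0, :, 0]
                for nid, node in mouse_colon.nodes.items()
            ]
        )
        # uniform translation, close to the true one
        assert np.max(np.ptp(shifts, axis=0)) < 1e-4
        assert np.linalg.norm(shifts.mean(axis=0) - t) < 0.02

    def test_matches_dense_quadratic_oracle_on_2d_element(self):
        """On one 2D element with 8 free parameters the sparse solve agrees
        with an independent dense minimisation of the same objective,
        reconstructed purely from objective evaluations."""
        mesh = _with_fitted(curved_square_2d())
        rng = np.random.default_rng(5)
        mps = [MaterialPoint(1, tuple(rng.uniform(0, 1, 2))) for _ in range(12)]
        projs = [
            Projection(i, mp, 0.0, 1.0,
                       eval_field(mesh, "coordinates", mp) + 0.1 * rng.standard_normal(3))
            for i, mp in enumerate(mps)
        ]
        cfg = FitConfig(lambda_strain=0.05, beta_smooth=0.01,
                        free_nodes={1, 2}, free_slots={0},
                        strain_mode="reference")

        # independent oracle: evaluate the quadratic objective through
        # eval_field + quadrature and solve its dense normal equations
        free = [(1, 0), (2, 0)]  # (node id, slot): 2 nodes x value slot x 3 comps

        def set_theta(m, th):
            for k, (nid, slot) in enumerate(free):
                m.nodes[nid].params["fitted"][0, :, slot] = th[3 * k : 3 * k + 3]

        def objective(th):
            m = mesh.copy()
            set_theta(m, th)
            val = 0.0
            for pr in projs:
                val += np.sum((eval_field(m, "fitted", pr.mp) - pr.point) ** 2)
            from anatscaffold.hermite import GAUSS3_W, GAUSS3_X

            for qi, wi in zip(GAUSS3_X, GAUSS3_W):
                for qj, wj in zip(GAUSS3_X, GAUSS3_W):
                    mp = MaterialPoint(1, (qi, qj))
                    for deriv, tw in [((1, 0), 1), ((0, 1), 1),
                                      ((2, 0), 1), ((0, 2), 1), ((1, 1), 2)]:
                        lam = cfg.lambda_strain if sum(deriv) == 1 else cfg.beta_smooth
                        diff = eval_field(m, "fitted", mp, deriv) - eval_field(
                            m, "coordinates", mp, deriv
                        )
                        val += lam * tw * wi * wj * float(np.sum(diff**2))
            return val

        n = 3 * len(free)
        th0 = np.concatenate(
            [mesh.nodes[nid].params["coordinates"][0, :, slot] for nid, slot in free]
        )
        f0 = objective(th0)
        g = np.zeros(n)
        H = np.zeros((n, n))
        h = 1.0
        for i in range(n):
            ei = np.zeros(n)
            ei[i] = h
            fp, fm = objective(th0 + ei), objective(th0 - ei)
            g[i] = (fp - fm) / (2 * h)
            H[i, i] = (fp - 2 * f0 + fm) / h**2
        for i in range(n):
            for j in range(i + 1, n):
                ei = np.zeros(n)
                ej = np.zeros(n)
                ei[i] = h
                ej[j] = h
                H[i, j] = H[j, i] = (
                    objective(th0 + ei + ej)
                    - objective(th0 + ei)
                    - objective(th0 + ej)
                    + f0
                ) / h**2
        oracle = th0 - np.linalg.solve(H, g)

        solve_linear_fit(mesh, "fitted", projs, cfg)
        got = np.concatenate(
            [mesh.nodes[nid].params["fitted"][0, :, slot] for nid, slot in free]
        )
        np.testing.assert_allclose(got, oracle, atol=1e-8)


class TestFit:
    def test_zero_noise_self_data_converges_immediately(self, mouse_colon):
        from anatscaffold import sample_contours

        ds = sample_contours(mouse_colon, rings_per_element=1, points_per_ring=4,
                             noise_sd=0.0, seed=0)
        fitted, diag = fit(mouse_colon, ds, FitConfig(outer_iterations=3))
        assert diag.rms[0] < 1e-8
        assert diag.converged

    def test_translation_equivariance(self, mouse_colon):
        """fit(data + t) equals fit(data) + t."""
        from anatscaffold import sample_contours
        import copy

        ds = sample_contours(mouse_colon, rings_per_element=1, points_per_ring=4,
                             noise_sd=0.05, seed=4)
        t = np.array([2.0, -1.0, 0.5])
        ds2 = copy.deepcopy(ds)
        for c in ds2.contours:
            c.points = c.points + t
        cfg = FitConfig(outer_iterations=2, rms_tol=0.0)
        f1, _ = fit(mouse_colon, ds, cfg)
        shifted = mouse_colon.copy()
        for n in shifted.nodes.values():
            n.params["coordinates"][:, :, 0] += t
        f2, _ = fit(shifted, ds2, cfg)
        for nid in mouse_colon.nodes:
            a = f1.nodes[nid].params["fitted"][0].copy()
            a[:, 0] += t
            b = f2.nodes[nid].params["fitted"][0]
            # tolerance reflects normal-equations conditioning, not method bias
            np.testing.assert_allclose(a, b, atol=1e-5)

    def test_objective_monotone_in_point_mode(self, mouse_colon):
        from anatscaffold import DeformationSpec, make_specimen

        spec = DeformationSpec(mode="bulge", amplitude=0.06, noise_sd=0.02, seed=6)
        sp = make_specimen(mouse_colon, spec, n_cells=1,
                           rings_per_element=2, points_per_ring=5)
        cfg = FitConfig(data_term="point", strain_mode="reference",
                        outer_iterations=5, rms_tol=0.0)
        _, diag = fit(mouse_colon, sp.contours, cfg)
        assert len(diag.objective) == 5
        for a, b in zip(diag.objective, diag.objective[1:]):
            assert b <= a + 1e-10 * max(1.0, a)
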