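"""Fitting a scaffold's coordinate field to segmented specimen data.

The fit alternates two steps (iterated closest point with a linear core):

1. *Projection*: every segmentation data point is projected onto the
   scaffold — the nearest material point ``(element, xi)`` is found by
   seeding a coarse xi grid in each candidate element and polishing with a
   clamped Gauss-Newton iteration.  Points annotated with an anatomical term
   that names an annotation group only project onto that group's elements.
2. *Linear solve*: with the material coordinates frozen, the scaffold's
   nodal parameters minimise

       sum_i w_i ||x(xi_i; theta) - p_i||^2
         + lambda * sum_e int ||dx/dxi - dX/dxi||_F^2 dxi
         + beta   * sum_e int sum_{j<=k} ||d2(x - X)/dxi_j dxi_k||^2 dxi

   where ``X`` is the reference field.  The first penalty is a linearised
   strain measure (misfit of first derivatives against the reference
   state); the second is a Sobolev seminorm of the *displacement*, so both
   penalties vanish for any rigid translation of the reference.  Integrals
   use 3-point Gauss quadrature per direction and the problem is one sparse
   normal-equations solve per coordinate component; hard landmark
   constraints enter through Lagrange multipliers.

:func:`solve_linear_fit` implements exactly the objective above.  The outer
loop :func:`fit` defaults to two refinements that recover material
parameterisation, not just surface shape: an anisotropic point-to-plane
data metric (tangential motion of correspondences is down-weighted, so it
is governed by the penalties instead of by stale correspondences) and a
corotational strain linearisation (the reference derivative frame is
rotated by the polar factor of the current deformation gradient before the
misfit is measured, approximating rotation-invariant tissue strain).  Set
``FitConfig(data_term="point", strain_mode="reference")`` for the plain
formulation, whose total objective is guaranteed non-increasing across
outer iterations.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field as dataclass_field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .hermite import (
    GAUSS3_W,
    GAUSS3_X,
    MaterialPoint,
    Mesh,
    MeshError,
    eval_field,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Projection",
    "FitConfig",
    "FitDiagnostics",
    "FitError",
    "project_point",
    "project_points",
    "project_dataset",
    "solve_linear_fit",
    "fit",
]


class FitError(RuntimeError):
    """Numerical failure during fitting."""


# ---------------------------------------------------------------------------
# batched Hermite evaluation over element parameter blocks
# ---------------------------------------------------------------------------


def flat_weights(xis: np.ndarray, deriv: Sequence[int]) -> np.ndarray:
    """Weights for a batch of xi, flattened over (corner, slot).

    ``xis`` is (N, d); returns (N, 4**d) with flat index
    ``corner * 2**d + slot`` matching :func:`flat_params`.
    """
    xis = np.atleast_2d(np.asarray(xis, dtype=float))
    n, d = xis.shape
    b = []
    for i in range(d):
        coeffs = _deriv_coeffs(deriv[i] if deriv else 0)
        powers = xis[:, i : i + 1] ** np.arange(coeffs.shape[1])
        b.append(powers @ coeffs.T)  # (N, 4): H00, H10, H01, H11
    n_cs = 2**d
    out = np.ones((n, n_cs * n_cs))
    for c in range(n_cs):
        for s in range(n_cs):
            w = np.ones(n)
            for i in range(d):
                w = w * b[i][:, 2 * ((c >> i) & 1) + ((s >> i) & 1)]
            out[:, c * n_cs + s] = w
    return out


def _deriv_coeffs(k: int) -> np.ndarray:
    from .hermite import _HERMITE_COEFFS

    coeffs = _HERMITE_COEFFS
    for _ in range(int(k)):
        coeffs = coeffs[:, 1:] * np.arange(1, coeffs.shape[1])
    if coeffs.shape[1] < 4:
        coeffs = np.pad(coeffs, ((0, 0), (0, 4 - coeffs.shape[1])))
    return coeffs


def flat_params(mesh: Mesh, element_id: int, field: str) -> np.ndarray:
    """Element nodal parameters flattened to (ncomp, 4**d), corner-major."""
    e = mesh.elements[element_id]
    p = mesh.element_params(e, field)  # (corners, ncomp, slots)
    return np.transpose(p, (1, 0, 2)).reshape(p.shape[1], -1)


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------


@dataclass
class Projection:
    """Closest material point of one datum, with its fit weight."""

    data_index: int
    mp: MaterialPoint
    distance: float
    weight: float = 1.0
    point: Optional[np.ndarray] = None  # the datum itself (target, mm)


_SEED_1D = (1.0 / 6.0, 0.5, 5.0 / 6.0)


def _seed_grid(d: int) -> np.ndarray:
    return np.array(list(itertools.product(*[_SEED_1D] * d)))[:, ::-1].copy()


def _newton_polish(
    P: np.ndarray, pts: np.ndarray, xi0: np.ndarray, d: int,
    max_iter: int = 20, step_tol: float = 1e-10,
) -> Tuple[np.ndarray, np.ndarray]:
    """Clamped Gauss-Newton closest-point iteration, batched.

    ``P`` is (K, 3, 4**d) element parameters, ``pts`` (K, 3) the targets,
    ``xi0`` (K, d) the seeds.  A singular Gauss-Newton system falls back to
    a damped gradient step; steps that increase the distance are halved
    (never fails).  Returns (xi, squared distances).
    """
    xi = xi0.copy()
    w = flat_weights(xi, (0,) * d)
    x = np.einsum("kf,kcf->kc", w, P)
    r = x - pts
    d2 = np.einsum("kc,kc->k", r, r)
    eye = np.eye(d) * 1e-12
    for _ in range(max_iter):
        J = np.empty((xi.shape[0], 3, d))
        for i in range(d):
            dw = flat_weights(xi, tuple(1 if j == i else 0 for j in range(d)))
            J[:, :, i] = np.einsum("kf,kcf->kc", dw, P)
        g = np.einsum("kci,kc->ki", J, r)
        H = np.einsum("kci,kcj->kij", J, J) + eye
        # active-set reduction: at a bound with the gradient pushing
        # outward, freeze that coordinate so the step solves the reduced
        # problem in the remaining directions
        act = ((xi <= 1e-12) & (g > 0)) | ((xi >= 1 - 1e-12) & (g < 0))
        if np.any(act):
            g = np.where(act, 0.0, g)
            for i in range(d):
                ai = act[:, i]
                if np.any(ai):
                    H[ai, i, :] = 0.0
                    H[ai, :, i] = 0.0
                    H[ai, i, i] = 1.0
        try:
            step = -np.linalg.solve(H, g[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = -g
        bad = ~np.all(np.isfinite(step), axis=1)
        if np.any(bad):
            step[bad] = -g[bad]
        # backtracking line search with clamping to [0,1]^d
        alpha = np.ones(xi.shape[0])
        xi_new = xi.copy()
        d2_new = d2.copy()
        active = np.ones(xi.shape[0], dtype=bool)
        for _bt in range(10):
            trial = np.clip(xi + alpha[:, None] * step, 0.0, 1.0)
            wt = flat_weights(trial, (0,) * d)
            xt = np.einsum("kf,kcf->kc", wt, P)
            rt = xt - pts
            d2t = np.einsum("kc,kc->k", rt, rt)
            improve = active & (d2t <= d2 + 1e-16)
            xi_new[improve] = trial[improve]
            d2_new[improve] = d2t[improve]
            active = active & ~improve
            if not np.any(active):
                break
            alpha[active] *= 0.5
        moved = np.linalg.norm(xi_new - xi, axis=1)
        xi = xi_new
        d2 = d2_new
        if np.all(moved < step_tol):
            break
        w = flat_weights(xi, (0,) * d)
        x = np.einsum("kf,kcf->kc", w, P)
        r = x - pts
    return xi, d2


def project_points(
    mesh: Mesh,
    field: str,
    points: np.ndarray,
    elements: Optional[Iterable[int]] = None,
    polish_all: bool = False,
) -> List[Tuple[MaterialPoint, float]]:
    """Closest material point for each of a batch of 3D points.

    Candidate elements are seeded with a 3-per-direction xi grid; Newton
    polishing runs on every candidate whose best seed is competitive (within
    an element-diameter margin of the global best seed), or on every
    candidate when ``polish_all`` is set.  Ties (distance difference below
    1e-12) break to the lowest element id, then the lexicographically
    smallest xi.
    """
    if not mesh.elements:
        raise MeshError("mesh has no elements")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    eids = sorted(elements) if elements is not None else sorted(mesh.elements)
    if not eids:
        raise MeshError("empty candidate element set")
    by_dim: Dict[int, List[int]] = {}
    for eid in eids:
        by_dim.setdefault(mesh.elements[eid].dimension, []).append(eid)

    n = pts.shape[0]
    best: List[Optional[Tuple[float, int, Tuple[float, ...]]]] = [None] * n
    for d, eids_d in by_dim.items():
        seeds = _seed_grid(d)  # (S, d)
        Wg = flat_weights(seeds, (0,) * d)  # (S, F)
        P = np.stack([flat_params(mesh, eid, field) for eid in eids_d])  # (M,3,F)
        X = np.einsum("sf,mcf->msc", Wg, P)  # (M, S, 3)
        # element diameter estimate from corner spread
        corners = P[:, :, :: 2**d]  # value slots, (M, 3, corners)
        diam = np.linalg.norm(
            corners.max(axis=2) - corners.min(axis=2), axis=1
        )  # (M,)
        chunk = max(1, int(4e6 // max(X.shape[0] * X.shape[1], 1)))
        for c0 in range(0, n, chunk):
            sub = slice(c0, min(c0 + chunk, n))
            diff = X[None, :, :, :] - pts[sub, None, None, :]  # (n', M, S, 3)
            d2 = np.einsum("nmsc,nmsc->nms", diff, diff)
            seed_best = d2.min(axis=2)  # (n', M)
            seed_arg = d2.argmin(axis=2)
            gbest = seed_best.min(axis=1)  # (n',)
            if polish_all:
                mask = np.ones_like(seed_best, dtype=bool)
            else:
                mask = (
                    seed_best
                    <= (np.sqrt(gbest)[:, None] + 0.35 * diam[None, :]) ** 2 + 1e-30
                )
            pi, mi = np.nonzero(mask)
            if pi.size == 0:
                continue
            # polish from the best few seeds per candidate: on curved
            # elements the single best seed's basin can miss the optimum
            order = np.argsort(d2[pi, mi], axis=1)
            for rank in range(min(3, order.shape[1])):
                xi0 = seeds[order[:, rank]]
                xi, dist2 = _newton_polish(P[mi], pts[sub][pi], xi0, d)
                for k in range(pi.size):
                    cand = (float(np.sqrt(max(dist2[k], 0.0))), eids_d[mi[k]],
                            tuple(np.round(np.clip(xi[k], 0.0, 1.0), 15)))
                    cur = best[c0 + pi[k]]
                    if cur is None or cand[0] < cur[0] - 1e-12 or (
                        abs(cand[0] - cur[0]) <= 1e-12 and cand[1:] < cur[1:]
                    ):
                        best[c0 + pi[k]] = cand
    out = []
    for k in range(n):
        dist, eid, xi = best[k]  # type: ignore[misc]
        out.append((MaterialPoint(eid, xi), dist))
    return out


def project_point(
    mesh: Mesh,
    field: str,
    point: Sequence[float],
    elements: Optional[Iterable[int]] = None,
) -> Projection:
    """Project a single 3D point onto the nearest element of the mesh."""
    [(mp, dist)] = project_points(
        mesh, field, np.asarray(point, dtype=float)[None, :],
        elements=elements, polish_all=True,
    )
    return Projection(data_index=0, mp=mp, distance=dist,
                      point=np.asarray(point, dtype=float))


def project_dataset(mesh: Mesh, field: str, data, config: "FitConfig") -> List[Projection]:
    """Project every contour/marker point of a dataset onto the scaffold.

    Points whose anatomical term matches an annotation group are restricted
    to that group's elements; unmatched terms project against the whole mesh
    (logged once per term).
    """
    points, terms = data.all_points()
    if len(points) == 0:
        raise MeshError("empty dataset: nothing to project")
    group_elements: Dict[str, Set[int]] = {}
    for g in mesh.groups:
        if g.elements:
            group_elements.setdefault(g.term, set()).update(g.elements)
            if g.abbrev:
                group_elements.setdefault(g.abbrev, set()).update(g.elements)
    by_term: Dict[Optional[str], List[int]] = {}
    unmatched: Set[str] = set()
    for i, term in enumerate(terms):
        key = term if term in group_elements else None
        if key is None and term:
            unmatched.add(term)
        by_term.setdefault(key, []).append(i)
    for term in sorted(unmatched):
        logger.warning("term %r matches no annotation group; projecting on whole mesh", term)
    projections: List[Optional[Projection]] = [None] * len(points)
    for key, idxs in by_term.items():
        cands = group_elements[key] if key is not None else None
        res = project_points(mesh, field, points[idxs], elements=cands)
        for i, (mp, dist) in zip(idxs, res):
            w = config.group_weights.get(terms[i], 1.0)
            projections[i] = Projection(
                data_index=i, mp=mp, distance=dist, weight=w, point=points[i]
            )
    return [p for p in projections if p is not None]


# ---------------------------------------------------------------------------
# linear solve
# ---------------------------------------------------------------------------


@dataclass
class FitConfig:
    """Weights, penalties and schedule for scaffold fitting."""

    group_weights: Dict[str, float] = dataclass_field(default_factory=dict)
    lambda_strain: float = 0.01
    beta_smooth: float = 0.001
    outer_iterations: int = 12
    rms_tol: float = 1e-6  # mm
    fixed_landmarks: List[Tuple[MaterialPoint, Sequence[float]]] = dataclass_field(
        default_factory=list
    )
    free_nodes: Optional[Set[int]] = None  # None = all nodes free
    free_slots: Optional[Set[int]] = None  # None = all parameter slots free
    # "surface": anisotropic point-to-plane data term (distance to the moving
    # surface; tangential component down-weighted by tangent_weight), the
    # default for fit() — it avoids the tangential-sliding stall of frozen
    # point-to-point correspondences so material coordinates are recovered,
    # not just the surface shape.  "point": isotropic point-to-point.
    data_term: str = "surface"
    tangent_weight: float = 0.05
    # "corotational": the strain penalty measures first derivatives against
    # the locally *rotated* reference frame (polar decomposition of the
    # current deformation gradient, re-linearised each outer iteration), an
    # approximation of true rotation-invariant tissue strain.  "reference":
    # plain misfit against the reference derivatives (fully linear, biased
    # for large rotations).
    strain_mode: str = "corotational"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lambda_strain) and self.lambda_strain >= 0):
            raise ValueError("lambda_strain must be finite and >= 0")
        if not (np.isfinite(self.beta_smooth) and self.beta_smooth >= 0):
            raise ValueError("beta_smooth must be finite and >= 0")
        if self.data_term not in ("surface", "point"):
            raise ValueError("data_term must be 'surface' or 'point'")
        if self.strain_mode not in ("corotational", "reference"):
            raise ValueError("strain_mode must be 'corotational' or 'reference'")
        if not 0.0 < self.tangent_weight <= 1.0:
            raise ValueError("tangent_weight must be in (0, 1]")


@dataclass
class FitDiagnostics:
    """Per-iteration trace of a fit."""

    rms: List[float] = dataclass_field(default_factory=list)
    objective: List[float] = dataclass_field(default_factory=list)
    group_rms: Dict[str, float] = dataclass_field(default_factory=dict)
    converged: bool = False


class _DofMap:
    """Scalar degrees of freedom: one per (node, version, slot) actually
    referenced by an element, shared across coordinate components."""

    def __init__(self, mesh: Mesh, config: FitConfig):
        self.index: Dict[Tuple[int, int, int], int] = {}
        self.free: List[bool] = []
        keys = set()
        for e in mesh.elements.values():
            nslots = 2**e.dimension
            for nid, ver in zip(e.nodes, e.versions):
                for s in range(nslots):
                    keys.add((nid, ver, s))
        for key in sorted(keys):
            nid, _ver, slot = key
            free = True
            if config.free_nodes is not None and nid not in config.free_nodes:
                free = False
            if config.free_slots is not None and slot not in config.free_slots:
                free = False
            self.index[key] = len(self.free)
            self.free.append(free)
        self.n = len(self.free)
        self.free_mask = np.array(self.free, dtype=bool)

    def element_cols(self, mesh: Mesh, eid: int) -> np.ndarray:
        e = mesh.elements[eid]
        nslots = 2**e.dimension
        cols = np.empty(len(e.nodes) * nslots, dtype=int)
        k = 0
        for nid, ver in zip(e.nodes, e.versions):
            for s in range(nslots):
                cols[k] = self.index[(nid, ver, s)]
                k += 1
        return cols

    def gather(self, mesh: Mesh, field: str, ncomp: int) -> np.ndarray:
        theta = np.zeros((self.n, ncomp))
        for (nid, ver, slot), j in self.index.items():
            theta[j] = mesh.nodes[nid].version(field, ver)[:, slot]
        return theta

    def scatter(self, mesh: Mesh, field: str, theta: np.ndarray) -> None:
        for (nid, ver, slot), j in self.index.items():
            mesh.nodes[nid].version(field, ver)[:, slot] = theta[j]


def _quad_rows(mesh: Mesh, dofs: _DofMap, specs_by_dim: Dict[int, List[Tuple[Tuple[int, ...], float]]]):
    """Sparse rows of derivative evaluations at Gauss points for penalty
    terms: returns a CSR matrix G with sqrt(quadrature weight * term weight)
    folded in, so the penalty is ||G (theta - theta_ref)||^2 per component."""
    rows_i: List[np.ndarray] = []
    cols_i: List[np.ndarray] = []
    vals_i: List[np.ndarray] = []
    row = 0
    wt_cache: Dict[Tuple[int, Tuple[int, ...]], Tuple[np.ndarray, np.ndarray]] = {}
    for eid in sorted(mesh.elements):
        e = mesh.elements[eid]
        d = e.dimension
        specs = specs_by_dim.get(d)
        if not specs:
            continue
        cols = dofs.element_cols(mesh, eid)
        for deriv, term_w in specs:
            key = (d, deriv)
            if key not in wt_cache:
                qpts = np.array(list(itertools.product(*[GAUSS3_X] * d)))[:, ::-1]
                qw = np.array(
                    [np.prod(ws) for ws in itertools.product(*[GAUSS3_W] * d)]
                )
                wt_cache[key] = (flat_weights(qpts, deriv), qw)
            W, qw = wt_cache[key]
            scale = np.sqrt(qw * term_w)[:, None]
            nq, nf = W.shape
            rows_i.append(np.repeat(np.arange(row, row + nq), nf))
            cols_i.append(np.tile(cols, nq))
            vals_i.append((W * scale).ravel())
            row += nq
    if row == 0:
        return sp.csr_matrix((0, dofs.n))
    return sp.csr_matrix(
        (np.concatenate(vals_i), (np.concatenate(rows_i), np.concatenate(cols_i))),
        shape=(row, dofs.n),
    )


def _strain_specs(d: int):
    return [(tuple(1 if j == i else 0 for j in range(d)), 1.0) for i in range(d)]


def _smooth_specs(d: int):
    specs = []
    for j in range(d):
        for k in range(j, d):
            deriv = [0] * d
            deriv[j] += 1
            deriv[k] += 1
            specs.append((tuple(deriv), 1.0 if j == k else 2.0))
    return specs


def _strain_targets(
    mesh: Mesh,
    dofs: _DofMap,
    theta_ref: np.ndarray,
    theta_cur: Optional[np.ndarray],
    corotational: bool,
) -> np.ndarray:
    """Per-row targets for the strain penalty ``||Gs theta - b||^2``.

    Reference mode: ``b = Gs theta_ref`` (derivatives of the reference).
    Corotational mode: at each quadrature point the reference derivative
    frame is rotated by the polar factor of the current deformation
    gradient, so pure local rotations are not penalised.  Row order matches
    :func:`_quad_rows` with the strain derivative specs.
    """
    rows: List[np.ndarray] = []
    wt_cache: Dict[Tuple[int, Tuple[int, ...]], np.ndarray] = {}
    for eid in sorted(mesh.elements):
        e = mesh.elements[eid]
        d = e.dimension
        cols = dofs.element_cols(mesh, eid)
        qpts = np.array(list(itertools.product(*[GAUSS3_X] * d)))[:, ::-1]
        qw = np.array([np.prod(ws) for ws in itertools.product(*[GAUSS3_W] * d)])
        Ws = []
        for deriv, _tw in _strain_specs(d):
            key = (d, deriv)
            if key not in wt_cache:
                wt_cache[key] = flat_weights(qpts, deriv)
            Ws.append(wt_cache[key])
        # derivative columns at all quad points: (nq, d, ncomp)
        Jref = np.stack([W @ theta_ref[cols] for W in Ws], axis=1)
        if corotational and theta_cur is not None:
            Jcur = np.stack([W @ theta_cur[cols] for W in Ws], axis=1)
            # Kabsch rotation aligning reference to current frame per point
            M = np.einsum("qdc,qde->qce", Jcur, Jref)  # (nq, 3, 3)
            U, _S, Vt = np.linalg.svd(M)
            det = np.linalg.det(np.einsum("qab,qbc->qac", U, Vt))
            D = np.repeat(np.eye(3)[None], len(det), axis=0)
            D[:, 2, 2] = np.sign(det)
            R = np.einsum("qab,qbc,qcd->qad", U, D, Vt)
            target = np.einsum("qce,qde->qdc", R, Jref)  # rotated reference
        else:
            target = Jref
        scale = np.sqrt(qw)
        for k in range(d):
            rows.append(target[:, k, :] * scale[:, None])
    return np.vstack(rows) if rows else np.zeros((0, theta_ref.shape[1]))


def solve_linear_fit(
    mesh: Mesh,
    field: str,
    projections: Sequence[Projection],
    config: FitConfig,
    reference_field: str = "coordinates",
) -> Mesh:
    """One regularised linear least-squares update of the nodal parameters.

    Material coordinates of the projections are frozen; the updated field is
    written in place on ``mesh`` (which is returned).  Raises
    :class:`FitError` when the system is singular (insufficient data with
    zero penalties).
    """
    mesh, _obj = _solve_point_fit(mesh, field, projections, config, reference_field)
    return mesh


def _solve_point_fit(
    mesh: Mesh,
    field: str,
    projections: Sequence[Projection],
    config: FitConfig,
    reference_field: str = "coordinates",
) -> Tuple[Mesh, float]:
    ncomp = mesh.fields[field]
    dofs = _DofMap(mesh, config)
    theta = dofs.gather(mesh, field, ncomp)
    theta_ref = dofs.gather(mesh, reference_field, ncomp)

    # data rows
    rows_i, cols_i, vals_i = [], [], []
    targets = np.zeros((len(projections), ncomp))
    sqw = np.zeros(len(projections))
    for i, pr in enumerate(projections):
        if pr.point is None:
            raise FitError("projection carries no target point")
        e = mesh.elements[pr.mp.element_id]
        w = flat_weights(np.array([pr.mp.xi]), (0,) * e.dimension)[0]
        cols = dofs.element_cols(mesh, pr.mp.element_id)
        rows_i.append(np.full(cols.size, i))
        cols_i.append(cols)
        vals_i.append(w)
        targets[i] = np.asarray(pr.point, dtype=float)
        sqw[i] = np.sqrt(max(pr.weight, 0.0))
    A = sp.csr_matrix(
        (np.concatenate(vals_i), (np.concatenate(rows_i), np.concatenate(cols_i))),
        shape=(len(projections), dofs.n),
    )
    Aw = sp.diags(sqw) @ A

    dims = {e.dimension for e in mesh.elements.values()}
    Gs = _quad_rows(mesh, dofs, {d: _strain_specs(d) for d in dims})
    Gb = _quad_rows(mesh, dofs, {d: _smooth_specs(d) for d in dims})

    M = (Aw.T @ Aw).tocsc()
    bs = None
    if config.lambda_strain > 0:
        M = M + config.lambda_strain * (Gs.T @ Gs)
        bs = _strain_targets(
            mesh, dofs, theta_ref, theta, config.strain_mode == "corotational"
        )
    if config.beta_smooth > 0:
        M = M + config.beta_smooth * (Gb.T @ Gb)

    rhs = Aw.T @ (sp.diags(sqw) @ targets)
    if bs is not None:
        rhs = rhs + config.lambda_strain * (Gs.T @ bs)
    if config.beta_smooth > 0:
        rhs = rhs + config.beta_smooth * (Gb.T @ (Gb @ theta_ref))

    free = dofs.free_mask
    fixed = ~free
    if np.any(fixed):
        rhs = rhs - M[:, fixed] @ theta[fixed]
    Mff = M[free][:, free].tocsc()
    rhs_f = rhs[free]

    # hard landmark constraints via Lagrange multipliers
    cons = config.fixed_landmarks
    if cons:
        c_rows, c_cols, c_vals = [], [], []
        c_targets = np.zeros((len(cons), ncomp))
        free_idx = np.flatnonzero(free)
        remap = -np.ones(dofs.n, dtype=int)
        remap[free_idx] = np.arange(free_idx.size)
        for ci, (mp, target) in enumerate(cons):
            e = mesh.elements[mp.element_id]
            w = flat_weights(np.array([mp.xi]), (0,) * e.dimension)[0]
            cols = dofs.element_cols(mesh, mp.element_id)
            tgt = np.asarray(target, dtype=float)
            for c, v in zip(cols, w):
                if free[c]:
                    c_rows.append(ci)
                    c_cols.append(remap[c])
                    c_vals.append(v)
                else:
                    tgt = tgt - v * theta[c]
            c_targets[ci] = tgt
        C = sp.csr_matrix((c_vals, (c_rows, c_cols)), shape=(len(cons), free_idx.size))
        K = sp.bmat([[Mff, C.T], [C, None]], format="csc")
        big_rhs = np.vstack([rhs_f, c_targets])
    else:
        K = Mff
        big_rhs = rhs_f

    try:
        lu = spla.splu(K)
    except RuntimeError as exc:
        raise FitError(
            "singular fitting system (insufficient data with zero penalties); "
            "set lambda_strain/beta_smooth > 0"
        ) from exc
    sol = np.column_stack([lu.solve(big_rhs[:, c]) for c in range(ncomp)])
    for _ in range(2):  # iterative refinement (the normal matrix is ill-conditioned)
        resid = big_rhs - K @ sol
        sol = sol + np.column_stack([lu.solve(resid[:, c]) for c in range(ncomp)])
    if not np.all(np.isfinite(sol)):
        raise FitError(
            "fitting system produced non-finite parameters; "
            "set lambda_strain/beta_smooth > 0"
        )
    theta_new = theta.copy()
    theta_new[free] = sol[: int(free.sum())]
    dofs.scatter(mesh, field, theta_new)
    resid = A @ theta_new - targets
    obj = float(np.sum(sqw**2 * np.sum(resid**2, axis=1)))
    if bs is not None:
        obj += config.lambda_strain * float(np.sum((Gs @ theta_new - bs) ** 2))
    if config.beta_smooth > 0:
        obj += config.beta_smooth * float(
            np.sum((Gb @ (theta_new - theta_ref)) ** 2)
        )
    return mesh, obj


def _solve_surface_fit(
    mesh: Mesh,
    field: str,
    projections: Sequence[Projection],
    config: FitConfig,
    reference_field: str = "coordinates",
) -> Tuple[Mesh, float]:
    """Linear solve with an anisotropic (point-to-plane) data metric.

    Each datum contributes ``(x(xi_i) - p_i)^T W_i (x(xi_i) - p_i)`` with
    ``W_i = n n^T + tau^2 (I - n n^T)`` and ``n`` the unit residual
    direction at the frozen projection, so motion of the surface along the
    data normal is fully penalised while tangential re-parameterisation is
    governed mostly by the strain/smoothness penalties.  The three
    coordinate components couple, giving one sparse solve on the stacked
    system.
    """
    ncomp = mesh.fields[field]
    if ncomp != 3:
        raise FitError("surface data term requires a 3-component field")
    dofs = _DofMap(mesh, config)
    theta = dofs.gather(mesh, field, ncomp)
    theta_ref = dofs.gather(mesh, reference_field, ncomp)

    rows_i, cols_i, vals_i = [], [], []
    targets = np.zeros((len(projections), ncomp))
    weights = np.zeros(len(projections))
    metrics = np.zeros((len(projections), 3, 3))
    tau2 = config.tangent_weight**2
    eye = np.eye(3)
    for i, pr in enumerate(projections):
        if pr.point is None:
            raise FitError("projection carries no target point")
        e = mesh.elements[pr.mp.element_id]
        w = flat_weights(np.array([pr.mp.xi]), (0,) * e.dimension)[0]
        cols = dofs.element_cols(mesh, pr.mp.element_id)
        rows_i.append(np.full(cols.size, i))
        cols_i.append(cols)
        vals_i.append(w)
        p = np.asarray(pr.point, dtype=float)
        targets[i] = p
        weights[i] = max(pr.weight, 0.0)
        x = w @ theta[cols]
        r = p - x
        nrm = np.linalg.norm(r)
        if nrm > 1e-12:
            n = r / nrm
            metrics[i] = np.outer(n, n) + tau2 * (eye - np.outer(n, n))
        else:
            metrics[i] = tau2 * eye  # on-surface datum: tangential weight only
    A = sp.csr_matrix(
        (np.concatenate(vals_i), (np.concatenate(rows_i), np.concatenate(cols_i))),
        shape=(len(projections), dofs.n),
    )

    dims = {e.dimension for e in mesh.elements.values()}
    Gs = _quad_rows(mesh, dofs, {d: _strain_specs(d) for d in dims})
    Gb = _quad_rows(mesh, dofs, {d: _smooth_specs(d) for d in dims})
    P = config.lambda_strain * (Gs.T @ Gs) + config.beta_smooth * (Gb.T @ Gb)
    bs = _strain_targets(
        mesh, dofs, theta_ref, theta, config.strain_mode == "corotational"
    )
    P_rhs = config.lambda_strain * (Gs.T @ bs) + config.beta_smooth * (
        Gb.T @ (Gb @ theta_ref)
    )

    blocks = [[None] * 3 for _ in range(3)]
    rhs = np.zeros((3, dofs.n))
    for r in range(3):
        for c in range(3):
            D = sp.diags(weights * metrics[:, r, c])
            blk = (A.T @ D @ A).tocsc()
            if r == c:
                blk = blk + P
            blocks[r][c] = blk
            rhs[r] += A.T @ (D @ targets[:, c])
        rhs[r] += P_rhs[:, r]

    free = dofs.free_mask
    fixed = ~free
    nfree = int(free.sum())
    if np.any(fixed):
        for r in range(3):
            for c in range(3):
                rhs[r] = rhs[r] - blocks[r][c][:, fixed] @ theta[fixed, c]
    K = sp.bmat(
        [[blocks[r][c][free][:, free] for c in range(3)] for r in range(3)],
        format="csc",
    )
    big_rhs = np.concatenate([rhs[r][free] for r in range(3)])

    cons = config.fixed_landmarks
    if cons:
        free_idx = np.flatnonzero(free)
        remap = -np.ones(dofs.n, dtype=int)
        remap[free_idx] = np.arange(free_idx.size)
        c_rows, c_cols, c_vals = [], [], []
        c_targets = []
        ci = 0
        for mp, target in cons:
            e = mesh.elements[mp.element_id]
            w = flat_weights(np.array([mp.xi]), (0,) * e.dimension)[0]
            cols = dofs.element_cols(mesh, mp.element_id)
            tgt = np.asarray(target, dtype=float)
            for comp in range(3):
                t = tgt[comp]
                for col, v in zip(cols, w):
                    if free[col]:
                        c_rows.append(ci)
                        c_cols.append(comp * nfree + remap[col])
                        c_vals.append(v)
                    else:
                        t -= v * theta[col, comp]
                c_targets.append(t)
                ci += 1
        C = sp.csr_matrix((c_vals, (c_rows, c_cols)), shape=(ci, 3 * nfree))
        K = sp.bmat([[K, C.T], [C, None]], format="csc")
        big_rhs = np.concatenate([big_rhs, np.array(c_targets)])

    try:
        lu = spla.splu(K)
    except RuntimeError as exc:
        raise FitError(
            "singular fitting system; set lambda_strain/beta_smooth > 0"
        ) from exc
    sol = lu.solve(big_rhs)
    for _ in range(2):
        sol = sol + lu.solve(big_rhs - K @ sol)
    if not np.all(np.isfinite(sol)):
        raise FitError("fitting system produced non-finite parameters")
    theta_new = theta.copy()
    for comp in range(3):
        theta_new[free, comp] = sol[comp * nfree : (comp + 1) * nfree]
    dofs.scatter(mesh, field, theta_new)
    resid = A @ theta_new - targets
    obj = float(np.einsum("n,nc,ncd,nd->", weights, resid, metrics, resid))
    obj += config.lambda_strain * float(np.sum((Gs @ theta_new - bs) ** 2))
    obj += config.beta_smooth * float(np.sum((Gb @ (theta_new - theta_ref)) ** 2))
    return mesh, obj


def fit(
    mesh: Mesh,
    data,
    config: Optional[FitConfig] = None,
    field: str = "coordinates",
) -> Tuple[Mesh, FitDiagnostics]:
    """Fit the scaffold to a contour dataset.

    The reference field is left untouched; the result is stored as field
    ``"fitted"`` on a copy of the mesh.  Outer iterations alternate
    projection and the linear solve until the RMS data distance changes by
    less than ``rms_tol`` or ``outer_iterations`` is reached.
    """
    config = config or FitConfig()
    fitted = mesh.copy()
    fitted.declare_field("fitted", fitted.fields[field])
    for n in fitted.nodes.values():
        if field in n.params:
            n.params["fitted"] = n.params[field].copy()

    diag = FitDiagnostics()
    prev_rms = None
    for _it in range(config.outer_iterations):
        projections = project_dataset(fitted, "fitted", data, config)
        rms = float(np.sqrt(np.mean([p.distance**2 for p in projections])))
        diag.rms.append(rms)
        if not np.isfinite(rms):
            raise FitError("non-finite RMS during fitting")
        if prev_rms is not None and abs(prev_rms - rms) < config.rms_tol:
            diag.converged = True
            break
        prev_rms = rms
        solver = (
            _solve_surface_fit if config.data_term == "surface" else _solve_point_fit
        )
        _, obj = solver(fitted, "fitted", projections, config, reference_field=field)
        if not np.isfinite(obj):
            raise FitError("non-finite objective during fitting")
        diag.objective.append(obj)

    # final projection pass: closing RMS and per-group RMS
    projections = project_dataset(fitted, "fitted", data, config)
    _, terms = data.all_points()
    by_group: Dict[str, List[float]] = {}
    for pr in projections:
        by_group.setdefault(terms[pr.data_index] or "(unannotated)", []).append(
            pr.distance**2
        )
    diag.group_rms = {
        g: float(np.sqrt(np.mean(v))) for g, v in sorted(by_group.items())
    }
    final_rms = float(np.sqrt(np.mean([p.distance**2 for p in projections])))
    diag.rms.append(final_rms)
    if not diag.converged and len(diag.rms) > 1:
        diag.converged = abs(diag.rms[-2] - diag.rms[-1]) < config.rms_tol
    return fitted, diag
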