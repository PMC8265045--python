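"""Synthetic ground-truth specimens for end-to-end validation.

Experimental preparations distort organs, so fitting and material embedding
must be validated against specimens whose true deformation and true cell
locations are known.  This module deforms a generated scaffold with smooth
*analytic* maps (affine, circular bend, Gaussian bulge) whose Jacobians and
higher derivatives are exact — nodal derivative parameters are updated by
the chain rule, never by numerical differentiation — then samples noisy
contour rings from its surfaces and plants labelled cells at known material
points.  Recovery metrics compare embedded/transferred points against the
planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .hermite import MaterialPoint, Mesh, MeshError, check_jacobians, eval_field
from .io import Contour, ContourDataset
from .embedding import EmbeddedPoint

__all__ = [
    "Deformation",
    "Affine",
    "Bend",
    "Bulge",
    "Composite",
    "DeformationSpec",
    "SyntheticSpecimen",
    "Cell",
    "RegistrationMetrics",
    "deform_mesh",
    "sample_contours",
    "scatter_cells",
    "registration_error",
    "make_specimen",
]


# ---------------------------------------------------------------------------
# analytic deformations (value, Jacobian, Hessian, third derivative)
# ---------------------------------------------------------------------------


class Deformation:
    """Smooth map phi: R^3 -> R^3 with exact derivatives up to third order.

    ``jac(p)[i, j] = d phi_i / d p_j``; ``hess(p)[i, j, k]`` and
    ``third(p)[i, j, k, l]`` continue the pattern.
    """

    def value(self, p: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def jac(self, p: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def hess(self, p: np.ndarray) -> np.ndarray:
        return np.zeros((3, 3, 3))

    def third(self, p: np.ndarray) -> np.ndarray:
        return np.zeros((3, 3, 3, 3))


class Affine(Deformation):
    def __init__(self, matrix=None, offset=(0.0, 0.0, 0.0)):
        self.A = np.eye(3) if matrix is None else np.asarray(matrix, dtype=float)
        self.b = np.asarray(offset, dtype=float)

    def value(self, p):
        return self.A @ p + self.b

    def jac(self, p):
        return self.A.copy()


class Bend(Deformation):
    """Circular bend of the z axis about the y axis, centred on ``center``.

    A point (x, y, z) relative to the centre maps to
    ((r + x) cos(kz) - r, y, (r + x) sin(kz)) with bend radius r = 1/k, so
    the centre plane z = 0 is fixed and curvature k -> 0 recovers the
    identity.  The Jacobian determinant is 1 + k x, positive while |x| < r.
    """

    def __init__(self, curvature: float, center=(0.0, 0.0, 0.0)):
        if curvature <= 0:
            raise ValueError("curvature must be positive")
        self.k = float(curvature)
        self.c = np.asarray(center, dtype=float)

    def _parts(self, p):
        u = p - self.c
        x, z = u[0], u[2]
        k = self.k
        return u, x, k, np.sin(k * z), np.cos(k * z), 1.0 / k + x

    def value(self, p):
        u, x, k, s, c, a = self._parts(p)
        return self.c + np.array([a * c - 1.0 / k, u[1], a * s])

    def jac(self, p):
        _, x, k, s, c, a = self._parts(p)
        return np.array(
            [[c, 0.0, -a * k * s], [0.0, 1.0, 0.0], [s, 0.0, a * k * c]]
        )

    def hess(self, p):
        _, x, k, s, c, a = self._parts(p)
        H = np.zeros((3, 3, 3))
        H[0, 0, 2] = H[0, 2, 0] = -k * s
        H[0, 2, 2] = -a * k * k * c
        H[2, 0, 2] = H[2, 2, 0] = k * c
        H[2, 2, 2] = -a * k * k * s
        return H

    def third(self, p):
        _, x, k, s, c, a = self._parts(p)
        T = np.zeros((3, 3, 3, 3))
        k2, k3 = k * k, k**3
        # d3 / dx dz dz (all orderings)
        for perm in ((0, 2, 2), (2, 0, 2), (2, 2, 0)):
            T[(0,) + perm] = -k2 * c
            T[(2,) + perm] = -k2 * s
        T[0, 2, 2, 2] = a * k3 * s
        T[2, 2, 2, 2] = -a * k3 * c
        return T


class Bulge(Deformation):
    """Gaussian radial bulge: p -> p + amp * exp(-|p-c|^2 / (2 sigma^2)) (p-c)."""

    def __init__(self, amplitude: float, sigma: float, center=(0.0, 0.0, 0.0)):
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        self.a = float(amplitude)
        self.s2 = float(sigma) ** 2
        self.c = np.asarray(center, dtype=float)

    def _f(self, u):
        return self.a * np.exp(-float(u @ u) / (2.0 * self.s2))

    def value(self, p):
        u = p - self.c
        return p + self._f(u) * u

    def jac(self, p):
        u = p - self.c
        f = self._f(u)
        grad = -f * u / self.s2  # df/du
        return np.eye(3) * (1.0 + f) + np.outer(u, grad)

    def hess(self, p):
        u = p - self.c
        f = self._f(u)
        fj = -f * u / self.s2
        fjk = f * (np.outer(u, u) / self.s2**2 - np.eye(3) / self.s2)
        H = np.zeros((3, 3, 3))
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    H[i, j, k] = (
                        (i == j) * fj[k] + (i == k) * fj[j] + u[i] * fjk[j, k]
                    )
        return H

    def third(self, p):
        u = p - self.c
        f = self._f(u)
        fj = -f * u / self.s2
        fjk = f * (np.outer(u, u) / self.s2**2 - np.eye(3) / self.s2)
        T = np.zeros((3, 3, 3, 3))
        for j in range(3):
            for k in range(3):
                for l in range(3):
                    # f_{jkl}
                    val = fj[l] * (u[j] * u[k] / self.s2**2 - (j == k) / self.s2)
                    val += f * ((j == l) * u[k] + (k == l) * u[j]) / self.s2**2
                    for i in range(3):
                        T[i, j, k, l] = (
                            (i == j) * fjk[k, l]
                            + (i == k) * fjk[j, l]
                            + (i == l) * fjk[j, k]
                            + u[i] * val
                        )
        return T


class Composite(Deformation):
    """Sequential composition phi = phi_n o ... o phi_1 (chain rule exact)."""

    def __init__(self, parts: Sequence[Deformation]):
        self.parts = list(parts)

    def value(self, p):
        for d in self.parts:
            p = d.value(p)
        return p

    def jac(self, p):
        J = np.eye(3)
        for d in self.parts:
            J = d.jac(p) @ J
            p = d.value(p)
        return J

    def hess(self, p):
        # H_{ijk} of the composition via Faa di Bruno (second order)
        J = np.eye(3)
        H = np.zeros((3, 3, 3))
        for d in self.parts:
            Jd, Hd = d.jac(p), d.hess(p)
            H = np.einsum("ia,ajk->ijk", Jd, H) + np.einsum(
                "iab,aj,bk->ijk", Hd, J, J
            )
            J = Jd @ J
            p = d.value(p)
        return H

    def third(self, p):
        J = np.eye(3)
        H = np.zeros((3, 3, 3))
        T = np.zeros((3, 3, 3, 3))
        for d in self.parts:
            Jd, Hd, Td = d.jac(p), d.hess(p), d.third(p)
            T = (
                np.einsum("ia,ajkl->ijkl", Jd, T)
                + np.einsum("iab,aj,bkl->ijkl", Hd, J, H)
                + np.einsum("iab,ajk,bl->ijkl", Hd, H, J)
                + np.einsum("iab,ajl,bk->ijkl", Hd, H, J)
                + np.einsum("iabc,aj,bk,cl->ijkl", Td, J, J, J)
            )
            H = np.einsum("ia,ajk->ijk", Jd, H) + np.einsum(
                "iab,aj,bk->ijk", Hd, J, J
            )
            J = Jd @ J
            p = d.value(p)
        return T


@dataclass
class DeformationSpec:
    """Declarative deformation recipe for a synthetic specimen.

    ``mode`` is "affine", "bend", "bulge" or "composite" (bend then bulge);
    ``amplitude`` is a dimensionless fraction of the mesh size (bend: the
    bounding-box diagonal over the bend radius is ~8*amplitude at the mesh
    ends; bulge: peak relative displacement).  The rigid offset is applied
    last.  ``seed`` controls every stochastic step downstream.
    """

    mode: str = "bend"
    amplitude: float = 0.1
    offset: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    matrix: Optional[Sequence[Sequence[float]]] = None
    noise_sd: float = 0.0  # mm, contour sampling noise
    seed: int = 0

    def build(self, mesh: Mesh, field: str = "coordinates") -> Deformation:
        lo, hi = mesh.bounding_box(field)
        center = 0.5 * (lo + hi)
        diag = float(np.linalg.norm(hi - lo))
        parts: List[Deformation] = []
        if self.mode == "affine":
            parts.append(Affine(self.matrix, (0, 0, 0)))
        elif self.mode == "bend":
            curvature = 8.0 * self.amplitude / max(diag, 1e-12)
            parts.append(Bend(curvature, center))
        elif self.mode == "bulge":
            parts.append(
                Bulge(self.amplitude, sigma=0.35 * diag, center=center)
            )
        elif self.mode == "composite":
            curvature = 8.0 * self.amplitude / max(diag, 1e-12)
            parts.append(Bend(curvature, center))
            parts.append(Bulge(0.5 * self.amplitude, sigma=0.35 * diag, center=center))
        else:
            raise ValueError(f"unknown deformation mode {self.mode!r}")
        if any(self.offset):
            parts.append(Affine(None, self.offset))
        return parts[0] if len(parts) == 1 else Composite(parts)


# ---------------------------------------------------------------------------
# specimen construction
# ---------------------------------------------------------------------------


def deform_mesh(
    mesh: Mesh,
    deformation,
    field: str = "coordinates",
) -> Mesh:
    """Apply an analytic deformation to all nodal parameters of a field.

    Values map through the deformation; first-derivative slots through the
    Jacobian; cross-derivative slots pick up the exact Hessian/third-order
    chain-rule terms.  The deformed mesh's Jacobians are verified positive;
    a violation raises with a hint to reduce the deformation amplitude.
    """
    if isinstance(deformation, DeformationSpec):
        deformation = deformation.build(mesh, field)
    out = mesh.copy()
    for node in out.nodes.values():
        blk = node.params.get(field)
        if blk is None:
            continue
        for ver in range(blk.shape[0]):
            v = blk[ver, :, 0].copy()
            d = [blk[ver, :, 1].copy(), blk[ver, :, 2].copy(), blk[ver, :, 4].copy()]
            d12 = blk[ver, :, 3].copy()
            d13 = blk[ver, :, 5].copy()
            d23 = blk[ver, :, 6].copy()
            d123 = blk[ver, :, 7].copy()
            J = deformation.jac(v)
            H = deformation.hess(v)
            T = deformation.third(v)
            blk[ver, :, 0] = deformation.value(v)
            blk[ver, :, 1] = J @ d[0]
            blk[ver, :, 2] = J @ d[1]
            blk[ver, :, 4] = J @ d[2]
            blk[ver, :, 3] = J @ d12 + np.einsum("ijk,j,k->i", H, d[0], d[1])
            blk[ver, :, 5] = J @ d13 + np.einsum("ijk,j,k->i", H, d[0], d[2])
            blk[ver, :, 6] = J @ d23 + np.einsum("ijk,j,k->i", H, d[1], d[2])
            blk[ver, :, 7] = (
                J @ d123
                + np.einsum("ijk,j,k->i", H, d[0], d23)
                + np.einsum("ijk,j,k->i", H, d[1], d13)
                + np.einsum("ijk,j,k->i", H, d[2], d12)
                + np.einsum("ijkl,j,k,l->i", T, d[0], d[1], d[2])
            )
    try:
        check_jacobians(out, field)
    except MeshError as exc:
        raise MeshError(
            f"deformation produces inverted elements ({exc}); reduce the "
            "deformation amplitude"
        ) from exc
    return out


def sample_contours(
    truth_mesh: Mesh,
    rings_per_element: int = 2,
    points_per_ring: int = 8,
    noise_sd: float = 0.0,
    seed: int = 0,
    groups: Optional[Sequence[str]] = None,
    field: str = "coordinates",
) -> ContourDataset:
    """Sample noisy contour rings from the surfaces of a truth mesh.

    Rings lie at fixed xi levels on each face of the chosen surface
    annotation groups (default: "outer surface" if present, else every
    region group that carries faces); each sampled point gets isotropic
    Gaussian noise of standard deviation ``noise_sd`` mm.
    """
    if groups is None:
        if any(g.term == "outer surface" for g in truth_mesh.groups):
            chosen = [g for g in truth_mesh.groups if g.term == "outer surface"]
        else:
            chosen = [g for g in truth_mesh.groups if g.faces and g.kind == "region"]
    else:
        chosen = [truth_mesh.group(t) for t in groups]
    chosen = [g for g in chosen if g.faces]
    if not chosen:
        raise MeshError("no surface annotation group with faces to sample")
    rng = np.random.default_rng(seed)
    ds = ContourDataset(source="synthetic", units="mm")
    for g in chosen:
        for eid, axis, side in sorted(g.faces):
            e = truth_mesh.elements[eid]
            d = e.dimension
            free = [i for i in range(d) if i != axis - 1]
            for ring in range(rings_per_element):
                level = (ring + 0.5) / rings_per_element
                pts = []
                for j in range(points_per_ring):
                    u = (j + 0.5) / points_per_ring
                    xi = [0.0] * d
                    xi[axis - 1] = float(side)
                    xi[free[0]] = u
                    if len(free) > 1:
                        xi[free[1]] = level
                    pts.append(eval_field(truth_mesh, field, MaterialPoint(eid, xi)))
                pts = np.asarray(pts)
                if noise_sd > 0:
                    pts = pts + rng.normal(0.0, noise_sd, size=pts.shape)
                ds.contours.append(
                    Contour(term=g.term, ontology_id=g.ontology_id,
                            closed=False, points=pts)
                )
    return ds


@dataclass
class Cell:
    """A planted cell: its true material point and observed 3D position."""

    label: str
    term: str
    mp: MaterialPoint
    observed: np.ndarray  # mm, truth-field evaluation (+ recorded noise)


def scatter_cells(
    truth_mesh: Mesh,
    n: int,
    seed: int = 0,
    groups: Optional[Sequence[str]] = None,
    noise_sd: float = 0.0,
    field: str = "coordinates",
) -> List[Cell]:
    """Plant ``n`` cells at material points drawn uniformly over
    (element, xi) within the filtered annotation groups (default: all
    3D elements)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if groups is None:
        eids = sorted(e.id for e in truth_mesh.elements.values() if e.dimension == 3)
        term_of = {eid: "" for eid in eids}
    else:
        eids = []
        term_of = {}
        for t in groups:
            g = truth_mesh.group(t)
            for eid in sorted(g.elements):
                if truth_mesh.elements[eid].dimension == 3:
                    eids.append(eid)
                    term_of[eid] = g.term
        eids = sorted(set(eids))
    if not eids:
        raise MeshError("cell group filter selects no 3D elements")
    rng = np.random.default_rng(seed)
    cells = []
    for i in range(n):
        eid = eids[int(rng.integers(len(eids)))]
        xi = tuple(rng.uniform(0.0, 1.0, size=3))
        mp = MaterialPoint(eid, xi)
        obs = eval_field(truth_mesh, field, mp)
        if noise_sd > 0:
            obs = obs + rng.normal(0.0, noise_sd, size=3)
        cells.append(Cell(label=f"cell_{i:04d}", term=term_of[eid], mp=mp, observed=obs))
    return cells


# ---------------------------------------------------------------------------
# recovery metrics
# ---------------------------------------------------------------------------


@dataclass
class RegistrationMetrics:
    xi_rms: float  # element-normalised xi units, same-element pairs
    physical_rms: float  # mm
    worst: float  # mm
    off_mesh_count: int
    n_pairs: int
    missing_labels: List[str] = dataclass_field(default_factory=list)


def registration_error(
    true_cells: Sequence[Cell],
    recovered: Sequence,
    mesh: Mesh,
    field: str = "coordinates",
) -> RegistrationMetrics:
    """Compare recovered points against planted truth in a common field.

    ``recovered`` holds :class:`EmbeddedPoint` items and/or ``(label,
    point)`` pairs; embedded points are evaluated in ``mesh``/``field``, as
    are the true material points, so both sides live in the same
    configuration.  Labels present on only one side are reported, never
    silently dropped.
    """
    true_by_label = {c.label: c for c in true_cells}
    rec_pos: Dict[str, np.ndarray] = {}
    rec_mp: Dict[str, MaterialPoint] = {}
    off_mesh = 0
    for item in recovered:
        if isinstance(item, EmbeddedPoint):
            rec_mp[item.label] = item.mp
            rec_pos[item.label] = eval_field(mesh, field, item.mp)
            off_mesh += int(item.off_mesh)
        else:
            label, point = item
            rec_pos[label] = np.asarray(point, dtype=float)
    matched = sorted(set(true_by_label) & set(rec_pos))
    missing = sorted(set(true_by_label) ^ set(rec_pos))
    if not matched:
        raise ValueError("no labels in common between truth and recovery")
    d2 = []
    xi2 = []
    for label in matched:
        truth = true_by_label[label]
        t_pos = eval_field(mesh, field, truth.mp)
        d2.append(float(np.sum((t_pos - rec_pos[label]) ** 2)))
        mp = rec_mp.get(label)
        if mp is not None and mp.element_id == truth.mp.element_id:
            xi2.append(float(np.sum((np.array(mp.xi) - np.array(truth.mp.xi)) ** 2)))
    return RegistrationMetrics(
        xi_rms=float(np.sqrt(np.mean(xi2))) if xi2 else float("nan"),
        physical_rms=float(np.sqrt(np.mean(d2))),
        worst=float(np.sqrt(np.max(d2))),
        off_mesh_count=off_mesh,
        n_pairs=len(matched),
        missing_labels=missing,
    )


# ---------------------------------------------------------------------------
# whole specimens
# ---------------------------------------------------------------------------


@dataclass
class SyntheticSpecimen:
    """Ground-truth synthetic specimen: generic scaffold, deformed truth,
    sampled contours and planted cells."""

    generic_mesh: Mesh
    truth_mesh: Mesh
    contours: ContourDataset
    cells: List[Cell]
    spec: DeformationSpec
    seed: int


def make_specimen(
    generic_mesh: Mesh,
    spec: DeformationSpec,
    n_cells: int = 50,
    rings_per_element: int = 2,
    points_per_ring: int = 6,
    cell_groups: Optional[Sequence[str]] = None,
    contour_groups: Optional[Sequence[str]] = None,
) -> SyntheticSpecimen:
    """Deform a generic scaffold and derive its observable synthetic data."""
    truth = deform_mesh(generic_mesh, spec)
    contours = sample_contours(
        truth,
        rings_per_element=rings_per_element,
        points_per_ring=points_per_ring,
        noise_sd=spec.noise_sd,
        seed=spec.seed,
        groups=contour_groups,
    )
    cells = scatter_cells(
        truth, n_cells, seed=spec.seed + 1, groups=cell_groups
    )
    return SyntheticSpecimen(
        generic_mesh=generic_mesh,
        truth_mesh=truth,
        contours=contours,
        cells=cells,
        spec=spec,
        seed=spec.seed,
    )
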