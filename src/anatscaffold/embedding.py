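"""Material embedding and transfer of point data; organ placement.

A cell digitised at a 3D position in one specimen is stored as a material
point ``(element, xi)`` of that specimen's fitted scaffold.  Because every
configuration of the scaffold evaluates the same material point, the cell
can then be mapped to the generic reference scaffold — or to any other
specimen fitted with the same mesh topology — giving a unique one-to-one
correspondence of tissue locations across specimens and species.

Organ scaffolds are placed inside a body scaffold by matching a small
number of fiducial landmarks (three suffice) with a least-squares
similarity transform (rotation + isotropic scale + translation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dataclass_field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .hermite import MaterialPoint, Mesh, MeshError, eval_field
from .fitting import flat_params, flat_weights, project_points, _seed_grid

logger = logging.getLogger(__name__)

__all__ = [
    "EmbeddedPoint",
    "SimilarityTransform",
    "embed_points",
    "transfer_points",
    "fiducial_transform",
    "place_organ",
]


@dataclass
class EmbeddedPoint:
    """A labelled datum stored as a material point of a scaffold."""

    label: str
    term: str
    mp: MaterialPoint
    residual: float  # mm, datum to embedded location
    off_mesh: bool = False
    ontology_id: str = ""


@dataclass
class SimilarityTransform:
    """x -> scale * R x + t with R a proper rotation."""

    scale: float
    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3) or np.max(np.abs(R.T @ R - np.eye(3))) > 1e-10:
            raise ValueError("rotation must be 3x3 orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper (det +1)")
        if not self.scale > 0:
            raise ValueError("scale must be positive")
        self.rotation = R
        self.translation = np.asarray(self.translation, dtype=float)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.scale * (np.asarray(points, dtype=float) @ self.rotation.T) + self.translation

    def apply_vector(self, vectors: np.ndarray) -> np.ndarray:
        return self.scale * (np.asarray(vectors, dtype=float) @ self.rotation.T)


# ---------------------------------------------------------------------------
# embedding
# ---------------------------------------------------------------------------


def _invert_in_elements(
    mesh: Mesh, field: str, pts: np.ndarray, eids: Sequence[int]
) -> List[Optional[Tuple[int, Tuple[float, ...], float]]]:
    """Newton-solve x(xi) = p inside candidate 3D elements (batched).

    Returns per point (element id, xi, residual) for the best interior
    solution, or None when no element inverts the point.
    """
    eids3 = [e for e in eids if mesh.elements[e].dimension == 3]
    if not eids3:
        return [None] * len(pts)
    seeds = _seed_grid(3)
    Wg = flat_weights(seeds, (0, 0, 0))
    P = np.stack([flat_params(mesh, e, field) for e in eids3])  # (M,3,F)
    X = np.einsum("sf,mcf->msc", Wg, P)
    diff = X[None] - pts[:, None, None, :]
    d2 = np.einsum("nmsc,nmsc->nms", diff, diff)
    results: List[Optional[Tuple[int, Tuple[float, ...], float]]] = [None] * len(pts)
    # polish the best few elements per point
    order = np.argsort(d2.min(axis=2), axis=1)
    k_try = min(4, len(eids3))
    for rank in range(k_try):
        mi = order[:, rank]
        xi = seeds[d2[np.arange(len(pts)), mi].argmin(axis=1)].copy()
        Pm = P[mi]
        for _ in range(30):
            w = flat_weights(xi, (0, 0, 0))
            x = np.einsum("kf,kcf->kc", w, Pm)
            r = x - pts
            J = np.empty((len(pts), 3, 3))
            for i in range(3):
                dw = flat_weights(xi, tuple(1 if j == i else 0 for j in range(3)))
                J[:, :, i] = np.einsum("kf,kcf->kc", dw, Pm)
            try:
                step = np.linalg.solve(J, -r[..., None])[..., 0]
            except np.linalg.LinAlgError:
                break
            step = np.clip(step, -0.5, 0.5)
            xi = xi + step
            if np.max(np.abs(step)) < 1e-12:
                break
        w = flat_weights(np.clip(xi, 0.0, 1.0), (0, 0, 0))
        x = np.einsum("kf,kcf->kc", w, Pm)
        res = np.linalg.norm(x - pts, axis=1)
        inside = np.all((xi > -1e-9) & (xi < 1 + 1e-9), axis=1)
        for n in range(len(pts)):
            if not inside[n]:
                continue
            cand = (eids3[mi[n]], tuple(np.clip(xi[n], 0.0, 1.0)), float(res[n]))
            cur = results[n]
            if cur is None or cand[2] < cur[2] - 1e-12 or (
                abs(cand[2] - cur[2]) <= 1e-12 and cand[:2] < cur[:2]
            ):
                results[n] = cand
    return results


def embed_points(
    mesh: Mesh,
    field: str,
    points: np.ndarray,
    terms: Optional[Sequence[str]] = None,
    labels: Optional[Sequence[str]] = None,
    mode: str = "surface",
    tolerance: Optional[float] = None,
) -> List[EmbeddedPoint]:
    """Embed 3D points as material points of the scaffold.

    ``surface`` mode projects each point onto the nearest element;
    ``volume`` mode inverts the coordinate field inside candidate elements
    and falls back to surface projection (with ``off_mesh`` set when the
    residual exceeds the tolerance, default 1e-6 of the bounding-box
    diagonal).  Points with a term matching an annotation group are
    restricted to that group's elements.
    """
    if mode not in ("surface", "volume"):
        raise ValueError(f"unknown embedding mode {mode!r}")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n = pts.shape[0]
    terms = list(terms) if terms is not None else [""] * n
    labels = list(labels) if labels is not None else [f"point_{i}" for i in range(n)]
    lo, hi = mesh.bounding_box(field)
    tol = tolerance if tolerance is not None else 1e-6 * float(np.linalg.norm(hi - lo))

    group_elements: Dict[str, Set[int]] = {}
    for g in mesh.groups:
        if g.elements:
            group_elements.setdefault(g.term, set()).update(g.elements)
            if g.abbrev:
                group_elements.setdefault(g.abbrev, set()).update(g.elements)

    out: List[Optional[EmbeddedPoint]] = [None] * n
    by_key: Dict[Optional[str], List[int]] = {}
    for i, t in enumerate(terms):
        by_key.setdefault(t if t in group_elements else None, []).append(i)

    for key, idxs in by_key.items():
        cands = sorted(group_elements[key]) if key is not None else sorted(mesh.elements)
        sub = pts[idxs]
        inverted: List[Optional[Tuple[int, Tuple[float, ...], float]]]
        if mode == "volume":
            inverted = _invert_in_elements(mesh, field, sub, cands)
        else:
            inverted = [None] * len(idxs)
        need_proj = [k for k, inv in enumerate(inverted) if inv is None or inv[2] > tol]
        projected = {}
        if need_proj:
            res = project_points(mesh, field, sub[need_proj], elements=cands)
            projected = dict(zip(need_proj, res))
        for k, i in enumerate(idxs):
            inv = inverted[k]
            if inv is not None and inv[2] <= tol:
                mp = MaterialPoint(inv[0], inv[1])
                residual = inv[2]
            else:
                mp, residual = projected[k]
            out[i] = EmbeddedPoint(
                label=labels[i],
                term=terms[i],
                mp=mp,
                residual=float(residual),
                off_mesh=bool(residual > tol),
            )
    return [e for e in out if e is not None]


def transfer_points(
    embedded: Sequence[EmbeddedPoint],
    target_mesh: Mesh,
    field: str = "coordinates",
) -> Tuple[List[Tuple[str, np.ndarray]], List[str]]:
    """Evaluate embedded material points in a target mesh/field.

    Returns (list of (label, 3D point), list of per-point error messages for
    material points whose element is missing from the target).
    """
    out: List[Tuple[str, np.ndarray]] = []
    errors: List[str] = []
    for ep in embedded:
        if ep.mp.element_id not in target_mesh.elements:
            errors.append(
                f"{ep.label}: element {ep.mp.element_id} missing from target mesh"
            )
            continue
        out.append((ep.label, eval_field(target_mesh, field, ep.mp)))
    return out, errors


# ---------------------------------------------------------------------------
# fiducial alignment
# ---------------------------------------------------------------------------


def fiducial_transform(
    src: np.ndarray, dst: np.ndarray, allow_reflection: bool = False
) -> Tuple[SimilarityTransform, float]:
    """Least-squares similarity transform mapping ``src`` onto ``dst``.

    Umeyama's closed-form solution of min_{s,R,t} sum ||s R a_i + t - b_i||^2
    over >= 3 non-collinear point pairs; returns the transform and the RMS
    residual (mm).
    """
    a = np.atleast_2d(np.asarray(src, dtype=float))
    b = np.atleast_2d(np.asarray(dst, dtype=float))
    if a.shape != b.shape or a.shape[0] < 3 or a.shape[1] != 3:
        raise ValueError("need >= 3 matched 3D point pairs")
    mu_a, mu_b = a.mean(axis=0), b.mean(axis=0)
    A0, B0 = a - mu_a, b - mu_b
    sv = np.linalg.svd(A0, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1e-30):
        raise ValueError("fiducial points are collinear/degenerate")
    C = B0.T @ A0 / a.shape[0]
    U, S, Vt = np.linalg.svd(C)
    d = np.sign(np.linalg.det(U) * np.linalg.det(Vt))
    if d < 0 and not allow_reflection:
        D = np.diag([1.0, 1.0, -1.0])
    else:
        D = np.eye(3)
    R = U @ D @ Vt
    var_a = float(np.mean(np.sum(A0**2, axis=1)))
    s = float(np.trace(np.diag(S) @ D)) / var_a
    t = mu_b - s * R @ mu_a
    xf = SimilarityTransform(scale=s, rotation=R, translation=t)
    rms = float(np.sqrt(np.mean(np.sum((xf.apply(a) - b) ** 2, axis=1))))
    return xf, rms


def place_organ(
    organ: Mesh,
    body: Mesh,
    fiducial_pairs: Sequence[Tuple[MaterialPoint, MaterialPoint]],
    organ_field: str = "coordinates",
    body_field: str = "coordinates",
) -> Tuple[Mesh, SimilarityTransform, float]:
    """Place an organ scaffold in a body scaffold via fiducial landmarks.

    Each pair is (organ material point, body material point); both are
    evaluated in their own mesh and the similarity transform matching them
    is applied to all of the organ's nodal parameters (values affinely,
    derivative slots rotated and scaled).  Returns (placed organ mesh,
    transform, fiducial RMS).
    """
    if len(fiducial_pairs) < 3:
        raise ValueError("need >= 3 fiducial pairs")
    src = np.array([eval_field(organ, organ_field, mp) for mp, _ in fiducial_pairs])
    dst = np.array([eval_field(body, body_field, mp) for _, mp in fiducial_pairs])
    xf, rms = fiducial_transform(src, dst)
    placed = organ.copy()
    for node in placed.nodes.values():
        blk = node.params.get(organ_field)
        if blk is None:
            continue
        for v in range(blk.shape[0]):
            blk[v, :, 0] = xf.apply(blk[v, :, 0])
            blk[v, :, 1:] = xf.apply_vector(blk[v, :, 1:].T).T
    return placed, xf, rms
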