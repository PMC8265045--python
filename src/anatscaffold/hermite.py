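"""Cubic Hermite finite-element meshes ("scaffolds") and field evaluation.

A scaffold is a mesh of line/quad/hex elements whose fields are interpolated
with tensor-product cubic Hermite basis functions.  Each node stores, per
field and per component, a block of nodal parameters ordered

    (value, d/dxi1, d/dxi2, d2/dxi1dxi2, d/dxi3, d2/dxi1dxi3,
     d2/dxi2dxi3, d3/dxi1dxi2dxi3)

i.e. slot index ``s`` carries a first derivative in direction ``i`` iff bit
``i-1`` of ``s`` is set.  A d-dimensional element uses the first ``2**d``
slots.  Nodes may hold several *derivative versions* (alternative derivative
sets sharing the value slot's meaning); elements select a version per local
node, which is how deliberate C1 breaks (e.g. at vessel junctions) are
expressed.

Element-local coordinates xi lie in [0,1]^d with xi1 varying fastest in the
local node ordering; a ``MaterialPoint`` (element id, xi) is the
species-independent address of a tissue particle.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field as dataclass_field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

__all__ = [
    "SLOT_NAMES",
    "Node",
    "Element",
    "AnnotationGroup",
    "MaterialPoint",
    "Mesh",
    "MeshError",
    "basis_1d",
    "tensor_basis",
    "eval_field",
    "element_jacobian",
    "continuity_report",
    "FaceMismatch",
]

#: Canonical nodal-parameter slot ordering.
SLOT_NAMES = ("value", "d1", "d2", "d12", "d3", "d13", "d23", "d123")

#: Gauss-Legendre abscissae/weights on [0,1], 3 points per direction.
GAUSS3_X = (0.5 * (1.0 - np.sqrt(0.6)), 0.5, 0.5 * (1.0 + np.sqrt(0.6)))
GAUSS3_W = (5.0 / 18.0, 8.0 / 18.0, 5.0 / 18.0)


class MeshError(ValueError):
    """Raised for invalid mesh structure, unknown fields/elements, bad xi."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Node:
    """A mesh node: per-field blocks of nodal parameters.

    ``params[field]`` has shape ``(n_versions, n_components, 8)``; version
    indices used by elements are 1-based.
    """

    id: int
    params: Dict[str, np.ndarray] = dataclass_field(default_factory=dict)

    def set_field(self, field: str, block: np.ndarray) -> None:
        block = np.asarray(block, dtype=float)
        if block.ndim == 2:
            block = block[None, :, :]
        if block.ndim != 3 or block.shape[2] != 8:
            raise MeshError(
                f"node {self.id}: parameter block must be (versions, comps, 8), "
                f"got {block.shape}"
            )
        self.params[field] = block

    def version(self, field: str, version: int) -> np.ndarray:
        try:
            block = self.params[field]
        except KeyError:
            raise MeshError(f"node {self.id} has no field {field!r}") from None
        if not 1 <= version <= block.shape[0]:
            raise MeshError(
                f"node {self.id}, field {field!r}: derivative version {version} "
                f"out of range 1..{block.shape[0]}"
            )
        return block[version - 1]


@dataclass
class Element:
    """A line/quad/hex element with cubic Hermite basis in every direction.

    ``nodes`` lists the ``2**dimension`` corner node ids, lowest-xi corner
    first with xi1 varying fastest; ``versions`` selects a derivative version
    per local node (defaults to 1 everywhere).
    """

    id: int
    dimension: int
    nodes: Tuple[int, ...]
    versions: Tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.dimension not in (1, 2, 3):
            raise MeshError(f"element {self.id}: dimension must be 1, 2 or 3")
        self.nodes = tuple(int(n) for n in self.nodes)
        if len(self.nodes) != 2**self.dimension:
            raise MeshError(
                f"element {self.id}: expected {2**self.dimension} local nodes, "
                f"got {len(self.nodes)}"
            )
        if not self.versions:
            self.versions = (1,) * len(self.nodes)
        else:
            self.versions = tuple(int(v) for v in self.versions)
            if len(self.versions) != len(self.nodes):
                raise MeshError(f"element {self.id}: versions/nodes length mismatch")


@dataclass
class AnnotationGroup:
    """A named, ontology-linked subset of the mesh (region or landmark).

    ``faces`` lists oriented element faces ``(element_id, axis, side)`` with
    ``axis`` in 1..3 and ``side`` in {0, 1}; used for surface sampling and
    surface-restricted projection.
    """

    term: str
    ontology_id: str = ""
    elements: Set[int] = dataclass_field(default_factory=set)
    nodes: Set[int] = dataclass_field(default_factory=set)
    faces: Set[Tuple[int, int, int]] = dataclass_field(default_factory=set)
    kind: str = "region"  # region | landmark
    abbrev: str = ""

    def __post_init__(self) -> None:
        if not self.term:
            raise MeshError("annotation group requires a non-empty term")
        if self.kind not in ("region", "landmark"):
            raise MeshError(f"annotation group {self.term!r}: bad kind {self.kind!r}")


@dataclass(frozen=True)
class MaterialPoint:
    """Element-local address (element id, xi in [0,1]^d) of a material point."""

    element_id: int
    xi: Tuple[float, ...]

    def __post_init__(self) -> None:
        xi = tuple(float(x) for x in self.xi)
        object.__setattr__(self, "xi", xi)
        for x in xi:
            if not -1e-12 <= x <= 1.0 + 1e-12:
                raise MeshError(f"material coordinate {x} outside [0, 1]")


class Mesh:
    """A scaffold: nodes, Hermite elements, named fields, annotation groups.

    Fields are named coordinate/scalar fields; ``"coordinates"`` is the
    reference configuration and fitting adds ``"fitted"``.
    """

    def __init__(self) -> None:
        self.nodes: Dict[int, Node] = {}
        self.elements: Dict[int, Element] = {}
        self.fields: Dict[str, int] = {}  # name -> component count
        self.groups: List[AnnotationGroup] = []

    # -- construction -------------------------------------------------------

    def add_node(self, node: Node) -> Node:
        if node.id in self.nodes:
            raise MeshError(f"duplicate node id {node.id}")
        self.nodes[node.id] = node
        return node

    def add_element(self, element: Element) -> Element:
        if element.id in self.elements:
            raise MeshError(f"duplicate element id {element.id}")
        for nid in element.nodes:
            if nid not in self.nodes:
                raise MeshError(f"element {element.id} references missing node {nid}")
        self.elements[element.id] = element
        return element

    def declare_field(self, name: str, n_components: int = 3) -> None:
        self.fields[name] = int(n_components)

    def add_group(self, group: AnnotationGroup) -> AnnotationGroup:
        for eid in group.elements:
            if eid not in self.elements:
                raise MeshError(
                    f"group {group.term!r} references missing element {eid}"
                )
        for nid in group.nodes:
            if nid not in self.nodes:
                raise MeshError(f"group {group.term!r} references missing node {nid}")
        self.groups.append(group)
        return group

    # -- queries ------------------------------------------------------------

    def group(self, term: str) -> AnnotationGroup:
        for g in self.groups:
            if g.term == term or (g.abbrev and g.abbrev == term):
                return g
        raise MeshError(f"no annotation group named {term!r}")

    def find_groups(self, substring: str) -> List[AnnotationGroup]:
        s = substring.lower()
        return [g for g in self.groups if s in g.term.lower()]

    def element_params(
        self, element: Element, field: str
    ) -> np.ndarray:
        """Stack the element's nodal parameters: shape (2**d, ncomp, 2**d slots)."""
        nslots = 2**element.dimension
        out = []
        for nid, ver in zip(element.nodes, element.versions):
            out.append(self.nodes[nid].version(field, ver)[:, :nslots])
        return np.stack(out, axis=0)

    def bounding_box(self, field: str = "coordinates") -> Tuple[np.ndarray, np.ndarray]:
        vals = np.array(
            [n.params[field][0, :, 0] for n in self.nodes.values() if field in n.params]
        )
        if vals.size == 0:
            raise MeshError(f"no node carries field {field!r}")
        return vals.min(axis=0), vals.max(axis=0)

    def copy(self) -> "Mesh":
        import copy as _copy

        m = Mesh()
        m.fields = dict(self.fields)
        for n in self.nodes.values():
            m.add_node(Node(n.id, {f: b.copy() for f, b in n.params.items()}))
        for e in self.elements.values():
            m.add_element(Element(e.id, e.dimension, e.nodes, e.versions))
        m.groups = _copy.deepcopy(self.groups)
        return m


# ---------------------------------------------------------------------------
# basis functions
# ---------------------------------------------------------------------------

# rows: (H00 value@0, H10 deriv@0, H01 value@1, H11 deriv@1); one table per
# requested derivative order of the cubic Hermite shape functions.
_HERMITE_COEFFS = np.array(
    [  # 1, t, t^2, t^3
        [1.0, 0.0, -3.0, 2.0],
        [0.0, 1.0, -2.0, 1.0],
        [0.0, 0.0, 3.0, -2.0],
        [0.0, 0.0, -1.0, 1.0],
    ]
)


def basis_1d(xi: float, deriv: int = 0) -> np.ndarray:
    """The four 1D cubic Hermite weights at ``xi``, ordered
    (value@0, d/dxi@0, value@1, d/dxi@1); ``deriv`` differentiates them.
    """
    x = float(xi)
    if not -1e-12 <= x <= 1.0 + 1e-12:
        raise MeshError(f"xi={xi} outside [0, 1]")
    if not 0 <= int(deriv) <= 3:
        raise MeshError(f"derivative order {deriv} unsupported (0..3)")
    coeffs = _HERMITE_COEFFS
    for _ in range(int(deriv)):
        coeffs = coeffs[:, 1:] * np.arange(1, coeffs.shape[1])
    powers = x ** np.arange(coeffs.shape[1])
    return coeffs @ powers


def tensor_basis(xi: Sequence[float], deriv: Sequence[int] = ()) -> np.ndarray:
    """Tensor-product Hermite weight table, shape (2**d corners, 2**d slots).

    ``W[c, s]`` weights parameter slot ``s`` of corner ``c`` (corner bit i-1
    = position along xi_i, slot bit i-1 = first derivative along xi_i);
    ``deriv`` gives the derivative order per direction (default all zero).
    """
    xi = tuple(float(x) for x in xi)
    d = len(xi)
    if d not in (1, 2, 3):
        raise MeshError(f"xi must have 1..3 components, got {d}")
    deriv = tuple(int(k) for k in deriv) if deriv else (0,) * d
    if len(deriv) != d or any(k < 0 for k in deriv):
        raise MeshError(f"malformed derivative spec {deriv} for {d}D element")
    b = [basis_1d(xi[i], deriv[i]) for i in range(d)]
    n = 2**d
    w = np.empty((n, n))
    for c in range(n):
        for s in range(n):
            acc = 1.0
            for i in range(d):
                acc *= b[i][2 * ((c >> i) & 1) + ((s >> i) & 1)]
            w[c, s] = acc
    return w


# ---------------------------------------------------------------------------
# field evaluation
# ---------------------------------------------------------------------------


def eval_field(
    mesh: Mesh,
    field: str,
    mp: MaterialPoint,
    deriv: Sequence[int] = (),
) -> np.ndarray:
    """Evaluate a field (or a partial xi-derivative of it) at a material point."""
    if field not in mesh.fields:
        raise MeshError(f"unknown field {field!r}")
    try:
        element = mesh.elements[mp.element_id]
    except KeyError:
        raise MeshError(f"unknown element {mp.element_id}") from None
    if len(mp.xi) != element.dimension:
        raise MeshError(
            f"material point has {len(mp.xi)} coordinates for a "
            f"{element.dimension}D element"
        )
    w = tensor_basis(mp.xi, deriv)
    params = mesh.element_params(element, field)  # (corners, ncomp, slots)
    return np.einsum("cs,cks->k", w, params)


def element_jacobian(
    mesh: Mesh, field: str, mp: MaterialPoint
) -> Tuple[np.ndarray, float]:
    """3x3 Jacobian dx/dxi of a 3D element at ``mp`` and its determinant."""
    element = mesh.elements.get(mp.element_id)
    if element is None:
        raise MeshError(f"unknown element {mp.element_id}")
    if element.dimension != 3:
        raise MeshError(
            f"element {element.id} is {element.dimension}D; Jacobian needs 3D"
        )
    cols = [
        eval_field(mesh, field, mp, deriv=tuple(1 if j == i else 0 for j in range(3)))
        for i in range(3)
    ]
    jac = np.column_stack(cols)
    return jac, float(np.linalg.det(jac))


# ---------------------------------------------------------------------------
# inter-element continuity
# ---------------------------------------------------------------------------


@dataclass
class FaceMismatch:
    """One shared face whose cross-boundary interpolation disagrees."""

    element_a: int
    element_b: int
    face_nodes: Tuple[int, ...]
    max_value_gap: float
    max_deriv_gap: float
    versions_differ: bool


def _faces_of(element: Element) -> List[Tuple[int, int, Tuple[int, ...]]]:
    """All (axis, side, corner-node-tuple) faces of an element; face corners
    are ordered by the face-local binary index (remaining directions ascending,
    first remaining direction fastest)."""
    d = element.dimension
    out = []
    for axis in range(1, d + 1):
        rest = [i for i in range(d) if i != axis - 1]
        for side in (0, 1):
            corners = []
            for fidx in range(2 ** len(rest)):
                c = side << (axis - 1)
                for k, i in enumerate(rest):
                    c |= ((fidx >> k) & 1) << i
                corners.append(element.nodes[c])
            out.append((axis, side, tuple(corners)))
    return out


def _square_symmetries():
    """The 8 symmetries of the unit square as (perm index map, (u,v) map)."""
    syms = []
    for swap in (False, True):
        for fu in (False, True):
            for fv in (False, True):
                def idx_map(i, swap=swap, fu=fu, fv=fv):
                    u, v = i & 1, (i >> 1) & 1
                    if swap:
                        u, v = v, u
                    if fu:
                        u = 1 - u
                    if fv:
                        v = 1 - v
                    return u | (v << 1)

                def uv_map(u, v, swap=swap, fu=fu, fv=fv):
                    if swap:
                        u, v = v, u
                    if fu:
                        u = 1.0 - u
                    if fv:
                        v = 1.0 - v
                    return u, v

                syms.append((idx_map, uv_map))
    return syms


_SQUARE_SYMS = _square_symmetries()


def _match_face(corners_a: Tuple[int, ...], corners_b: Tuple[int, ...]):
    """Map from A's face coordinates to B's such that corners coincide."""
    n = len(corners_a)
    if n == 1:  # 1D elements share a point
        return lambda uv: uv
    if n == 2:  # edge
        if corners_a == corners_b:
            return lambda uv: uv
        if corners_a == corners_b[::-1]:
            return lambda uv: (1.0 - uv[0],)
        return None
    for idx_map, uv_map in _SQUARE_SYMS:
        if all(corners_b[idx_map(i)] == corners_a[i] for i in range(4)):
            return lambda uv, m=uv_map: m(uv[0], uv[1])
    return None


def _embed(uv: Sequence[float], axis: int, side: int, d: int) -> Tuple[float, ...]:
    xi = [0.0] * d
    rest = [i for i in range(d) if i != axis - 1]
    for k, i in enumerate(rest):
        xi[i] = uv[k]
    xi[axis - 1] = float(side)
    return tuple(xi)


def continuity_report(
    mesh: Mesh,
    field: str = "coordinates",
    tol: float = 1e-9,
    c1_where_versions_differ: bool = True,
) -> List[FaceMismatch]:
    """Check C0/C1 agreement across every shared element face.

    Returns one record per face where the cross-boundary value gap or the
    transverse first-derivative gap exceeds ``tol``.  With
    ``c1_where_versions_differ=False`` the derivative check is skipped on
    faces where the two elements select different derivative versions for a
    shared node (deliberate C1 breaks).
    """
    face_table: Dict[frozenset, List] = {}
    for e in mesh.elements.values():
        for axis, side, corners in _faces_of(e):
            face_table.setdefault(frozenset(corners), []).append(
                (e, axis, side, corners)
            )

    samples_1d = [0.0, 1.0 / 3.0, 2.0 / 3.0, 1.0]
    records: List[FaceMismatch] = []
    for key, entries in face_table.items():
        if len(entries) < 2:
            continue
        for (ea, axa, sa, ca), (eb, axb, sb, cb) in itertools.combinations(entries, 2):
            if ea.id == eb.id:
                continue
            mapping = _match_face(ca, cb)
            if mapping is None:
                continue
            d = ea.dimension
            nfree = d - 1
            versions_differ = False
            ver_a = dict(zip(ea.nodes, ea.versions))
            ver_b = dict(zip(eb.nodes, eb.versions))
            for nid in key:
                if ver_a.get(nid) != ver_b.get(nid):
                    versions_differ = True
                    break
            grid = (
                [()]
                if nfree == 0
                else [
                    tuple(p)
                    for p in itertools.product(samples_1d, repeat=nfree)
                ]
            )
            vgap = 0.0
            dgap = 0.0
            deriv_a = tuple(1 if i == axa - 1 else 0 for i in range(d))
            deriv_b = tuple(1 if i == axb - 1 else 0 for i in range(d))
            sign = -1.0 if sa == sb else 1.0
            check_c1 = c1_where_versions_differ or not versions_differ
            for uv in grid:
                xia = _embed(uv, axa, sa, d)
                xib = _embed(mapping(uv) if uv else uv, axb, sb, d)
                mpa = MaterialPoint(ea.id, xia)
                mpb = MaterialPoint(eb.id, xib)
                va = eval_field(mesh, field, mpa)
                vb = eval_field(mesh, field, mpb)
                vgap = max(vgap, float(np.linalg.norm(va - vb)))
                if check_c1:
                    da = eval_field(mesh, field, mpa, deriv_a)
                    db = eval_field(mesh, field, mpb, deriv_b)
                    dgap = max(dgap, float(np.linalg.norm(da - sign * db)))
            if vgap > tol or dgap > tol:
                records.append(
                    FaceMismatch(
                        element_a=ea.id,
                        element_b=eb.id,
                        face_nodes=tuple(sorted(key)),
                        max_value_gap=vgap,
                        max_deriv_gap=dgap,
                        versions_differ=versions_differ,
                    )
                )
    records.sort(key=lambda r: (r.element_a, r.element_b))
    return records


# ---------------------------------------------------------------------------
# validation helpers
# ---------------------------------------------------------------------------


def check_jacobians(
    mesh: Mesh, field: str = "coordinates", quadrature: int = 3
) -> float:
    """Minimum Jacobian determinant of all 3D elements at interior Gauss
    points; raises ``MeshError`` if any determinant is non-positive."""
    worst = np.inf
    pts = GAUSS3_X if quadrature == 3 else tuple((i + 0.5) / quadrature for i in range(quadrature))
    for e in mesh.elements.values():
        if e.dimension != 3:
            continue
        for xi in itertools.product(pts, repeat=3):
            _, det = element_jacobian(mesh, field, MaterialPoint(e.id, xi))
            if det < worst:
                worst = det
            if det <= 0.0:
                raise MeshError(
                    f"element {e.id}: non-positive Jacobian {det:.3e} at xi={xi}"
                )
    return float(worst)
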