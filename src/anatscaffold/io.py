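"""File formats: segmentation XML, native scaffold files, VTK export, CSV.

Segmentation data uses a small XML dialect modelled on neuromorphology
reconstruction files: a root element with a ``units`` attribute ("um", the
microscopy default, or "mm"), ``contour`` elements with ``name``, optional
``ontologyId`` and ``closed`` attributes and ``point`` children carrying
``x``/``y``/``z`` (and optional ``d``) attributes, and ``marker`` elements
likewise.  Coordinates are normalised to mm on load.  The dialect is a
declared subset of the public neuromorphological file specification, not a
compatibility claim.

The native scaffold format is versioned, text-based JSON with canonical key
ordering, so identical meshes serialise byte-identically; a checksum guards
against corruption.  VTK export subdivides each Hermite element into linear
hexahedra/quads sampled from the Hermite field (legacy ASCII unstructured
grid, readable by any VTK-compatible viewer).
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import dataclass, field as dataclass_field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from lxml import etree

from .hermite import (
    AnnotationGroup,
    Element,
    MaterialPoint,
    Mesh,
    MeshError,
    Node,
    eval_field,
)
from .embedding import EmbeddedPoint

logger = logging.getLogger(__name__)

__all__ = [
    "Contour",
    "Marker",
    "ContourDataset",
    "IOFormatError",
    "read_segmentation_xml",
    "write_segmentation_xml",
    "read_mesh",
    "write_mesh",
    "export_vtk",
    "write_embedded_csv",
    "read_embedded_csv",
    "read_fiducial_pairs_csv",
    "MESH_FORMAT_VERSION",
]

MESH_FORMAT_NAME = "anatscaffold-mesh"
MESH_FORMAT_VERSION = 1


class IOFormatError(ValueError):
    """Malformed or unsupported input file."""


# ---------------------------------------------------------------------------
# segmentation data
# ---------------------------------------------------------------------------


@dataclass
class Contour:
    term: str
    ontology_id: str
    closed: bool
    points: np.ndarray  # (n, 3) mm


@dataclass
class Marker:
    label: str
    term: str
    ontology_id: str
    point: np.ndarray  # (3,) mm


@dataclass
class ContourDataset:
    """Annotated contour polylines and marker points (physical mm)."""

    contours: List[Contour] = dataclass_field(default_factory=list)
    markers: List[Marker] = dataclass_field(default_factory=list)
    source: str = ""
    units: str = "mm"

    def all_points(self) -> Tuple[np.ndarray, List[str]]:
        """All data points stacked with their anatomical terms."""
        pts: List[np.ndarray] = []
        terms: List[str] = []
        for c in self.contours:
            pts.append(c.points)
            terms.extend([c.term] * len(c.points))
        for m in self.markers:
            pts.append(m.point[None, :])
            terms.append(m.term)
        if not pts:
            return np.zeros((0, 3)), []
        return np.vstack(pts), terms

    @property
    def n_points(self) -> int:
        return sum(len(c.points) for c in self.contours) + len(self.markers)


_UNIT_SCALE = {"um": 1e-3, "mm": 1.0}


def _read_points(elem, scale: float, path: str) -> np.ndarray:
    pts = []
    for p in elem.findall("point"):
        try:
            pts.append([float(p.get(k, "0")) * scale for k in ("x", "y", "z")])
        except (TypeError, ValueError) as exc:
            raise IOFormatError(
                f"{path}:{p.sourceline}: bad point coordinates"
            ) from exc
    return np.asarray(pts, dtype=float).reshape(-1, 3)


def read_segmentation_xml(path: str) -> ContourDataset:
    """Read a segmentation file in the documented XML dialect.

    Unknown child elements are ignored with a logged warning; a missing
    ontology id loads as an empty string with a warning.  A file with no
    contours and no markers is an error.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise IOFormatError(f"{path}: malformed XML: {exc}") from exc
    root = tree.getroot()
    units = (root.get("units") or "um").lower()
    if units not in _UNIT_SCALE:
        raise IOFormatError(f"{path}: unknown units {units!r} (use 'um' or 'mm')")
    scale = _UNIT_SCALE[units]

    ds = ContourDataset(source=str(path), units="mm")
    skipped = 0
    marker_count = 0
    for child in root:
        if not isinstance(child.tag, str):
            continue  # comments etc.
        tag = child.tag.lower()
        if tag == "contour":
            term = child.get("name", "")
            oid = child.get("ontologyId", "")
            if not oid:
                logger.warning(
                    "%s:%s: contour %r has no ontology id", path, child.sourceline, term
                )
            pts = _read_points(child, scale, str(path))
            if len(pts) < 2:
                raise IOFormatError(
                    f"{path}:{child.sourceline}: contour {term!r} needs >= 2 points"
                )
            closed = (child.get("closed", "false").lower() in ("true", "1", "yes"))
            ds.contours.append(Contour(term, oid, closed, pts))
        elif tag == "marker":
            term = child.get("name", "")
            oid = child.get("ontologyId", "")
            if not oid:
                logger.warning(
                    "%s:%s: marker %r has no ontology id", path, child.sourceline, term
                )
            pts = _read_points(child, scale, str(path))
            if len(pts) != 1:
                raise IOFormatError(
                    f"{path}:{child.sourceline}: marker {term!r} needs exactly 1 point"
                )
            marker_count += 1
            label = child.get("label") or f"marker_{marker_count}"
            ds.markers.append(Marker(label, term, oid, pts[0]))
        else:
            skipped += 1
            logger.warning(
                "%s:%s: ignoring unknown element <%s>", path, child.sourceline, child.tag
            )
    if not ds.contours and not ds.markers:
        raise IOFormatError(f"{path}: empty dataset (no contours, no markers)")
    ds.skipped_elements = skipped  # type: ignore[attr-defined]
    return ds


def write_segmentation_xml(ds: ContourDataset, path: str, units: str = "mm") -> None:
    """Write a dataset in the same XML dialect (default in mm)."""
    scale = 1.0 / _UNIT_SCALE[units]
    root = etree.Element("segmentation", units=units)
    for c in ds.contours:
        el = etree.SubElement(
            root, "contour", name=c.term, closed="true" if c.closed else "false"
        )
        if c.ontology_id:
            el.set("ontologyId", c.ontology_id)
        for p in c.points:
            etree.SubElement(
                el, "point",
                x=repr(float(p[0] * scale)), y=repr(float(p[1] * scale)), z=repr(float(p[2] * scale)),
            )
    for m in ds.markers:
        el = etree.SubElement(root, "marker", name=m.term, label=m.label)
        if m.ontology_id:
            el.set("ontologyId", m.ontology_id)
        p = m.point
        etree.SubElement(
            el, "point", x=repr(float(p[0] * scale)), y=repr(float(p[1] * scale)), z=repr(float(p[2] * scale))
        )
    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )


# ---------------------------------------------------------------------------
# native mesh format
# ---------------------------------------------------------------------------


def _mesh_payload(mesh: Mesh) -> dict:
    return {
        "fields": {name: int(nc) for name, nc in sorted(mesh.fields.items())},
        "nodes": [
            {
                "id": nid,
                "params": {
                    f: [[list(map(float, comp)) for comp in ver] for ver in blk]
                    for f, blk in sorted(mesh.nodes[nid].params.items())
                },
            }
            for nid in sorted(mesh.nodes)
        ],
        "elements": [
            {
                "id": eid,
                "dimension": mesh.elements[eid].dimension,
                "nodes": list(mesh.elements[eid].nodes),
                "versions": list(mesh.elements[eid].versions),
            }
            for eid in sorted(mesh.elements)
        ],
        "groups": [
            {
                "term": g.term,
                "abbrev": g.abbrev,
                "ontology_id": g.ontology_id,
                "kind": g.kind,
                "elements": sorted(g.elements),
                "nodes": sorted(g.nodes),
                "faces": sorted(list(f) for f in g.faces),
            }
            for g in mesh.groups
        ],
    }


def _canonical(obj) -> str:
    return json.dumps(obj, sort_keys=True, separators=(",", ":"))


def write_mesh(mesh: Mesh, path: str) -> None:
    """Write a mesh in the native versioned text format (lossless)."""
    payload = _mesh_payload(mesh)
    body = _canonical(payload)
    doc = {
        "format": MESH_FORMAT_NAME,
        "version": MESH_FORMAT_VERSION,
        "checksum": hashlib.sha256(body.encode()).hexdigest(),
        "mesh": payload,
    }
    with open(path, "w") as fh:
        fh.write(_canonical(doc))
        fh.write("\n")


def read_mesh(path: str) -> Mesh:
    """Read a native mesh file; errors on version mismatch, warns on
    checksum mismatch."""
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise IOFormatError(f"{path}: not a valid mesh file: {exc}") from exc
    if doc.get("format") != MESH_FORMAT_NAME:
        raise IOFormatError(f"{path}: not a {MESH_FORMAT_NAME} file")
    version = doc.get("version")
    if version != MESH_FORMAT_VERSION:
        raise IOFormatError(
            f"{path}: format version {version} unsupported "
            f"(this build reads version {MESH_FORMAT_VERSION})"
        )
    payload = doc["mesh"]
    checksum = hashlib.sha256(_canonical(payload).encode()).hexdigest()
    if checksum != doc.get("checksum"):
        logger.warning("%s: checksum mismatch (file may be corrupted)", path)

    mesh = Mesh()
    for name, nc in payload["fields"].items():
        mesh.declare_field(name, nc)
    for nd in payload["nodes"]:
        node = Node(int(nd["id"]))
        for f, blk in nd["params"].items():
            node.set_field(f, np.asarray(blk, dtype=float))
        mesh.add_node(node)
    for el in payload["elements"]:
        mesh.add_element(
            Element(int(el["id"]), int(el["dimension"]),
                    tuple(el["nodes"]), tuple(el["versions"]))
        )
    for gr in payload["groups"]:
        mesh.add_group(
            AnnotationGroup(
                term=gr["term"],
                abbrev=gr.get("abbrev", ""),
                ontology_id=gr.get("ontology_id", ""),
                kind=gr.get("kind", "region"),
                elements=set(gr.get("elements", [])),
                nodes=set(gr.get("nodes", [])),
                faces={tuple(f) for f in gr.get("faces", [])},
            )
        )
    return mesh


# ---------------------------------------------------------------------------
# VTK export
# ---------------------------------------------------------------------------

# binary corner order -> VTK hexahedron / quad vertex order
_VTK_HEX_ORDER = (0, 1, 3, 2, 4, 5, 7, 6)
_VTK_QUAD_ORDER = (0, 1, 3, 2)


def export_vtk(
    mesh: Mesh, field: str, path: str, refine_per_element: int = 1
) -> None:
    """Export the Hermite field as a legacy-ASCII VTK unstructured grid.

    Each d-dimensional element is subdivided into ``refine**d`` linear
    cells with vertices sampled from the Hermite interpolation; annotation
    groups with element members are exported as 0/1 cell-data arrays.
    """
    r = int(refine_per_element)
    if r < 1:
        raise IOFormatError("refine_per_element must be >= 1")
    points: List[np.ndarray] = []
    cells: List[Tuple[int, List[int]]] = []  # (vtk cell type, vertex ids)
    cell_parent: List[int] = []
    for eid in sorted(mesh.elements):
        e = mesh.elements[eid]
        d = e.dimension
        # lattice of sampled vertices
        shape = (r + 1,) * d
        base = len(points)
        import itertools as _it

        idx_of = {}
        for flat, idx in enumerate(_it.product(*[range(r + 1)] * d)):
            xi = tuple(i / r for i in idx)
            points.append(eval_field(mesh, field, MaterialPoint(eid, xi)))
            idx_of[idx] = base + flat
        for cell in _it.product(*[range(r)] * d):
            verts = []
            for c in range(2**d):
                idx = tuple(cell[i] + ((c >> i) & 1) for i in range(d))
                verts.append(idx_of[idx])
            if d == 3:
                cells.append((12, [verts[i] for i in _VTK_HEX_ORDER]))
            elif d == 2:
                cells.append((9, [verts[i] for i in _VTK_QUAD_ORDER]))
            else:
                cells.append((3, verts))
            cell_parent.append(eid)

    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"anatscaffold field {field}\n")
        fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(points)} double\n")
        for p in points:
            fh.write(f"{p[0]:.12g} {p[1]:.12g} {p[2]:.12g}\n")
        total = sum(len(v) + 1 for _, v in cells)
        fh.write(f"CELLS {len(cells)} {total}\n")
        for _, verts in cells:
            fh.write(" ".join([str(len(verts))] + [str(v) for v in verts]) + "\n")
        fh.write(f"CELL_TYPES {len(cells)}\n")
        for t, _ in cells:
            fh.write(f"{t}\n")
        region_groups = [g for g in mesh.groups if g.elements]
        if region_groups:
            fh.write(f"CELL_DATA {len(cells)}\n")
            for g in region_groups:
                name = "".join(ch if ch.isalnum() else "_" for ch in g.term)
                fh.write(f"SCALARS {name} int 1\nLOOKUP_TABLE default\n")
                for parent in cell_parent:
                    fh.write("1\n" if parent in g.elements else "0\n")


def read_vtk_unstructured(path: str) -> Tuple[np.ndarray, List[List[int]], List[int]]:
    """Minimal legacy-VTK reader (points, cells, cell types) used for
    round-trip checks of :func:`export_vtk` output."""
    with open(path) as fh:
        tokens = fh.read().split()
    it = iter(range(len(tokens)))
    i = 0
    pts = None
    cells: List[List[int]] = []
    types: List[int] = []
    while i < len(tokens):
        t = tokens[i]
        if t == "POINTS":
            n = int(tokens[i + 1])
            vals = [float(v) for v in tokens[i + 3 : i + 3 + 3 * n]]
            pts = np.array(vals).reshape(n, 3)
            i += 3 + 3 * n
        elif t == "CELLS":
            ncell = int(tokens[i + 1])
            total = int(tokens[i + 2])
            j = i + 3
            for _ in range(ncell):
                k = int(tokens[j])
                cells.append([int(v) for v in tokens[j + 1 : j + 1 + k]])
                j += k + 1
            i = j
        elif t == "CELL_TYPES":
            n = int(tokens[i + 1])
            types = [int(v) for v in tokens[i + 2 : i + 2 + n]]
            i += 2 + n
        else:
            i += 1
    if pts is None:
        raise IOFormatError(f"{path}: no POINTS section")
    return pts, cells, types


# ---------------------------------------------------------------------------
# embedded-point tables
# ---------------------------------------------------------------------------

_EMBED_COLUMNS = (
    "label", "term", "ontology_id", "element",
    "xi1", "xi2", "xi3", "residual", "off_mesh",
)


def write_embedded_csv(points: Sequence[EmbeddedPoint], path: str) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_EMBED_COLUMNS)
        for ep in points:
            xi = list(ep.mp.xi) + [""] * (3 - len(ep.mp.xi))
            w.writerow(
                [ep.label, ep.term, ep.ontology_id, ep.mp.element_id,
                 *[repr(x) if x != "" else "" for x in xi],
                 repr(ep.residual), int(ep.off_mesh)]
            )


def read_embedded_csv(path: str) -> List[EmbeddedPoint]:
    out: List[EmbeddedPoint] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(_EMBED_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise IOFormatError(f"{path}: missing columns {sorted(missing)}")
        for row in reader:
            xi = tuple(
                float(row[k]) for k in ("xi1", "xi2", "xi3") if row[k] not in ("", None)
            )
            out.append(
                EmbeddedPoint(
                    label=row["label"],
                    term=row["term"],
                    ontology_id=row["ontology_id"],
                    mp=MaterialPoint(int(row["element"]), xi),
                    residual=float(row["residual"]),
                    off_mesh=bool(int(row["off_mesh"])),
                )
            )
    return out


def read_fiducial_pairs_csv(path: str) -> List[Tuple[MaterialPoint, MaterialPoint]]:
    """Fiducial pairs as CSV columns organ_element, oxi1..3, body_element, bxi1..3."""
    pairs = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            organ_mp = MaterialPoint(
                int(row["organ_element"]),
                tuple(float(row[f"oxi{i}"]) for i in (1, 2, 3)),
            )
            body_mp = MaterialPoint(
                int(row["body_element"]),
                tuple(float(row[f"bxi{i}"]) for i in (1, 2, 3)),
            )
            pairs.append((organ_mp, body_mp))
    if not pairs:
        raise IOFormatError(f"{path}: no fiducial pairs")
    return pairs
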