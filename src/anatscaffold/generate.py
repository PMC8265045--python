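"""Algorithmic generation of annotated anatomical scaffolds.

Organ scaffolds are produced from a small set of anatomical and mathematical
parameters: a cross-section profile swept along a centerline for tubular
organs (colon), per-region swept manifolds for the atria, and concentric
cylindrical shells for the whole body.  Species presets encode the
topological differences that matter anatomically — the human colon has three
taeniae coli, the pig two and the mouse none; the left atrium receives four
pulmonary veins in the human, two in the pig and three in the rat.

All generation is deterministic: identical parameters give identical meshes.
Geometric magnitudes (radii, lengths) are plausible defaults in mm; only the
topological counts above are treated as anatomically mandated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dataclass_field
from fractions import Fraction
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.interpolate import CubicSpline

from .hermite import (
    AnnotationGroup,
    Element,
    MaterialPoint,
    Mesh,
    MeshError,
    Node,
    eval_field,
)

__all__ = [
    "CrossSectionSpec",
    "Centerline",
    "SpeciesPreset",
    "GenerationError",
    "build_tube",
    "make_colon",
    "make_atria",
    "make_body",
    "refine",
    "merge_meshes",
    "PRESETS",
    "generate_preset",
]


class GenerationError(ValueError):
    """Raised when parameters produce an invalid scaffold."""


# ---------------------------------------------------------------------------
# cross-section and centerline
# ---------------------------------------------------------------------------


@dataclass
class CrossSectionSpec:
    """Tube cross-section profile.

    The wall is centred on ``base_radius``; taeniae add a thickness bump to
    the outer surface over their angular extent and haustra modulate the
    radius sinusoidally along the tube, suppressed under the taeniae.

    Angles are degrees; radii/thicknesses mm; ``haustra_wavelength`` is the
    number of haustral cycles per axial element segment.
    """

    base_radius: float
    wall_thickness: float
    n_around: int = 8
    taeniae: Tuple[Tuple[float, float, float], ...] = ()  # (centre deg, width deg, bump mm)
    haustra_amplitude: float = 0.0
    haustra_wavelength: float = 1.0

    def __post_init__(self) -> None:
        if self.n_around < 4:
            raise GenerationError("n_around must be >= 4")
        if self.base_radius <= 0 or self.wall_thickness <= 0:
            raise GenerationError("radii and wall thickness must be positive")
        spans = []
        for centre, width, bump in self.taeniae:
            if width <= 0 or bump < 0:
                raise GenerationError("taenia width must be > 0 and bump >= 0")
            spans.append(((centre - width / 2) % 360.0, width))
        spans.sort()
        for (a0, w0), (a1, w1) in zip(spans, spans[1:] + spans[:1]):
            gap = (a1 - a0) % 360.0 or 360.0
            if gap < w0 - 1e-9:
                raise GenerationError("taenia angular extents overlap")

    # radius of the wall mid-surface, before taenia thickening
    def core_radius(self, theta: np.ndarray, s_frac: np.ndarray, n_segments: int) -> np.ndarray:
        r = np.full(np.broadcast(theta, s_frac).shape, self.base_radius, dtype=float)
        if self.haustra_amplitude > 0.0:
            cycles = self.haustra_wavelength * n_segments
            axial = np.sin(np.pi * cycles * s_frac) ** 2
            r = r + self.haustra_amplitude * axial * self._haustra_window(theta)
        return r

    def taenia_bump(self, theta: np.ndarray) -> np.ndarray:
        out = np.zeros(np.shape(theta), dtype=float)
        for centre, width, bump in self.taeniae:
            half = math.radians(width) / 2.0
            delta = np.angle(np.exp(1j * (np.asarray(theta) - math.radians(centre))))
            mask = np.abs(delta) < half
            out = out + np.where(mask, bump * np.cos(np.pi * delta / (2 * half)) ** 2, 0.0)
        return out

    def _haustra_window(self, theta: np.ndarray) -> np.ndarray:
        """1 between taeniae, dipping smoothly to 0 at taenia centres."""
        if not self.taeniae:
            return np.ones(np.shape(theta), dtype=float)
        w = np.ones(np.shape(theta), dtype=float)
        for centre, width, _ in self.taeniae:
            half = math.radians(width) / 2.0
            delta = np.angle(np.exp(1j * (np.asarray(theta) - math.radians(centre))))
            mask = np.abs(delta) < half
            w = w - np.where(mask, np.cos(np.pi * delta / (2 * half)) ** 2, 0.0)
        return np.clip(w, 0.0, 1.0)

    def max_outer_radius(self) -> float:
        bump = max((b for _, _, b in self.taeniae), default=0.0)
        return self.base_radius + self.haustra_amplitude + bump + self.wall_thickness / 2


class Centerline:
    """An arc-length parameterised 3D path with rotation-minimising frames.

    Built from ordered waypoints (mm); frames are parallel-transported along
    the path (double-reflection on a fine sampling) so the swept cross
    sections never flip at inflection points.  ``twist`` optionally gives an
    axial twist angle (radians) per waypoint, interpolated along arc length.
    """

    _N_FINE = 1024

    def __init__(self, points: Sequence[Sequence[float]], twist: Optional[Sequence[float]] = None):
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
            raise GenerationError("centerline needs >= 2 3D points")
        if np.any(np.linalg.norm(np.diff(pts, axis=0), axis=1) < 1e-12):
            raise GenerationError("centerline has repeated consecutive points")
        self.points = pts
        chord = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
        bc = "natural" if pts.shape[0] > 2 else None
        if pts.shape[0] == 2:  # straight segment
            self._spline = None
            self._p0, self._p1 = pts[0], pts[1]
        else:
            self._spline = CubicSpline(chord, pts, axis=0, bc_type=bc)
        self.length = float(chord[-1])
        if twist is not None:
            tw = np.asarray(twist, dtype=float)
            if tw.shape[0] != pts.shape[0]:
                raise GenerationError("twist must match waypoint count")
            self._twist = CubicSpline(chord, tw) if pts.shape[0] > 2 else None
            self._tw_lin = tw
        else:
            self._twist = None
            self._tw_lin = None
        self._build_frames()

    def _pos_chord(self, u: np.ndarray) -> np.ndarray:
        if self._spline is None:
            t = np.asarray(u) / self.length
            return self._p0 + np.multiply.outer(t, self._p1 - self._p0)
        return self._spline(u)

    def _build_frames(self) -> None:
        u = np.linspace(0.0, self.length, self._N_FINE)
        p = self._pos_chord(u)
        # unit tangents
        if self._spline is None:
            t = np.tile((self._p1 - self._p0) / self.length, (self._N_FINE, 1))
        else:
            d = self._spline(u, 1)
            t = d / np.linalg.norm(d, axis=1, keepdims=True)
        # initial normal: least-aligned axis
        e = np.zeros((self._N_FINE, 3))
        a = np.eye(3)[np.argmin(np.abs(t[0]))]
        e0 = a - np.dot(a, t[0]) * t[0]
        e[0] = e0 / np.linalg.norm(e0)
        for i in range(self._N_FINE - 1):  # double reflection (rotation minimising)
            v1 = p[i + 1] - p[i]
            c1 = float(v1 @ v1)
            if c1 < 1e-30:
                e[i + 1] = e[i]
                continue
            el = e[i] - (2.0 / c1) * (v1 @ e[i]) * v1
            tl = t[i] - (2.0 / c1) * (v1 @ t[i]) * v1
            v2 = t[i + 1] - tl
            c2 = float(v2 @ v2)
            en = el if c2 < 1e-30 else el - (2.0 / c2) * (v2 @ el) * v2
            en = en - (en @ t[i + 1]) * t[i + 1]
            e[i + 1] = en / np.linalg.norm(en)
        self._fine_u = u
        self._fine_t = t
        self._fine_e1 = e
        # discrete curvature for self-intersection checks
        dt = np.gradient(t, u, axis=0)
        self.max_curvature = float(np.max(np.linalg.norm(dt, axis=1)))
        self._curvature = np.linalg.norm(dt, axis=1)

    def frame(self, s: float) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(point, tangent, e1, e2) at arc length s (clamped to [0, L])."""
        s = min(max(float(s), 0.0), self.length)
        p = self._pos_chord(np.array([s]))[0]
        t = self._interp_unit(self._fine_t, s)
        e1 = self._interp_unit(self._fine_e1, s)
        e1 = e1 - (e1 @ t) * t
        e1 /= np.linalg.norm(e1)
        if self._tw_lin is not None:
            ang = (
                float(self._twist(s))
                if self._twist is not None
                else float(np.interp(s, [0.0, self.length], self._tw_lin))
            )
            e2 = np.cross(t, e1)
            e1 = math.cos(ang) * e1 + math.sin(ang) * e2
        e2 = np.cross(t, e1)
        return p, t, e1, e2

    def _interp_unit(self, table: np.ndarray, s: float) -> np.ndarray:
        v = np.array([np.interp(s, self._fine_u, table[:, k]) for k in range(3)])
        n = np.linalg.norm(v)
        return v / n if n > 0 else v

    def min_bend_radius(self) -> Tuple[float, float]:
        """(smallest radius of curvature, arc length where it occurs)."""
        i = int(np.argmax(self._curvature))
        k = self._curvature[i]
        return (math.inf if k < 1e-12 else 1.0 / k), float(self._fine_u[i])


# ---------------------------------------------------------------------------
# swept-tube construction
# ---------------------------------------------------------------------------


def build_tube(
    cross_section: CrossSectionSpec,
    centerline: Centerline,
    n_segments: int,
    field: str = "coordinates",
    group_prefix: str = "",
) -> Mesh:
    """Sweep a cross-section along a centerline into a tri-cubic tube mesh.

    Produces ``n_segments x n_around x 1`` (wall) hex elements with local
    directions xi1 = circumferential, xi2 = axial, xi3 = transmural, and
    annotation groups "inner surface", "outer surface", "start", "end"
    (optionally prefixed) plus one region group per taenia coli.
    """
    if n_segments < 1:
        raise GenerationError("n_segments must be >= 1")
    cs = cross_section
    cl = centerline
    r_min, s_at = cl.min_bend_radius()
    if r_min < cs.max_outer_radius():
        raise GenerationError(
            f"centerline bend radius {r_min:.3f} mm at arc length {s_at:.2f} mm "
            f"is smaller than the tube radius {cs.max_outer_radius():.3f} mm "
            "(self-intersecting sweep)"
        )

    na, ns = cs.n_around, n_segments
    L = cl.length

    def fmap(theta: float, s: float, t: float) -> np.ndarray:
        """Physical position at circumferential angle theta (rad), arc length
        s (mm), transmural coordinate t in [0,1] (inner->outer)."""
        p, _, e1, e2 = cl.frame(s)
        th = np.asarray(theta, dtype=float)
        sf = np.asarray(s, dtype=float) / L
        rc = cs.core_radius(th, sf, ns)
        inner = rc - cs.wall_thickness / 2.0
        outer = rc + cs.wall_thickness / 2.0 + cs.taenia_bump(th)
        rho = inner + t * (outer - inner)
        return p + rho * (np.cos(th) * e1 + np.sin(th) * e2)

    dtheta = 2 * math.pi / na
    ds = L / ns
    h_th, h_s, h_t = 1e-3, max(L * 1e-4, 1e-6), 1e-3

    def params_at(theta: float, s: float, t: float) -> np.ndarray:
        # slots: value, d1(theta), d2(s), d12, d3(t), d13, d23, d123 — scaled
        # to element xi spans (dtheta, ds, 1)
        def f(a, b, c):
            return fmap(a, b, c)

        def D(fun, axis, step):
            def g(a, b, c):
                args = [a, b, c]
                lo, hi = list(args), list(args)
                lo[axis] -= step
                hi[axis] += step
                return (fun(*hi) - fun(*lo)) / (2 * step)

            return g

        f1 = D(f, 0, h_th)
        f2 = D(f, 1, h_s)
        f3 = D(f, 2, h_t)
        f12 = D(f1, 1, h_s)
        f13 = D(f1, 2, h_t)
        f23 = D(f2, 2, h_t)
        f123 = D(f12, 2, h_t)
        blk = np.empty((3, 8))
        blk[:, 0] = f(theta, s, t)
        blk[:, 1] = f1(theta, s, t) * dtheta
        blk[:, 2] = f2(theta, s, t) * ds
        blk[:, 3] = f12(theta, s, t) * dtheta * ds
        blk[:, 4] = f3(theta, s, t)
        blk[:, 5] = f13(theta, s, t) * dtheta
        blk[:, 6] = f23(theta, s, t) * ds
        blk[:, 7] = f123(theta, s, t) * dtheta * ds
        return blk

    mesh = Mesh()
    mesh.declare_field(field, 3)

    def nid(i: int, j: int, k: int) -> int:
        return 1 + k + 2 * ((j % na) + na * i)

    for i in range(ns + 1):
        s = i * ds
        for j in range(na):
            theta = j * dtheta
            for k in (0, 1):
                node = Node(nid(i, j, k))
                node.set_field(field, params_at(theta, s, float(k)))
                mesh.add_node(node)

    def eid(i: int, j: int) -> int:
        return 1 + j + na * i

    for i in range(ns):
        for j in range(na):
            corners = []
            for c3 in (0, 1):
                for c2 in (0, 1):
                    for c1 in (0, 1):
                        corners.append(nid(i + c2, j + c1, c3))
            mesh.add_element(Element(eid(i, j), 3, tuple(corners)))

    pre = f"{group_prefix} " if group_prefix else ""
    all_eids = set(mesh.elements)
    inner = AnnotationGroup(term=f"{pre}inner surface", kind="region")
    outer = AnnotationGroup(term=f"{pre}outer surface", kind="region")
    for e in all_eids:
        inner.faces.add((e, 3, 0))
        outer.faces.add((e, 3, 1))
    inner.elements = set(all_eids)
    outer.elements = set(all_eids)
    for i in range(ns + 1):
        for j in range(na):
            inner.nodes.add(nid(i, j, 0))
            outer.nodes.add(nid(i, j, 1))
    start = AnnotationGroup(term=f"{pre}start", kind="landmark")
    end = AnnotationGroup(term=f"{pre}end", kind="landmark")
    for j in range(na):
        start.faces.add((eid(0, j), 2, 0))
        end.faces.add((eid(ns - 1, j), 2, 1))
        for k in (0, 1):
            start.nodes.add(nid(0, j, k))
            end.nodes.add(nid(ns, j, k))
    for g in (inner, outer, start, end):
        mesh.add_group(g)

    for idx, (centre, width, _) in enumerate(cs.taeniae, start=1):
        lo = math.radians(centre - width / 2)
        hi = math.radians(centre + width / 2)
        g = AnnotationGroup(
            term=f"{pre}taenia coli {idx}",
            ontology_id="UBERON:0012419",
            kind="region",
        )
        for i in range(ns):
            for j in range(na):
                th0, th1 = j * dtheta, (j + 1) * dtheta
                # does [th0, th1] intersect the taenia extent (mod 2pi)?
                for shift in (-2 * math.pi, 0.0, 2 * math.pi):
                    if th0 < hi + shift and th1 > lo + shift:
                        g.elements.add(eid(i, j))
                        g.faces.add((eid(i, j), 3, 1))
                        break
        mesh.add_group(g)
    return mesh


# ---------------------------------------------------------------------------
# species presets
# ---------------------------------------------------------------------------


@dataclass
class SpeciesPreset:
    """Named parameter bundle for a species-specific scaffold."""

    name: str
    organ: str  # colon | atria | body
    params: Dict = dataclass_field(default_factory=dict)


def _colon_preset(name: str) -> SpeciesPreset:
    if name == "human-colon":
        cs = CrossSectionSpec(
            base_radius=25.0,
            wall_thickness=3.0,
            n_around=12,
            taeniae=((0.0, 30.0, 1.5), (120.0, 30.0, 1.5), (240.0, 30.0, 1.5)),
            haustra_amplitude=3.0,
            haustra_wavelength=1.0,
        )
        way = [
            (-100, 0, 0), (-100, 0, 90), (-100, 0, 140), (-62, 0, 178),
            (0, 0, 190), (62, 0, 178), (100, 0, 140), (100, 0, 90), (100, 0, 0),
        ]
        return SpeciesPreset(name, "colon", dict(cross_section=cs, waypoints=way, n_segments=8))
    if name == "pig-colon":
        cs = CrossSectionSpec(
            base_radius=20.0,
            wall_thickness=2.5,
            n_around=12,
            taeniae=((0.0, 25.0, 1.2), (180.0, 25.0, 1.2)),
            haustra_amplitude=2.5,
            haustra_wavelength=1.0,
        )
        # inward-winding spiral (the pig colon is coiled)
        way = [
            (
                (90.0 - 14.0 * t) * math.cos(2.2 * math.pi * t),
                (90.0 - 14.0 * t) * math.sin(2.2 * math.pi * t),
                18.0 * t,
            )
            for t in np.linspace(0.0, 1.0, 12)
        ]
        return SpeciesPreset(name, "colon", dict(cross_section=cs, waypoints=way, n_segments=10))
    if name == "mouse-colon":
        cs = CrossSectionSpec(
            base_radius=1.25, wall_thickness=0.3, n_around=8,
            taeniae=(), haustra_amplitude=0.0,
        )
        way = [(0, 0, 0), (0, 0, 10), (2, 0, 20), (6, 0, 28), (12, 0, 34)]
        return SpeciesPreset(name, "colon", dict(cross_section=cs, waypoints=way, n_segments=8))
    raise GenerationError(f"unknown colon preset {name!r}")


def make_colon(preset) -> Mesh:
    """Colon scaffold for a species preset (or a SpeciesPreset instance)."""
    if isinstance(preset, str):
        preset = _colon_preset(preset)
    p = preset.params
    mesh = build_tube(p["cross_section"], Centerline(p["waypoints"]), p["n_segments"])
    colon = AnnotationGroup(
        term="colon", ontology_id="UBERON:0001155", kind="region",
        elements=set(mesh.elements), abbrev="COL",
    )
    mesh.add_group(colon)
    return mesh


# atrial region catalogue: (term, abbrev, ontology id)
_ATRIA_TERMS = {
    "LA": ("left atrium", "UBERON:0002079"),
    "RA": ("right atrium", "UBERON:0002078"),
    "LAA": ("left atrial auricle", "UBERON:0006630"),
    "RAA": ("right atrial auricle", "UBERON:0006631"),
    "IVC": ("inferior vena cava", "UBERON:0001072"),
    "SVC": ("superior vena cava", "UBERON:0001585"),
}
_PV_ONTOLOGY = "UBERON:0002016"


def _region_tube(
    term: str,
    abbrev: str,
    ontology: str,
    waypoints,
    radius: float,
    wall: float,
    n_around: int = 8,
    n_segments: int = 2,
) -> Mesh:
    cs = CrossSectionSpec(base_radius=radius, wall_thickness=wall, n_around=n_around)
    mesh = build_tube(cs, Centerline(waypoints), n_segments)
    # endocardial + epicardial surfaces and the open end rims bound the
    # region's tissue volume; the rims make the axial extent data-visible
    faces = (
        set(mesh.group("outer surface").faces)
        | set(mesh.group("inner surface").faces)
        | set(mesh.group("start").faces)
        | set(mesh.group("end").faces)
    )
    mesh.groups = []  # region group replaces the generic tube groups
    mesh.add_group(
        AnnotationGroup(
            term=term,
            abbrev=abbrev,
            ontology_id=ontology,
            kind="region",
            elements=set(mesh.elements),
            nodes=set(mesh.nodes),
            faces=faces,
        )
    )
    return mesh


def make_atria(
    preset: Optional[str] = None,
    n_pulmonary_veins: Optional[int] = None,
    has_ivc: bool = True,
    has_svc: bool = True,
    la_radius: float = 2.0,
    ra_radius: float = 2.2,
    scale: float = 1.0,
) -> Mesh:
    """Atrial scaffold: chambers, auricles, pulmonary veins and caval veins
    as separate annotated manifolds.

    With a species preset the vein count and names follow the species (human
    4 pulmonary veins, pig 2, rat 3); with explicit parameters the veins are
    named "pulmonary vein 1..n".
    """
    pv_names: List[Tuple[str, str]]
    if preset is not None:
        if preset == "rat-atria":
            scale, la_radius, ra_radius = 1.0, 2.0, 2.2
            pv_names = [
                ("left pulmonary vein", "LPV"),
                ("middle pulmonary vein", "MPV"),
                ("right pulmonary vein", "RPV"),
            ]
        elif preset == "human-atria":
            scale, la_radius, ra_radius = 8.0, 2.2, 2.4
            pv_names = [
                ("left superior pulmonary vein", "LSPV"),
                ("left inferior pulmonary vein", "LIPV"),
                ("right superior pulmonary vein", "RSPV"),
                ("right inferior pulmonary vein", "RIPV"),
            ]
        elif preset == "pig-atria":
            scale, la_radius, ra_radius = 5.0, 2.1, 2.3
            pv_names = [
                ("left pulmonary vein", "LPV"),
                ("right pulmonary vein", "RPV"),
            ]
        else:
            raise GenerationError(f"unknown atria preset {preset!r}")
    else:
        if n_pulmonary_veins is None or not 1 <= n_pulmonary_veins <= 6:
            raise GenerationError("n_pulmonary_veins must be in 1..6")
        pv_names = [
            (f"pulmonary vein {i + 1}", f"PV{i + 1}") for i in range(n_pulmonary_veins)
        ]

    S = scale
    pieces: List[Mesh] = []
    la_t, la_o = _ATRIA_TERMS["LA"]
    ra_t, ra_o = _ATRIA_TERMS["RA"]
    pieces.append(
        _region_tube(la_t, "LA", la_o, [(-2.5 * S, 0, 0), (-2.5 * S, 0, 3.0 * S)],
                     la_radius * S, 0.5 * S)
    )
    pieces.append(
        _region_tube(ra_t, "RA", ra_o, [(2.5 * S, 0, 0), (2.5 * S, 0, 3.0 * S)],
                     ra_radius * S, 0.5 * S)
    )
    laa_t, laa_o = _ATRIA_TERMS["LAA"]
    pieces.append(
        _region_tube(laa_t, "LAA", laa_o,
                     [(-4.8 * S, 0.8 * S, 2.0 * S), (-6.2 * S, 1.5 * S, 2.6 * S)],
                     0.9 * S, 0.3 * S, n_segments=1)
    )
    raa_t, raa_o = _ATRIA_TERMS["RAA"]
    pieces.append(
        _region_tube(raa_t, "RAA", raa_o,
                     [(4.9 * S, 0.8 * S, 2.0 * S), (6.3 * S, 1.5 * S, 2.6 * S)],
                     0.9 * S, 0.3 * S, n_segments=1)
    )
    # pulmonary-vein stubs fanned across the left-atrial roof
    n_pv = len(pv_names)
    for i, (term, abbrev) in enumerate(pv_names):
        frac = (i + 0.5) / n_pv - 0.5  # -0.5..0.5 across the roof
        x0 = (-2.5 + 2.4 * frac) * S
        y0 = (0.6 if i % 2 == 0 else -0.6) * S
        pieces.append(
            _region_tube(term, abbrev, _PV_ONTOLOGY,
                         [(x0, y0, 3.1 * S), (x0 + 0.5 * S * frac, y0 * 1.6, 4.5 * S)],
                         0.5 * S, 0.15 * S, n_segments=1)
        )
    if has_ivc:
        t, o = _ATRIA_TERMS["IVC"]
        pieces.append(
            _region_tube(t, "IVC", o,
                         [(2.5 * S, 0.2 * S, -0.1 * S), (2.8 * S, 0.5 * S, -1.6 * S)],
                         0.8 * S, 0.2 * S, n_segments=1)
        )
    if has_svc:
        t, o = _ATRIA_TERMS["SVC"]
        pieces.append(
            _region_tube(t, "SVC", o,
                         [(2.5 * S, 0.2 * S, 3.1 * S), (2.8 * S, 0.5 * S, 4.6 * S)],
                         0.8 * S, 0.2 * S, n_segments=1)
        )
    return merge_meshes(pieces)


def make_body(
    length: float = 200.0,
    core_radius: float = 18.0,
    n_axial_segments: int = 6,
    n_around: int = 8,
    diaphragm_position: float = 0.6,
    outer_radius: Optional[float] = None,
    field: str = "coordinates",
) -> Mesh:
    """Whole-body scaffold: a cylindrical visceral core surrounded by an
    outer layer carrying the spinal cord, with the core divided by the
    diaphragm into thorax (cranial) and abdomen (caudal).

    The body axis is z in [0, length]; dorsal is +y.  One axial node station
    is placed exactly at ``diaphragm_position * length``.
    """
    if not 0.0 < diaphragm_position < 1.0:
        raise GenerationError("diaphragm_position must be in (0, 1)")
    if n_axial_segments < 2:
        raise GenerationError("need >= 2 axial segments to place the diaphragm")
    if n_around < 4:
        raise GenerationError("n_around must be >= 4")
    outer_radius = outer_radius if outer_radius is not None else 1.4 * core_radius
    r0 = 0.15 * core_radius
    radii = (r0, core_radius, outer_radius)

    k = min(max(int(round(diaphragm_position * n_axial_segments)), 1), n_axial_segments - 1)
    z_dia = diaphragm_position * length
    stations = np.concatenate(
        [np.linspace(0.0, z_dia, k + 1), np.linspace(z_dia, length, n_axial_segments - k + 1)[1:]]
    )

    mesh = Mesh()
    mesh.declare_field(field, 3)
    dtheta = 2 * math.pi / n_around

    def nid(i: int, j: int, st: int) -> int:
        return 1 + st + 3 * ((j % n_around) + n_around * i)

    for i, z in enumerate(stations):
        dz_lo = stations[i] - stations[i - 1] if i > 0 else stations[1] - stations[0]
        dz_hi = stations[i + 1] - stations[i] if i < n_axial_segments else dz_lo
        dz = 0.5 * (dz_lo + dz_hi)
        for j in range(n_around):
            th = j * dtheta
            c, s = math.cos(th), math.sin(th)
            for st, r in enumerate(radii):
                dr = (radii[min(st + 1, 2)] - radii[max(st - 1, 0)]) / (
                    (1 if st in (0, 2) else 2)
                )
                blk = np.zeros((3, 8))
                blk[:, 0] = (r * c, r * s, z)
                blk[:, 1] = (-r * s * dtheta, r * c * dtheta, 0.0)
                blk[:, 2] = (0.0, 0.0, dz)
                blk[:, 4] = (dr * c, dr * s, 0.0)
                blk[:, 5] = (-dr * s * dtheta, dr * c * dtheta, 0.0)
                node = Node(nid(i, j, st))
                node.set_field(field, blk)
                mesh.add_node(node)

    def eid(i: int, j: int, layer: int) -> int:
        return 1 + layer + 2 * ((j % n_around) + n_around * i)

    for i in range(n_axial_segments):
        for j in range(n_around):
            for layer in (0, 1):
                corners = []
                for c3 in (0, 1):
                    for c2 in (0, 1):
                        for c1 in (0, 1):
                            corners.append(nid(i + c2, j + c1, layer + c3))
                mesh.add_element(Element(eid(i, j, layer), 3, tuple(corners)))

    core = {eid(i, j, 0) for i in range(n_axial_segments) for j in range(n_around)}
    thorax = AnnotationGroup(term="thorax", ontology_id="UBERON:0000915", kind="region")
    abdomen = AnnotationGroup(term="abdomen", ontology_id="UBERON:0000916", kind="region")
    for i in range(n_axial_segments):
        for j in range(n_around):
            (thorax if i >= k else abdomen).elements.add(eid(i, j, 0))
    diaphragm = AnnotationGroup(
        term="diaphragm", ontology_id="UBERON:0001103", kind="landmark"
    )
    for j in range(n_around):
        diaphragm.faces.add((eid(k, j, 0), 2, 0))
        for st in (0, 1):
            diaphragm.nodes.add(nid(k, j, st))
    j_dorsal = min(range(n_around), key=lambda j: abs(j * dtheta - math.pi / 2))
    cord = AnnotationGroup(
        term="spinal cord", ontology_id="UBERON:0002240", kind="landmark",
        nodes={nid(i, j_dorsal, 2) for i in range(n_axial_segments + 1)},
    )
    skin = AnnotationGroup(term="skin", ontology_id="UBERON:0002097", kind="region")
    for i in range(n_axial_segments):
        for j in range(n_around):
            skin.faces.add((eid(i, j, 1), 3, 1))
            skin.elements.add(eid(i, j, 1))
    skin.nodes = {
        nid(i, j, 2) for i in range(n_axial_segments + 1) for j in range(n_around)
    }
    for g in (thorax, abdomen, diaphragm, cord, skin):
        mesh.add_group(g)
    return mesh


# ---------------------------------------------------------------------------
# preset registry
# ---------------------------------------------------------------------------

PRESETS: Tuple[str, ...] = (
    "human-colon", "pig-colon", "mouse-colon",
    "human-atria", "pig-atria", "rat-atria",
    "rat-body",
)


def generate_preset(name: str, **overrides) -> Mesh:
    """Generate the scaffold for any named species preset."""
    if name.endswith("-colon"):
        return make_colon(name)
    if name.endswith("-atria"):
        return make_atria(preset=name)
    if name == "rat-body":
        return make_body(**overrides)
    raise GenerationError(f"unknown preset {name!r}; choose one of {PRESETS}")


# ---------------------------------------------------------------------------
# mesh utilities
# ---------------------------------------------------------------------------


def merge_meshes(meshes: Sequence[Mesh]) -> Mesh:
    """Disjoint union of meshes with renumbered node/element ids."""
    out = Mesh()
    n_off = 0
    e_off = 0
    for m in meshes:
        for f, nc in m.fields.items():
            out.fields.setdefault(f, nc)
        for n in sorted(m.nodes.values(), key=lambda n: n.id):
            out.add_node(Node(n.id + n_off, {f: b.copy() for f, b in n.params.items()}))
        for e in sorted(m.elements.values(), key=lambda e: e.id):
            out.add_element(
                Element(e.id + e_off, e.dimension,
                        tuple(n + n_off for n in e.nodes), e.versions)
            )
        for g in m.groups:
            out.add_group(
                AnnotationGroup(
                    term=g.term, ontology_id=g.ontology_id, kind=g.kind,
                    abbrev=g.abbrev,
                    elements={e + e_off for e in g.elements},
                    nodes={n + n_off for n in g.nodes},
                    faces={(e + e_off, ax, sd) for e, ax, sd in g.faces},
                )
            )
        n_off += max(m.nodes, default=0)
        e_off += max(m.elements, default=0)
    return out


def _canonical_face_key(corners: Tuple[int, int, int, int], u: Fraction, v: Fraction):
    """Orientation-independent key for a point on a quad face."""
    best = None
    for swap in (False, True):
        for fu in (False, True):
            for fv in (False, True):
                uu, vv = (v, u) if swap else (u, v)
                cs = corners
                if swap:
                    cs = (cs[0], cs[2], cs[1], cs[3])
                if fu:
                    cs = (cs[1], cs[0], cs[3], cs[2])
                    uu = 1 - uu
                if fv:
                    cs = (cs[2], cs[3], cs[0], cs[1])
                    vv = 1 - vv
                cand = (cs, uu, vv)
                if best is None or cand < best:
                    best = cand
    return ("f",) + best[0] + (best[1], best[2])


def refine(mesh: Mesh, factors: Sequence[int]) -> Mesh:
    """Subdivide every element by the given factor per xi direction.

    New nodal parameters are sampled from the parent interpolation (values
    and chain-rule-scaled derivatives), so the geometry at any former
    material location is unchanged; annotation groups propagate to child
    elements/faces and original corner nodes keep their ids.
    """
    factors = tuple(int(f) for f in factors)
    if len(factors) != 3 or any(f < 1 for f in factors):
        raise GenerationError("factors must be 3 integers >= 1")

    out = Mesh()
    out.fields = dict(mesh.fields)
    key_to_nid: Dict = {}
    next_nid = max(mesh.nodes, default=0) + 1
    child_of: Dict[int, List[int]] = {}
    face_children: Dict[Tuple[int, int, int], List[Tuple[int, int, int]]] = {}
    next_eid = 1

    def point_key(e: Element, fr: Tuple[Fraction, ...]):
        d = e.dimension
        onb = [f in (0, 1) for f in fr]
        free = [i for i in range(d) if not onb[i]]
        if len(free) == 0:
            c = sum((int(fr[i]) << i) for i in range(d))
            return ("n", e.nodes[c])
        if len(free) == 1:
            i = free[0]
            fixed = sum((int(fr[j]) << j) for j in range(d) if j != i)
            a = e.nodes[fixed]
            b = e.nodes[fixed | (1 << i)]
            t = fr[i]
            return ("e", a, b, t) if a < b else ("e", b, a, 1 - t)
        if len(free) == 2:
            i, j = free
            fixed = sum((int(fr[kk]) << kk) for kk in range(d) if kk not in (i, j))
            cs = (
                e.nodes[fixed],
                e.nodes[fixed | (1 << i)],
                e.nodes[fixed | (1 << j)],
                e.nodes[fixed | (1 << i) | (1 << j)],
            )
            return _canonical_face_key(cs, fr[i], fr[j])
        return ("i", e.id) + fr

    for eid in sorted(mesh.elements):
        e = mesh.elements[eid]
        d = e.dimension
        f = factors[:d]
        lattice: Dict[Tuple[int, ...], int] = {}
        ranges = [range(fi + 1) for fi in f]
        import itertools as _it

        for idx in _it.product(*ranges):
            fr = tuple(Fraction(idx[i], f[i]) for i in range(d))
            key = point_key(e, fr)
            nid = key_to_nid.get(key)
            if nid is None:
                if key[0] == "n":
                    nid = key[1]
                else:
                    nid = next_nid
                    next_nid += 1
                key_to_nid[key] = nid
                node = Node(nid)
                xi = tuple(float(x) for x in fr)
                for field in mesh.fields:
                    if field not in mesh.nodes[e.nodes[0]].params:
                        continue
                    nslots = 2**d
                    blk = np.zeros((mesh.fields[field], 8))
                    for s in range(nslots):
                        deriv = tuple((s >> i) & 1 for i in range(d))
                        val = eval_field(mesh, field, MaterialPoint(e.id, xi), deriv)
                        scale = 1.0
                        for i in range(d):
                            if deriv[i]:
                                scale /= f[i]
                        blk[:, s] = val * scale
                    node.set_field(field, blk)
                if nid not in out.nodes:
                    out.add_node(node)
            lattice[idx] = nid

        kids = []
        for rcell in _it.product(*[range(fi) for fi in reversed(f)]):
            cell = rcell[::-1]  # xi1 varies fastest in child numbering
            corners = []
            for c in range(2**d):
                idx = tuple(cell[i] + ((c >> i) & 1) for i in range(d))
                corners.append(lattice[idx])
            ce = Element(next_eid, d, tuple(corners))
            out.add_element(ce)
            kids.append(next_eid)
            for axis in range(1, d + 1):
                for side in (0, 1):
                    if cell[axis - 1] == (0 if side == 0 else f[axis - 1] - 1):
                        face_children.setdefault((e.id, axis, side), []).append(
                            (next_eid, axis, side)
                        )
            next_eid += 1
        child_of[e.id] = kids

    for g in mesh.groups:
        ng = AnnotationGroup(
            term=g.term, ontology_id=g.ontology_id, kind=g.kind, abbrev=g.abbrev
        )
        for eid in g.elements:
            ng.elements.update(child_of.get(eid, []))
        ng.nodes = {n for n in g.nodes if n in out.nodes}
        for face in g.faces:
            ng.faces.update(face_children.get(face, []))
        out.add_group(ng)
    return out
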