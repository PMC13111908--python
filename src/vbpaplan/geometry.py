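"""Parametric vessel geometry: centerlines, lesions, tube meshes, trees.

A vessel is represented as a 3-D centerline with a circular cross-section of
known radius at every arclength station. This is the representation every
virtual-dilation operator edits: lesions and balloons act on the 1-D radius
profile, and the full 3-D lumen surface is recovered by sweeping circles
along the centerline. Pulmonary anatomy is a rooted tree of such segments,
with the main pulmonary artery as generation 0 and the right/left pulmonary
arteries as generation 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .errors import (
    InvalidGeometryError,
    OutOfRangeError,
    SegmentLookupError,
    TopologyError,
    ValidationError,
)

__all__ = [
    "Centerline",
    "LesionSpec",
    "VesselModel",
    "SurfaceMesh",
    "TreeSegment",
    "VesselTree",
    "build_vessel",
    "apply_lesion",
    "lesion_shape",
    "tube_surface_mesh",
    "build_tree",
]


# ---------------------------------------------------------------------------
# Centerline


@dataclass(frozen=True)
class Centerline:
    """Ordered 3-D polyline with cumulative arclength, both in mm.

    Invariants: at least two points, consecutive points distinct, arclength
    strictly increasing and starting at 0.
    """

    points: np.ndarray  # (n, 3) mm
    arclength: np.ndarray  # (n,) mm

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        s = np.asarray(self.arclength, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
            raise InvalidGeometryError(
                f"centerline needs >=2 points of dim 3, got shape {pts.shape}"
            )
        if s.shape != (pts.shape[0],):
            raise InvalidGeometryError("arclength must have one value per point")
        if s[0] != 0.0:
            raise InvalidGeometryError("arclength must start at 0")
        if not np.all(np.diff(s) > 0):
            raise InvalidGeometryError(
                "arclength must be strictly increasing (duplicate points?)"
            )
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "arclength", s)

    @classmethod
    def from_points(cls, points) -> "Centerline":
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
            raise InvalidGeometryError(
                f"centerline needs >=2 points of dim 3, got shape {pts.shape}"
            )
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg <= 0):
            raise InvalidGeometryError("consecutive centerline points must be distinct")
        s = np.concatenate([[0.0], np.cumsum(seg)])
        return cls(points=pts, arclength=s)

    @property
    def length(self) -> float:
        return float(self.arclength[-1])

    @property
    def n_stations(self) -> int:
        return self.points.shape[0]

    def resample(self, n: int) -> "Centerline":
        """Resample to ``n`` arclength-uniform stations (linear in segments)."""
        if n < 2:
            raise ValidationError("need at least 2 stations")
        s_new = np.linspace(0.0, self.length, n)
        pts = np.column_stack(
            [np.interp(s_new, self.arclength, self.points[:, k]) for k in range(3)]
        )
        return Centerline.from_points(pts)

    def tangents(self) -> np.ndarray:
        """Unit tangents by central differences (one-sided at the ends)."""
        t = np.gradient(self.points, self.arclength, axis=0)
        return t / np.linalg.norm(t, axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Lesions


@dataclass(frozen=True)
class LesionSpec:
    """A focal stenosis on the radius profile.

    kind
        ``"web"`` — short diaphragm-like intraluminal web: an abrupt
        orifice-type constriction with steep shoulders whose axial extent is
        at most one local diameter (``length <= 2 * local radius``).
        ``"ring"`` — ring-like stenosis: an extended smooth circumferential
        narrowing (``length > 2 * local radius``).
    center_s
        Arclength position of the throat, mm.
    length
        Axial extent of the lesion, mm. The radius profile is modified only
        inside ``[center_s - length/2, center_s + length/2]``.
    severity
        Fraction of the reference cross-section *area* removed at the
        throat, in (0, 1): throat area = (1 - severity) x reference area.
    """

    kind: str
    center_s: float
    length: float
    severity: float

    def __post_init__(self):
        if self.kind not in ("web", "ring"):
            raise ValidationError(f"lesion kind must be 'web' or 'ring', got {self.kind!r}")
        if not (0.0 < self.severity < 1.0):
            raise ValidationError(f"severity must lie in (0,1), got {self.severity}")
        if self.length <= 0:
            raise ValidationError("lesion length must be positive")

    @property
    def s_min(self) -> float:
        return self.center_s - 0.5 * self.length

    @property
    def s_max(self) -> float:
        return self.center_s + 0.5 * self.length


def lesion_shape(lesion: LesionSpec, s: np.ndarray) -> np.ndarray:
    """Axial weight w(s) in [0, 1] of a lesion: 1 at the throat, 0 outside.

    The local cross-section area is scaled by ``1 - severity * w(s)``, so the
    radius factor is ``sqrt(1 - severity * w)``.

    * ring — raised-cosine dip over the full lesion length (smooth taper).
    * web — near-rectangular diaphragm: plateau of width
      ``min(length, diaphragm width)`` with steep tanh shoulders; weight is
      clipped to exactly zero outside the lesion extent so the profile is
      bit-identical elsewhere.
    """
    s = np.asarray(s, dtype=float)
    w = np.zeros_like(s)
    inside = (s >= lesion.s_min) & (s <= lesion.s_max)
    if lesion.kind == "ring":
        w[inside] = 0.5 * (
            1.0 + np.cos(2.0 * np.pi * (s[inside] - lesion.center_s) / lesion.length)
        )
    else:  # web: product-of-sigmoids plateau with steep shoulders
        half = 0.5 * lesion.length
        # shoulder steepness: sharp relative to the diaphragm width
        tau = max(lesion.length / 12.0, 1.0e-9)
        x = s[inside] - lesion.center_s
        up = 0.5 * (1.0 + np.tanh((x + 0.75 * half) / tau))
        down = 0.5 * (1.0 + np.tanh((0.75 * half - x) / tau))
        # normalize so the throat weight is exactly 1 (tanh plateau < 1)
        w0 = (0.5 * (1.0 + np.tanh(0.75 * half / tau))) ** 2
        w[inside] = up * down / w0
    return np.clip(w, 0.0, 1.0)


# ---------------------------------------------------------------------------
# VesselModel


@dataclass(frozen=True)
class VesselModel:
    """Centerline + radius-per-station description of one vessel segment."""

    centerline: Centerline
    radius: np.ndarray  # (n,) mm, > 0
    lesions: tuple = ()
    name: str = "vessel"

    def __post_init__(self):
        r = np.asarray(self.radius, dtype=float)
        if r.shape != (self.centerline.n_stations,):
            raise InvalidGeometryError(
                "radius must be sampled at every centerline station"
            )
        if np.any(r <= 0):
            raise InvalidGeometryError("radius must be positive everywhere")
        object.__setattr__(self, "radius", r)
        object.__setattr__(self, "lesions", tuple(self.lesions))

    @property
    def s(self) -> np.ndarray:
        return self.centerline.arclength

    @property
    def length(self) -> float:
        return self.centerline.length

    def radius_at(self, s) -> np.ndarray:
        """Linear interpolation of the radius profile at arclength ``s``."""
        return np.interp(s, self.s, self.radius)

    def area(self) -> np.ndarray:
        """Cross-section area per station, mm²."""
        return np.pi * self.radius**2

    def min_radius(self) -> float:
        return float(self.radius.min())

    def with_radius(self, radius, lesions=None) -> "VesselModel":
        return replace(
            self,
            radius=np.asarray(radius, dtype=float),
            lesions=self.lesions if lesions is None else tuple(lesions),
        )


def build_vessel(centerline_spec, base_radius: float, stations: int = 101,
                 name: str = "vessel") -> VesselModel:
    """Build a uniform-radius vessel from a centerline point set.

    ``centerline_spec`` is an (m, 3) array of points (mm); it is resampled to
    ``stations`` arclength-uniform stations. ``base_radius`` (mm) is applied
    uniformly.
    """
    if base_radius <= 0:
        raise ValidationError("base_radius must be positive")
    if stations < 2:
        raise ValidationError("need at least 2 stations")
    cl = Centerline.from_points(centerline_spec).resample(stations)
    return VesselModel(centerline=cl, radius=np.full(stations, float(base_radius)),
                       name=name)


def apply_lesion(vessel: VesselModel, lesion: LesionSpec) -> VesselModel:
    """Narrow the vessel's radius profile by a focal stenosis.

    The throat area equals ``(1 - severity)`` times the local reference area;
    outside ``[center_s ± length/2]`` the radius is bit-identical to the
    input. The morphology constraint is checked against the local radius at
    the lesion center: webs must be short (length ≤ local diameter), rings
    long (length > local diameter).
    """
    if not (0.0 <= lesion.s_min and lesion.s_max <= vessel.length):
        raise OutOfRangeError(
            f"lesion [{lesion.s_min:.2f}, {lesion.s_max:.2f}] mm outside vessel "
            f"[0, {vessel.length:.2f}] mm"
        )
    r_local = float(vessel.radius_at(lesion.center_s))
    if lesion.kind == "web" and lesion.length > 2.0 * r_local:
        raise ValidationError(
            f"web lesion length {lesion.length} mm exceeds local diameter "
            f"{2 * r_local:.2f} mm"
        )
    if lesion.kind == "ring" and lesion.length <= 2.0 * r_local:
        raise ValidationError(
            f"ring lesion length {lesion.length} mm must exceed local diameter "
            f"{2 * r_local:.2f} mm"
        )
    w = lesion_shape(lesion, vessel.s)
    r_new = vessel.radius * np.sqrt(1.0 - lesion.severity * w)
    return vessel.with_radius(r_new, lesions=vessel.lesions + (lesion,))


# ---------------------------------------------------------------------------
# Surface meshing


@dataclass
class SurfaceMesh:
    """Triangulated lumen surface with per-face metadata.

    ``face_s`` records the arclength (mm) of each lateral face centroid along
    the source vessel; cap faces carry the end arclength. ``distal`` marks
    faces belonging to distal vasculature (used by the wall-shear exclusion
    rule); ``region_tag`` is a free-form label per face.
    """

    vertices: np.ndarray  # (nv, 3) mm
    triangles: np.ndarray  # (nf, 3) int
    face_s: np.ndarray  # (nf,) mm
    region_tag: np.ndarray  # (nf,) object/str
    distal: np.ndarray  # (nf,) bool

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.triangles.min(initial=0) < 0 or (
            self.triangles.size and self.triangles.max() >= len(self.vertices)
        ):
            raise InvalidGeometryError("triangle indices out of range")
        areas = self.face_areas()
        if np.any(areas <= 0):
            raise InvalidGeometryError("all face areas must be positive")

    def face_areas(self) -> np.ndarray:
        """Triangle areas, mm²."""
        v = self.vertices
        t = self.triangles
        a = v[t[:, 1]] - v[t[:, 0]]
        b = v[t[:, 2]] - v[t[:, 0]]
        return 0.5 * np.linalg.norm(np.cross(a, b), axis=1)

    def face_centroids(self) -> np.ndarray:
        return self.vertices[self.triangles].mean(axis=1)

    def face_normals(self) -> np.ndarray:
        """Unit normals with the winding orientation (outward for tubes
        produced by :func:`tube_surface_mesh`)."""
        v = self.vertices
        t = self.triangles
        n = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
        return n / np.linalg.norm(n, axis=1, keepdims=True)

    @property
    def n_faces(self) -> int:
        return len(self.triangles)

    def total_area(self) -> float:
        return float(self.face_areas().sum())


def _transport_frames(cl: Centerline) -> tuple[np.ndarray, np.ndarray]:
    """Parallel-transport orthonormal frames (e1, e2) normal to the tangent
    at every station; avoids torsion artifacts of Frenet frames."""
    t = cl.tangents()
    n = len(t)
    e1 = np.empty((n, 3))
    # initial normal: any vector not parallel to t[0]
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(ref, t[0])) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    v = ref - np.dot(ref, t[0]) * t[0]
    e1[0] = v / np.linalg.norm(v)
    for i in range(1, n):
        # rotate previous normal into the new tangent plane
        v = e1[i - 1] - np.dot(e1[i - 1], t[i]) * t[i]
        nv = np.linalg.norm(v)
        if nv < 1.0e-12:  # rare: tangent flipped; restart frame
            ref = np.array([1.0, 0.0, 0.0])
            v = ref - np.dot(ref, t[i]) * t[i]
            nv = np.linalg.norm(v)
        e1[i] = v / nv
    e2 = np.cross(t, e1)
    return e1, e2


def tube_surface_mesh(vessel: VesselModel, n_circ: int = 32,
                      with_caps: bool = False,
                      distal_from_s: Optional[float] = None,
                      region: str = "") -> SurfaceMesh:
    """Sweep circles of local radius along the centerline into a triangle tube.

    ``n_circ`` circumferential vertices per station (>= 8); each quad of the
    sweep is split into two triangles, so an open tube has
    ``2 * n_circ * (stations - 1)`` lateral faces. Normals point outward.
    ``distal_from_s`` flags faces with centroid arclength beyond it as distal.
    """
    if n_circ < 8:
        raise ValidationError(f"n_circ must be >= 8, got {n_circ}")
    cl = vessel.centerline
    if cl.length <= 0:
        raise InvalidGeometryError("zero-length vessel cannot be meshed")
    e1, e2 = _transport_frames(cl)
    n_st = cl.n_stations
    theta = 2.0 * np.pi * np.arange(n_circ) / n_circ
    ct, st = np.cos(theta), np.sin(theta)
    # vertices: station-major rings
    rings = (
        cl.points[:, None, :]
        + vessel.radius[:, None, None]
        * (ct[None, :, None] * e1[:, None, :] + st[None, :, None] * e2[:, None, :])
    )
    vertices = rings.reshape(-1, 3)

    tris = []
    fs = []
    for i in range(n_st - 1):
        base0 = i * n_circ
        base1 = (i + 1) * n_circ
        s_mid = 0.5 * (cl.arclength[i] + cl.arclength[i + 1])
        for j in range(n_circ):
            j2 = (j + 1) % n_circ
            a, b = base0 + j, base0 + j2
            c, d = base1 + j, base1 + j2
            # outward-facing winding
            tris.append((a, b, c))
            tris.append((b, d, c))
            fs.extend((s_mid, s_mid))
    tags = ["lateral"] * len(tris)

    if with_caps:
        v_list = [vertices]
        nv = len(vertices)
        for end, s_end in ((0, 0.0), (n_st - 1, cl.length)):
            center = cl.points[end]
            v_list.append(center[None, :])
            ci = nv
            nv += 1
            base = end * n_circ
            for j in range(n_circ):
                j2 = (j + 1) % n_circ
                if end == 0:  # inlet cap faces -s direction
                    tris.append((ci, base + j, base + j2))
                else:
                    tris.append((ci, base + j2, base + j))
                fs.append(s_end)
                tags.append("cap_inlet" if end == 0 else "cap_outlet")
        vertices = np.vstack(v_list)

    face_s = np.asarray(fs)
    distal = (
        face_s >= distal_from_s if distal_from_s is not None
        else np.zeros(len(tris), dtype=bool)
    )
    region_tag = np.asarray(
        [f"{region}:{t}" if region else t for t in tags], dtype=object
    )
    return SurfaceMesh(
        vertices=vertices,
        triangles=np.asarray(tris, dtype=np.int64),
        face_s=face_s,
        region_tag=region_tag,
        distal=np.asarray(distal, dtype=bool),
    )


# ---------------------------------------------------------------------------
# Vessel trees


@dataclass
class TreeSegment:
    """One segment of a pulmonary tree: a vessel plus topology metadata."""

    segment_id: str
    vessel: VesselModel
    parent: Optional[str]
    generation: int = 0
    side: str = "trunk"  # left | right | trunk


@dataclass
class VesselTree:
    """Rooted tree of vessel segments with flow boundary conditions.

    Generation 0 is the main pulmonary artery (root); the two generation-1
    children define the right/left sides. ``inlet_flow`` is the cardiac
    output (L/min) entering the root; every leaf carries an outlet pressure
    (Pa, default 0 — the reduced-order outflow assumption).
    """

    segments: dict  # id -> TreeSegment
    children: dict  # id -> list of child ids
    root: str
    inlet_flow: float  # L/min
    outlet_pressure: dict  # leaf id -> Pa

    def __post_init__(self):
        if self.root not in self.segments:
            raise TopologyError(f"root {self.root!r} not among segments")
        # depth/acyclicity check
        seen = set()
        stack = [(self.root, 0)]
        while stack:
            sid, depth = stack.pop()
            if sid in seen:
                raise TopologyError(f"cycle detected at segment {sid!r}")
            seen.add(sid)
            seg = self.segments[sid]
            if seg.generation != depth:
                raise TopologyError(
                    f"segment {sid!r}: generation {seg.generation} != depth {depth}"
                )
            for c in self.children.get(sid, []):
                stack.append((c, depth + 1))
        if seen != set(self.segments):
            raise TopologyError("tree is disconnected (unreachable segments)")
        for leaf in self.leaves():
            if leaf not in self.outlet_pressure:
                raise TopologyError(f"leaf {leaf!r} missing an outlet pressure")

    def leaves(self) -> list:
        return [sid for sid in self.segments if not self.children.get(sid)]

    def parent_of(self, sid: str) -> Optional[str]:
        return self.segments[sid].parent

    def generation_1(self) -> dict:
        """Map side -> segment id for the generation-1 (RPA/LPA) branches."""
        out = {}
        for sid in self.children.get(self.root, []):
            out[self.segments[sid].side] = sid
        return out

    def replace_segment(self, sid: str, vessel: VesselModel) -> "VesselTree":
        if sid not in self.segments:
            raise SegmentLookupError(sid)
        segments = dict(self.segments)
        old = segments[sid]
        segments[sid] = TreeSegment(
            segment_id=sid, vessel=vessel, parent=old.parent,
            generation=old.generation, side=old.side,
        )
        return VesselTree(
            segments=segments, children={k: list(v) for k, v in self.children.items()},
            root=self.root, inlet_flow=self.inlet_flow,
            outlet_pressure=dict(self.outlet_pressure),
        )


def build_tree(tree_spec: dict) -> VesselTree:
    """Assemble a :class:`VesselTree` from a declarative spec.

    ``tree_spec`` keys:

    segments
        list of dicts: ``id``, ``parent`` (None for root), ``length`` mm,
        ``radius`` mm, optional ``stations`` (default 21), optional
        ``direction`` (3-vector, default +z with a small splay per side),
        optional ``side`` override.
    inlet_flow
        cardiac output, L/min.
    outlet_pressure
        scalar Pa applied to all leaves, or dict per leaf id.
    inlet_extension
        optional length in local diameters prepended to the root so the
        root inflow is fully developed (default 0; 10 is the usual
        fully-developed-flow rule of thumb).

    Generations are assigned by depth (root = 0); side labels propagate from
    the generation-1 split. Maximum depth is 7 generations.
    """
    seg_specs = {s["id"]: dict(s) for s in tree_spec["segments"]}
    if len(seg_specs) != len(tree_spec["segments"]):
        raise TopologyError("duplicate segment ids")
    roots = [sid for sid, s in seg_specs.items() if s.get("parent") is None]
    if len(roots) != 1:
        raise TopologyError(f"tree must have exactly one root, found {len(roots)}")
    root = roots[0]

    children: dict = {sid: [] for sid in seg_specs}
    for sid, s in seg_specs.items():
        p = s.get("parent")
        if p is not None:
            if p not in seg_specs:
                raise TopologyError(f"segment {sid!r} references unknown parent {p!r}")
            children[p].append(sid)

    # depth-first: assign generation, side, and 3-D placement
    generation: dict = {}
    side: dict = {}
    order: list = []
    stack = [(root, 0, "trunk", None)]
    visiting = set()
    while stack:
        sid, depth, sd, parent = stack.pop()
        if sid in generation:
            raise TopologyError(f"cycle detected at segment {sid!r}")
        if depth > 7:
            raise TopologyError("tree depth exceeds 7 generations")
        generation[sid] = depth
        order.append(sid)
        visiting.add(sid)
        kids = children[sid]
        if depth == 0 and len(kids) == 2:
            # generation-1 split defines sides; honour explicit overrides
            sides = [seg_specs[k].get("side") for k in kids]
            if sides == [None, None]:
                sides = ["right", "left"]
            for k, s_lbl in zip(kids, sides):
                stack.append((k, depth + 1, s_lbl or "trunk", sid))
        else:
            for k in kids:
                stack.append((k, depth + 1, seg_specs[k].get("side", sd), sid))
        side[sid] = seg_specs[sid].get("side", sd) if depth > 0 else "trunk"

    ext_diams = float(tree_spec.get("inlet_extension", 0.0))

    # build geometry: simple splayed layout, each segment a straight vessel
    origin: dict = {root: np.zeros(3)}
    direction: dict = {}
    segments: dict = {}
    for sid in order:
        spec = seg_specs[sid]
        L = float(spec["length"])
        r = float(spec["radius"])
        if L <= 0 or r <= 0:
            raise InvalidGeometryError(f"segment {sid!r}: length and radius must be > 0")
        if "direction" in spec:
            d = np.asarray(spec["direction"], dtype=float)
            d = d / np.linalg.norm(d)
        else:
            d = _default_direction(side[sid], generation[sid])
        direction[sid] = d
        p0 = origin[sid]
        n_st = int(spec.get("stations", 21))
        extra = 0.0
        if sid == root and ext_diams > 0:
            extra = ext_diams * 2.0 * r
            p0 = p0 - extra * d
        pts = p0[None, :] + np.linspace(0.0, L + extra, n_st)[:, None] * d[None, :]
        vessel = build_vessel(pts, r, stations=n_st, name=sid)
        segments[sid] = TreeSegment(
            segment_id=sid, vessel=vessel, parent=spec.get("parent"),
            generation=generation[sid], side=side[sid],
        )
        tip = origin[sid] + L * d
        for k in children[sid]:
            origin[k] = tip

    leaves = [sid for sid in segments if not children[sid]]
    op = tree_spec.get("outlet_pressure", 0.0)
    if isinstance(op, dict):
        outlet_pressure = {sid: float(op[sid]) for sid in leaves}
    else:
        outlet_pressure = {sid: float(op) for sid in leaves}

    return VesselTree(
        segments=segments, children=children, root=root,
        inlet_flow=float(tree_spec.get("inlet_flow", 5.0)),
        outlet_pressure=outlet_pressure,
    )


def _default_direction(side_label: str, gen: int) -> np.ndarray:
    """Splay branches laterally by side so the layout is roughly planar."""
    if gen == 0 or side_label == "trunk":
        return np.array([0.0, 0.0, 1.0])
    sign = 1.0 if side_label == "right" else -1.0
    ang = np.deg2rad(25.0 + 8.0 * gen)
    return np.array([sign * np.sin(ang), 0.0, np.cos(ang)])
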