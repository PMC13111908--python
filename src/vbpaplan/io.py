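"""File formats: JSON case files, STL surfaces, VTK structured grids, CSV.

Case files (vessels and trees) are versioned JSON documents. Surface
meshes go through STL (ASCII or binary, via trimesh; per-face tags are not
part of STL and are dropped on export). Velocity fields use the legacy
ASCII VTK STRUCTURED_POINTS format with a point-data VECTORS array named
``velocity`` and optional SCALARS ``pressure`` and ``mask`` — readable by
any VTK-aware viewer. Radius-vs-arclength profiles dump to two-column CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import trimesh

from .dilation import BalloonSpec
from .errors import ValidationError
from .flow import GridSpec, VelocityField
from .geometry import (
    Centerline,
    LesionSpec,
    SurfaceMesh,
    VesselModel,
    VesselTree,
    build_tree,
)

SCHEMA_VERSION = 1

__all__ = [
    "vessel_to_dict",
    "vessel_from_dict",
    "save_vessel",
    "load_vessel",
    "tree_spec_to_json",
    "load_tree",
    "save_surface_stl",
    "load_surface_stl",
    "save_field_vtk",
    "load_field_vtk",
    "save_radius_csv",
]


# ---------------------------------------------------------------------------
# JSON cases


def vessel_to_dict(vessel: VesselModel) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "kind": "vessel",
        "name": vessel.name,
        "points": vessel.centerline.points.tolist(),
        "radius": vessel.radius.tolist(),
        "lesions": [
            {
                "kind": l.kind,
                "center_s": l.center_s,
                "length": l.length,
                "severity": l.severity,
            }
            for l in vessel.lesions
        ],
    }


def vessel_from_dict(d: dict) -> VesselModel:
    if d.get("kind") != "vessel":
        raise ValidationError("not a vessel case document")
    cl = Centerline.from_points(np.asarray(d["points"], dtype=float))
    lesions = tuple(
        LesionSpec(
            kind=l["kind"], center_s=l["center_s"],
            length=l["length"], severity=l["severity"],
        )
        for l in d.get("lesions", [])
    )
    return VesselModel(
        centerline=cl, radius=np.asarray(d["radius"], dtype=float),
        lesions=lesions, name=d.get("name", "vessel"),
    )


def save_vessel(vessel: VesselModel, path) -> None:
    Path(path).write_text(json.dumps(vessel_to_dict(vessel), indent=1))


def load_vessel(path) -> VesselModel:
    return vessel_from_dict(json.loads(Path(path).read_text()))


def tree_spec_to_json(tree_spec: dict, path) -> None:
    doc = {"schema_version": SCHEMA_VERSION, "kind": "tree", **tree_spec}
    Path(path).write_text(json.dumps(doc, indent=1))


def load_tree(path) -> VesselTree:
    doc = json.loads(Path(path).read_text())
    if doc.get("kind") != "tree":
        raise ValidationError("not a tree case document")
    return build_tree(doc)


def balloon_from_string(text: str) -> BalloonSpec:
    """Parse the clinical ``DxL@S`` shorthand, e.g. ``2.5x30@55`` for a
    2.5 mm x 30 mm balloon centered at arclength 55 mm."""
    try:
        dims, center = text.split("@")
        d, l = dims.lower().split("x")
        return BalloonSpec(
            diameter=float(d), length=float(l), center_s=float(center)
        )
    except (ValueError, AttributeError) as exc:
        raise ValidationError(
            f"balloon spec {text!r} not of the form DxL@S"
        ) from exc


# ---------------------------------------------------------------------------
# STL


def save_surface_stl(mesh: SurfaceMesh, path, ascii_stl: bool = False) -> None:
    tm = trimesh.Trimesh(
        vertices=mesh.vertices, faces=mesh.triangles, process=False
    )
    ft = "stl_ascii" if ascii_stl else "stl"
    tm.export(str(path), file_type=ft)


def load_surface_stl(path) -> SurfaceMesh:
    tm = trimesh.load_mesh(str(path), process=False)
    nf = len(tm.faces)
    return SurfaceMesh(
        vertices=np.asarray(tm.vertices, dtype=float),
        triangles=np.asarray(tm.faces, dtype=np.int64),
        face_s=np.full(nf, np.nan),
        region_tag=np.asarray(["imported"] * nf, dtype=object),
        distal=np.zeros(nf, dtype=bool),
    )


# ---------------------------------------------------------------------------
# Legacy VTK structured points (ASCII)
#
# Layout written (bit-exact contract):
#   # vtk DataFile Version 3.0 / title / ASCII / DATASET STRUCTURED_POINTS
#   DIMENSIONS nx ny nz ; ORIGIN ; SPACING ; POINT_DATA n
#   VECTORS velocity double  (x fastest, VTK node order)
#   SCALARS mask int 1 + LOOKUP_TABLE default
#   [SCALARS pressure double 1 + LOOKUP_TABLE default]
# Floats use repr-precision %.17g so a write/read round-trip is exact.


def save_field_vtk(fld: VelocityField, path, title: str = "vbpaplan field"
                   ) -> None:
    nx, ny, nz = fld.grid.shape
    n = nx * ny * nz
    # VTK expects x varying fastest -> transpose to (z, y, x) then ravel
    u = np.transpose(fld.u, (2, 1, 0, 3)).reshape(n, 3)
    mask = np.transpose(fld.mask, (2, 1, 0)).reshape(n)
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} {nz}",
        "ORIGIN {:.17g} {:.17g} {:.17g}".format(*fld.grid.origin),
        "SPACING {:.17g} {:.17g} {:.17g}".format(*fld.grid.spacing),
        f"POINT_DATA {n}",
        "VECTORS velocity double",
    ]
    lines += ["{:.17g} {:.17g} {:.17g}".format(*row) for row in u]
    lines += ["SCALARS mask int 1", "LOOKUP_TABLE default"]
    lines += [str(int(v)) for v in mask]
    if fld.pressure is not None:
        p = np.transpose(fld.pressure, (2, 1, 0)).reshape(n)
        lines += ["SCALARS pressure double 1", "LOOKUP_TABLE default"]
        lines += ["{:.17g}".format(v) for v in p]
    Path(path).write_text("\n".join(lines) + "\n")


def load_field_vtk(path) -> VelocityField:
    tokens = Path(path).read_text().split("\n")
    it = iter(tokens)
    dims = origin = spacing = None
    n = None
    u = mask = pressure = None

    def grab_floats(count, width):
        vals = []
        while len(vals) < count * width:
            vals.extend(next(it).split())
        return np.asarray(vals, dtype=float).reshape(count, width)

    for line in it:
        parts = line.split()
        if not parts:
            continue
        key = parts[0].upper()
        if key == "DIMENSIONS":
            dims = tuple(int(v) for v in parts[1:4])
        elif key == "ORIGIN":
            origin = tuple(float(v) for v in parts[1:4])
        elif key == "SPACING":
            spacing = tuple(float(v) for v in parts[1:4])
        elif key == "POINT_DATA":
            n = int(parts[1])
        elif key == "VECTORS":
            u = grab_floats(n, 3)
        elif key == "SCALARS":
            name = parts[1].lower()
            next(it)  # LOOKUP_TABLE line
            vals = grab_floats(n, 1).ravel()
            if name == "mask":
                mask = vals.astype(bool)
            elif name == "pressure":
                pressure = vals
    if dims is None or u is None:
        raise ValidationError(f"{path}: not a structured-points VTK file")
    nx, ny, nz = dims
    grid = GridSpec(origin=origin, spacing=spacing, shape=dims)
    u3 = np.transpose(u.reshape(nz, ny, nx, 3), (2, 1, 0, 3))
    m3 = (
        np.transpose(mask.reshape(nz, ny, nx), (2, 1, 0))
        if mask is not None
        else np.ones(dims, dtype=bool)
    )
    p3 = (
        np.transpose(pressure.reshape(nz, ny, nx), (2, 1, 0))
        if pressure is not None
        else None
    )
    return VelocityField(grid=grid, u=u3, mask=m3, pressure=p3)


def save_radius_csv(vessel: VesselModel, path) -> None:
    rows = ["arclength_mm,radius_mm"]
    rows += [
        f"{s:.17g},{r:.17g}" for s, r in zip(vessel.s, vessel.radius)
    ]
    Path(path).write_text("\n".join(rows) + "\n")
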