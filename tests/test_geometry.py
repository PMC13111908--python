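"""Vessel construction, lesioning, tube meshing and tree assembly."""

import numpy as np
import pytest
import trimesh

from vbpaplan.errors import (
    InvalidGeometryError,
    OutOfRangeError,
    TopologyError,
    ValidationError,
)
from vbpaplan.geometry import (
    Centerline,
    LesionSpec,
    apply_lesion,
    build_tree,
    build_vessel,
    tube_surface_mesh,
)


class TestBuildVessel:
    def test_uniform_cylinder_cross_section_area(self):
        v = build_vessel([[0, 0, 0], [0, 0, 100.0]], 10.0, 101)
        assert np.allclose(v.area(), 100.0 * np.pi)
        assert v.length == pytest.approx(100.0)

    def test_single_point_centerline_rejected(self):
        with pytest.raises(InvalidGeometryError):
            build_vessel([[0, 0, 0]], 10.0, 11)

    def test_duplicate_points_rejected(self):
        with pytest.raises(InvalidGeometryError):
            build_vessel([[0, 0, 0], [0, 0, 0], [0, 0, 1]], 1.0, 11)

    def test_helical_arclength_exceeds_chord(self):
        t = np.linspace(0, 4 * np.pi, 200)
        pts = np.column_stack([10 * np.cos(t), 10 * np.sin(t), 5 * t])
        v = build_vessel(pts, 2.0, 200)
        chord = np.linalg.norm(pts[-1] - pts[0])
        assert v.length >= chord

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValidationError):
            build_vessel([[0, 0, 0], [0, 0, 10.0]], 0.0, 11)


class TestApplyLesion:
    def test_ring_throat_radius_from_severity(self):
        # area ratio 0.25 -> radius ratio 0.5
        v = build_vessel([[0, 0, 0], [0, 0, 100.0]], 10.0, 401)
        les = apply_lesion(
            v, LesionSpec(kind="ring", center_s=50.0, length=40.0, severity=0.75)
        )
        assert les.min_radius() == pytest.approx(5.0, rel=1e-6)

    def test_web_throat_and_locality(self):
        # severity 0.96 on radius 5 -> throat radius 1; stations one
        # lesion-length away are untouched bit-exactly
        v = build_vessel([[0, 0, 0], [0, 0, 100.0]], 5.0, 801)
        lesion = LesionSpec(kind="web", center_s=50.0, length=4.0, severity=0.96)
        les = apply_lesion(v, lesion)
        assert les.min_radius() == pytest.approx(1.0, rel=1e-6)
        far = np.abs(v.s - 50.0) >= lesion.length
        assert np.array_equal(les.radius[far], v.radius[far])

    def test_lesion_beyond_vessel_end_rejected(self):
        v = build_vessel([[0, 0, 0], [0, 0, 100.0]], 10.0, 101)
        with pytest.raises(OutOfRangeError):
            apply_lesion(
                v, LesionSpec(kind="ring", center_s=150.0, length=30.0,
                              severity=0.5)
            )

    @pytest.mark.parametrize("severity", [0.0, 1.0, -0.2, 1.5])
    def test_severity_outside_open_interval_rejected(self, severity):
        with pytest.raises(ValidationError):
            LesionSpec(kind="ring", center_s=50.0, length=30.0, severity=severity)

    def test_web_morphology_length_constraint(self):
        v = build_vessel([[0, 0, 0], [0, 0, 100.0]], 5.0, 101)
        with pytest.raises(ValidationError):
            # a "web" longer than the local diameter is not a diaphragm
            apply_lesion(
                v, LesionSpec(kind="web", center_s=50.0, length=11.0,
                              severity=0.5)
            )

    def test_lesion_preserves_radius_outside_extent(self):
        v = build_vessel([[0, 0, 0], [0, 0, 100.0]], 10.0, 501)
        lesion = LesionSpec(kind="ring", center_s=40.0, length=30.0, severity=0.6)
        les = apply_lesion(v, lesion)
        outside = (v.s < lesion.s_min) | (v.s > lesion.s_max)
        assert np.array_equal(les.radius[outside], v.radius[outside])


class TestTubeSurfaceMesh:
    def test_lateral_area_matches_cylinder(self):
        v = build_vessel([[0, 0, 0], [0, 0, 100.0]], 10.0, 101)
        mesh = tube_surface_mesh(v, n_circ=64)
        exact = 2 * np.pi * 10.0 * 100.0
        assert mesh.total_area() == pytest.approx(exact, rel=0.01)

    def test_lateral_triangle_count(self):
        v = build_vessel([[0, 0, 0], [0, 0, 100.0]], 10.0, 101)
        mesh = tube_surface_mesh(v, n_circ=32, with_caps=False)
        assert mesh.n_faces == 32 * 100 * 2

    def test_too_few_circumferential_vertices_rejected(self):
        v = build_vessel([[0, 0, 0], [0, 0, 100.0]], 10.0, 11)
        with pytest.raises(ValidationError):
            tube_surface_mesh(v, n_circ=4)

    def test_area_error_halves_under_refinement(self):
        v = build_vessel([[0, 0, 0], [0, 0, 100.0]], 10.0, 51)
        exact = 2 * np.pi * 10.0 * 100.0
        err = [
            abs(tube_surface_mesh(v, n_circ=n).total_area() - exact)
            for n in (16, 32)
        ]
        assert err[1] <= 0.5 * err[0]

    def test_capped_tube_is_watertight_with_outward_normals(self):
        v = build_vessel([[0, 0, 0], [0, 0, 50.0]], 5.0, 21)
        mesh = tube_surface_mesh(v, n_circ=32, with_caps=True)
        tm = trimesh.Trimesh(
            vertices=mesh.vertices, faces=mesh.triangles, process=False
        )
        assert tm.is_watertight
        # positive signed volume means consistently outward winding
        assert tm.volume == pytest.approx(np.pi * 25.0 * 50.0, rel=0.02)


def _symmetric_spec(depth, inlet_flow=5.0):
    segments = [{"id": "root", "parent": None, "length": 40.0, "radius": 12.0}]

    def grow(pid, radius, gen):
        if gen > depth:
            return
        r = radius * 2 ** (-1 / 3)
        for k in range(2):
            sid = f"{pid}.{k}"
            segments.append(
                {"id": sid, "parent": pid, "length": 4 * r, "radius": r}
            )
            grow(sid, r, gen + 1)

    grow("root", 12.0, 1)
    return {"segments": segments, "inlet_flow": inlet_flow,
            "outlet_pressure": 0.0}


class TestBuildTree:
    def test_symmetric_two_generation_tree(self):
        tree = build_tree(_symmetric_spec(1))
        kids = tree.children["root"]
        assert len(kids) == 2
        g1 = [tree.segments[k] for k in kids]
        assert all(s.generation == 1 for s in g1)
        assert g1[0].vessel.radius[0] == g1[1].vessel.radius[0]
        assert g1[0].vessel.length == pytest.approx(g1[1].vessel.length)

    def test_seven_generation_binary_tree_has_128_leaves(self):
        tree = build_tree(_symmetric_spec(7))
        assert len(tree.leaves()) == 2**7

    def test_cyclic_spec_rejected(self):
        spec = {
            "segments": [
                {"id": "a", "parent": "b", "length": 10, "radius": 5},
                {"id": "b", "parent": "a", "length": 10, "radius": 5},
            ],
            "inlet_flow": 5.0,
        }
        with pytest.raises(TopologyError):
            build_tree(spec)

    def test_generation_labels_equal_depth(self):
        tree = build_tree(_symmetric_spec(4))

        def depth(sid):
            d = 0
            while tree.segments[sid].parent is not None:
                sid = tree.segments[sid].parent
                d += 1
            return d

        for sid in tree.segments:
            assert tree.segments[sid].generation == depth(sid)

    def test_inlet_extension_lengthens_root(self):
        base = build_tree(_symmetric_spec(1))
        spec = _symmetric_spec(1)
        spec["inlet_extension"] = 10.0  # local diameters
        ext = build_tree(spec)
        added = ext.segments["root"].vessel.length - base.segments["root"].vessel.length
        assert added == pytest.approx(10.0 * 2 * 12.0)

    def test_side_labels_propagate_from_generation_one(self):
        spec = _symmetric_spec(3)
        tree = build_tree(spec)
        right_g1, left_g1 = tree.children["root"]
        for sid, seg in tree.segments.items():
            if sid.startswith(right_g1):
                assert seg.side == "right"
            elif sid.startswith(left_g1):
                assert seg.side == "left"


class TestCenterline:
    def test_resample_preserves_endpoints_and_length(self):
        pts = np.column_stack(
            [np.linspace(0, 30, 7), np.zeros(7), np.linspace(0, 40, 7)]
        )
        cl = Centerline.from_points(pts).resample(25)
        assert cl.n_stations == 25
        assert cl.length == pytest.approx(50.0, rel=1e-6)
        assert np.allclose(cl.points[0], pts[0])
        assert np.allclose(cl.points[-1], pts[-1])
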