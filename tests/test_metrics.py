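"""Q-criterion, helicity banding, wall shear stress and PVR."""

import numpy as np
import pytest

from conftest import MU_NEWT, TUBE_LENGTH, TUBE_RADIUS
from vbpaplan.errors import (
    EmptyRegionError,
    UndefinedCompositionError,
    ValidationError,
)
from vbpaplan.flow import GridSpec, analytic_field
from vbpaplan.geometry import build_vessel, tube_surface_mesh
from vbpaplan.metrics import (
    RHCRecord,
    VortexBandVolumes,
    pvr_from_rhc,
    sawss,
    strip_sawss,
    vortex_band_volumes,
    vortex_composition,
    vortex_fields,
    wall_shear_stress,
)


def cube_grid(extent=10.0, n=33):
    return GridSpec.from_bounds(
        (-extent, -extent, -extent), (extent, extent, extent), (n, n, n)
    )


class TestVortexFields:
    def test_planar_shear_has_zero_q(self):
        fld = analytic_field("planar_shear", {"gamma": 8.0}, cube_grid())
        q_star, _, q_raw = vortex_fields(fld)
        assert np.allclose(q_raw, 0.0, atol=1e-10)
        assert np.all(q_star == 0.0)

    def test_solid_rotation_q_equals_omega_squared(self):
        om = 7.0
        fld = analytic_field("solid_rotation", {"omega": om}, cube_grid())
        _, _, q_raw = vortex_fields(fld)
        inner = (slice(1, -1),) * 3
        assert np.allclose(q_raw[inner], om**2, rtol=1e-6)

    def test_beltrami_helicity_is_unity_in_interior(self):
        fld = analytic_field(
            "beltrami_abc",
            {"A": 1.0, "B": 1.0, "C": 1.0, "wavenumber": 0.4},
            cube_grid(extent=8.0, n=49),
        )
        _, h, _ = vortex_fields(fld)
        inner = (slice(2, -2),) * 3
        assert np.all(np.abs(h[inner]) > 1.0 - 1e-3)

    def test_helicity_bounded_everywhere(self):
        fld = analytic_field(
            "vortex_wake",
            {"u_axial": 0.4, "kappa": 3.0, "n_vortices": 5,
             "core_radius": 1.2, "radius": 8.0, "seed": 3},
            GridSpec.from_bounds((-8, -8, 0), (8, 8, 32), (49, 49, 49)),
        )
        _, h, _ = vortex_fields(fld)
        assert np.all(h >= -1.0) and np.all(h <= 1.0)

    def test_planar_flow_has_zero_helicity(self):
        # 2-component z-invariant flow: u and omega are orthogonal
        fld = analytic_field("lamb_oseen",
                             {"circulation": 1e-3, "core_radius": 3.0},
                             cube_grid())
        _, h, _ = vortex_fields(fld)
        assert np.allclose(h, 0.0, atol=1e-9)

    def test_too_small_grid_rejected(self):
        grid = GridSpec(origin=(0, 0, 0), spacing=(1, 1, 1), shape=(2, 2, 2))
        fld = analytic_field("planar_shear", {"gamma": 1.0}, grid)
        from vbpaplan.errors import GradientError

        with pytest.raises(GradientError):
            vortex_fields(fld)


class TestBandVolumes:
    def test_counting_synthetic_voxels(self):
        q = np.zeros((6, 6, 6))
        h = np.zeros((6, 6, 6))
        q[:3, 0, 0] = 1.0
        h[:3, 0, 0] = 0.9  # 3 voxels exceed every band threshold
        mask = np.ones_like(q, dtype=bool)
        v = vortex_band_volumes(q, h, mask, voxel_volume=2.0)
        assert v.as_tuple() == (6.0, 6.0, 6.0)

    def test_bands_are_nested(self):
        fld = analytic_field(
            "vortex_wake",
            {"u_axial": 0.3, "kappa": 4.0, "n_vortices": 4,
             "core_radius": 1.0, "radius": 8.0, "seed": 1},
            GridSpec.from_bounds((-8, -8, 0), (8, 8, 32), (49, 49, 49)),
        )
        q, h, _ = vortex_fields(fld)
        v = vortex_band_volumes(q, h, fld.mask,
                                voxel_volume=fld.grid.voxel_volume)
        assert v.v_low >= v.v_moderate >= v.v_high

    def test_threshold_outside_unit_interval_rejected(self):
        q = h = np.zeros((4, 4, 4))
        with pytest.raises(ValidationError):
            vortex_band_volumes(q, h, np.ones_like(q, bool), q_min=1.5)

    def test_band_volumes_stable_under_grid_refinement(self):
        """Mirrors a mesh-independence criterion: refining the grid twice
        changes each band volume by less than 1% on a smooth field with
        broad band structures."""
        params = {"u_jet": 0.3, "swirl": 3.0, "core_radius": 5.0,
                  "radius": 9.0}
        vols = []
        for n in (65, 129):
            grid = GridSpec.from_bounds((-10, -10, 0), (10, 10, 32),
                                        (n, n, 17))
            fld = analytic_field("swirling_jet", params, grid)
            q, h, _ = vortex_fields(fld)
            v = vortex_band_volumes(q, h, fld.mask,
                                    voxel_volume=fld.grid.voxel_volume)
            vols.append(np.array(v.as_tuple()))
        rel = np.abs(vols[1] - vols[0]) / vols[0]
        assert np.all(rel < 0.01)


class TestComposition:
    @pytest.mark.parametrize(
        "vols,expected",
        [
            ((2068.65, 320.01, 7.28), (84.18, 15.47, 0.35)),
            ((9093.00, 2239.64, 90.31), (74.38, 24.63, 0.99)),
            ((8219.96, 2213.31, 167.95), (71.03, 26.93, 2.04)),
        ],
    )
    def test_published_composition_arithmetic(self, vols, expected):
        v = VortexBandVolumes(*vols)
        assert vortex_composition(v) == expected

    def test_all_volume_in_low_band(self):
        assert vortex_composition(VortexBandVolumes(42.0, 0.0, 0.0)) == (
            100.0, 0.0, 0.0,
        )

    def test_zero_low_band_rejected(self):
        with pytest.raises(UndefinedCompositionError):
            vortex_composition(VortexBandVolumes(0.0, 0.0, 0.0))

    def test_inconsistent_bands_warn(self):
        with pytest.warns(UserWarning):
            vortex_composition(VortexBandVolumes(10.0, 9.0, 5.0))


@pytest.fixture(scope="module")
def poiseuille_wss(poiseuille_field):
    vessel = build_vessel(
        [[0, 0, 0], [0, 0, TUBE_LENGTH]], TUBE_RADIUS, 41
    )
    mesh = tube_surface_mesh(vessel, n_circ=64, distal_from_s=80.0)
    wss = wall_shear_stress(
        poiseuille_field, mesh, newtonian_mu=MU_NEWT
    )
    return mesh, wss


class TestWallShear:
    def test_poiseuille_wall_shear_closed_form(self, poiseuille_field,
                                               poiseuille_wss):
        _, wss = poiseuille_wss
        # WSS = 4 mu Q / (pi r^3) = 2 mu umax / r for the parabolic profile
        umax = 0.2  # 2 * mean_velocity
        exact = 2.0 * MU_NEWT * umax / (TUBE_RADIUS * 1e-3)
        mid = np.abs(wss.surface.face_s - 50.0) < 20.0
        assert np.median(wss.wss[mid]) == pytest.approx(exact, rel=0.05)

    def test_zero_flow_gives_zero_wss(self, poiseuille_field):
        vessel = build_vessel([[0, 0, 0], [0, 0, TUBE_LENGTH]], TUBE_RADIUS, 21)
        mesh = tube_surface_mesh(vessel, n_circ=16)
        fld = poiseuille_field
        zero = type(fld)(grid=fld.grid, u=np.zeros_like(fld.u), mask=fld.mask)
        wss = wall_shear_stress(zero, mesh, newtonian_mu=MU_NEWT)
        assert np.allclose(wss.wss, 0.0)

    def test_wss_linear_in_flow(self, poiseuille_field, poiseuille_wss):
        mesh, wss1 = poiseuille_wss
        fld = poiseuille_field
        doubled = type(fld)(grid=fld.grid, u=2.0 * fld.u, mask=fld.mask)
        wss2 = wall_shear_stress(doubled, mesh, newtonian_mu=MU_NEWT)
        assert np.allclose(wss2.wss, 2.0 * wss1.wss, rtol=1e-9)


class TestSawss:
    def make(self, wss_values, distal=None, areas=None):
        n = len(wss_values)
        vessel = build_vessel([[0, 0, 0], [0, 0, 10.0]], 2.0, 3)
        mesh = tube_surface_mesh(vessel, n_circ=8)
        # overwrite metadata on the first n faces; restrict region to them
        from vbpaplan.metrics import WallShearField

        full = np.zeros(mesh.n_faces)
        full[:n] = wss_values
        if distal is not None:
            mesh.distal[:] = False
            mesh.distal[:n] = distal
        w = WallShearField(surface=mesh, wss=full,
                          face_area=mesh.face_areas())
        region = np.zeros(mesh.n_faces, dtype=bool)
        region[:n] = True
        return w, region

    def test_uniform_field(self):
        w, region = self.make([1.0, 1.0, 1.0, 1.0])
        assert sawss(w, region) == pytest.approx(1.0)

    def test_equal_area_mean(self):
        w, region = self.make([1.0, 3.0])
        assert sawss(w, region) == pytest.approx(2.0)

    def test_distal_exclusion_rule(self):
        w, region = self.make([1.0, 1.0, 6.0], distal=[False, False, True])
        assert sawss(w, region) == pytest.approx(1.0)

    def test_high_value_kept_when_not_distal(self):
        w, region = self.make([1.0, 1.0, 6.0], distal=[False, False, False])
        assert sawss(w, region) == pytest.approx(8.0 / 3.0)

    def test_empty_region_rejected(self):
        w, region = self.make([6.0], distal=[True])
        with pytest.raises(EmptyRegionError):
            sawss(w, region)


class TestStripSawss:
    def test_uniform_field_any_strip_matches_global(self, poiseuille_wss):
        _, wss = poiseuille_wss
        global_val = sawss(wss)
        assert strip_sawss(wss, 50.0, 10.0) == pytest.approx(
            global_val, rel=0.02
        )

    def test_strip_outside_vessel_rejected(self, poiseuille_wss):
        _, wss = poiseuille_wss
        with pytest.raises(EmptyRegionError):
            strip_sawss(wss, 500.0, 10.0)

    def test_ten_and_five_mm_strips_agree_on_uniform_wss(self, poiseuille_wss):
        _, wss = poiseuille_wss
        a = strip_sawss(wss, 50.0, 10.0)
        b = strip_sawss(wss, 50.0, 5.0)
        assert a == pytest.approx(b, rel=0.01)


class TestPvr:
    @pytest.mark.parametrize(
        "mpap,pawp,co,expected",
        [
            (19, 13, 5.26, 91.25),  # rounds to the printed 91
            (47, 15, 5.6, 457.14),
            (27, 7, 2.2, 727.27),
        ],
    )
    def test_clinical_records(self, mpap, pawp, co, expected):
        got = pvr_from_rhc(RHCRecord(mpap=mpap, pawp=pawp, co=co))
        assert got == pytest.approx(expected, abs=0.005)

    def test_equal_pressures_give_zero(self):
        assert pvr_from_rhc(RHCRecord(mpap=20, pawp=20, co=5.0)) == 0.0

    def test_nonpositive_cardiac_output_rejected(self):
        with pytest.raises(ValidationError):
            RHCRecord(mpap=20, pawp=10, co=0.0)

    def test_wedge_above_mpap_flagged(self):
        with pytest.warns(UserWarning):
            v = pvr_from_rhc(RHCRecord(mpap=10, pawp=14, co=4.0))
        assert v < 0
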