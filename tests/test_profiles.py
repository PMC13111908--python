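"""Profile extraction, k-means clustering and the composite score."""

import numpy as np
import pytest

from conftest import TUBE_LENGTH, TUBE_RADIUS
from vbpaplan.errors import OutOfRangeError, ValidationError
from vbpaplan.geometry import build_vessel
from vbpaplan.profiles import (
    ProfileSample,
    centroid_distance,
    cluster_profile,
    compare_states,
    composite_score,
    extract_profile,
)


@pytest.fixture(scope="module")
def tube_vessel():
    return build_vessel([[0, 0, 0], [0, 0, TUBE_LENGTH]], TUBE_RADIUS, 41)


def parabola_profile(n=64, shift=0.0, station="question1"):
    s = np.linspace(0.0, 1.0, n)
    v = 4.0 * s * (1.0 - s) + shift
    return ProfileSample(station=station, points=np.column_stack([s, v]))


class TestExtractProfile:
    def test_poiseuille_profile_is_normalized_parabola(
        self, poiseuille_field, tube_vessel
    ):
        prof = extract_profile(poiseuille_field, tube_vessel, 50.0, 65)
        s, v = prof.points[:, 0], prof.points[:, 1]
        exact = 4.0 * s * (1.0 - s)
        assert np.abs(v - exact).max() < 0.02
        assert prof.v_scale == pytest.approx(0.2, rel=0.01)

    def test_zero_flow_profile_is_zero(self, poiseuille_field, tube_vessel):
        fld = poiseuille_field
        zero = type(fld)(grid=fld.grid, u=np.zeros_like(fld.u), mask=fld.mask)
        prof = extract_profile(zero, tube_vessel, 50.0)
        assert np.all(prof.points[:, 1] == 0.0)

    def test_too_few_points_rejected(self, poiseuille_field, tube_vessel):
        with pytest.raises(ValidationError):
            extract_profile(poiseuille_field, tube_vessel, 50.0, n_points=4)

    def test_station_outside_vessel_rejected(self, poiseuille_field,
                                             tube_vessel):
        with pytest.raises(OutOfRangeError):
            extract_profile(poiseuille_field, tube_vessel, 250.0)


class TestClusterProfile:
    def test_separated_blobs_recover_spatial_order(self):
        rng = np.random.default_rng(0)
        blobs = []
        for center in (0.05, 0.35, 0.65, 0.95):
            s = center + 0.01 * rng.standard_normal(20)
            v = 0.5 + 0.01 * rng.standard_normal(20)
            blobs.append(np.column_stack([s, v]))
        pts = np.vstack(blobs)
        order = np.argsort(pts[:, 0], kind="stable")
        prof = ProfileSample(station="q", points=pts[order])
        cs = cluster_profile(prof, seed=0)
        # each spatial blob maps to one label, in ascending order
        s = prof.points[:, 0]
        for label, (lo, hi) in zip(
            (1, 2, 3, 4), ((0, 0.2), (0.2, 0.5), (0.5, 0.8), (0.8, 1.0))
        ):
            sel = (s >= lo) & (s < hi)
            assert np.all(cs.labels[sel] == label)

    def test_deterministic_under_seed(self):
        prof = parabola_profile()
        a = cluster_profile(prof, seed=3)
        b = cluster_profile(prof, seed=3)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.centroids, b.centroids)

    def test_central_clusters_are_faster_on_parabola(self):
        cs = cluster_profile(parabola_profile(), seed=0)
        v = cs.profile.points[:, 1]
        central = v[np.isin(cs.labels, (2, 3))].mean()
        wall = v[np.isin(cs.labels, (1, 4))].mean()
        assert central > wall

    def test_fewer_points_than_clusters_rejected(self):
        with pytest.raises(ValidationError):
            ProfileSample(station="q", points=np.zeros((3, 2)))


class TestCentroidDistance:
    def test_identical_sets_have_zero_distance(self):
        a = cluster_profile(parabola_profile(), seed=0)
        d, mean = centroid_distance(a, a)
        assert np.all(d == 0.0) and mean == 0.0

    def test_uniform_velocity_shift_moves_every_centroid_by_delta(self):
        delta = 0.07
        a = cluster_profile(parabola_profile(), seed=0)
        b = cluster_profile(parabola_profile(shift=delta), seed=0)
        d, mean = centroid_distance(a, b)
        assert np.allclose(d, delta, atol=1e-9)
        assert mean == pytest.approx(delta, abs=1e-9)

    def test_mean_matches_bruteforce_recomputation(self):
        rng = np.random.default_rng(5)
        a = cluster_profile(parabola_profile(), seed=0)
        pts = np.column_stack(
            [np.sort(rng.uniform(0, 1, 64)), rng.uniform(0, 1, 64)]
        )
        b = cluster_profile(ProfileSample(station="q", points=pts), seed=0)
        d, mean = centroid_distance(a, b)
        brute = np.mean(
            [
                np.sqrt(((a.centroids[k] - b.centroids[k]) ** 2).sum())
                for k in range(4)
            ]
        )
        assert mean == pytest.approx(brute, rel=1e-12)


class TestCompositeScore:
    def test_zero_for_identical_inputs(self):
        a = cluster_profile(parabola_profile(), seed=0)
        res = composite_score(a, a)
        assert res.hausdorff == 0.0
        assert res.wasserstein == 0.0
        assert res.procrustes == pytest.approx(0.0, abs=1e-12)
        assert res.composite == pytest.approx(0.0, abs=1e-12)

    def test_weights_must_sum_to_one(self):
        a = cluster_profile(parabola_profile(), seed=0)
        with pytest.raises(ValidationError):
            composite_score(a, a, weights=(0.5, 0.4, 0.4))

    def test_pure_velocity_shift_decomposition(self):
        """For a +delta shift in v: Wasserstein = delta exactly, Hausdorff
        = delta (point spacing exceeds delta), Procrustes ~ 0 (translation
        removed), so composite = 0.6 * delta + 0.4 * eps."""
        delta = 0.05
        base = parabola_profile(n=16)
        shifted = parabola_profile(n=16, shift=delta)
        a = cluster_profile(base, seed=0)
        b = cluster_profile(shifted, seed=0)
        res = composite_score(b, a)
        assert res.wasserstein == pytest.approx(delta, abs=1e-12)
        assert res.hausdorff == pytest.approx(delta, abs=1e-12)
        assert res.procrustes < 1e-6
        assert res.composite == pytest.approx(0.6 * delta, abs=4e-7)

    def test_symmetric_in_hausdorff_and_wasserstein(self):
        a = cluster_profile(parabola_profile(), seed=0)
        rng = np.random.default_rng(2)
        pts = np.column_stack(
            [np.sort(rng.uniform(0, 1, 64)),
             np.clip(rng.normal(0.5, 0.2, 64), 0, 1)]
        )
        b = cluster_profile(ProfileSample(station="q", points=pts), seed=0)
        ab = composite_score(a, b)
        ba = composite_score(b, a)
        assert ab.hausdorff == pytest.approx(ba.hausdorff, rel=1e-12)
        assert ab.wasserstein == pytest.approx(ba.wasserstein, rel=1e-12)


class TestCompareStates:
    def region_profiles(self, n_regions, shift=0.0):
        return {
            f"region{i}": parabola_profile(shift=shift, station=f"region{i}")
            for i in range(n_regions)
        }

    def test_bookkeeping_28_regions_gives_336_comparisons(self):
        ref = self.region_profiles(28)
        states = {
            "pre": self.region_profiles(28, shift=0.2),
            "vbpa1": self.region_profiles(28, shift=0.1),
            "vbpa2": self.region_profiles(28, shift=0.05),
        }
        df = compare_states(states, ref, seed=0)
        assert df.attrs["n_centroid_comparisons"] == 336
        assert len(df) == 28 * 3
        # 12 of the 28 regions taken as lesion-specific: 12 x 3 x 4 = 144
        lesion_regions = sorted(ref)[:12]
        sub = df[df.region.isin(lesion_regions)]
        assert len(sub) * 4 == 144

    def test_identical_state_scores_zero_and_beats_shifted(self):
        ref = self.region_profiles(3)
        states = {
            "vbpa2": self.region_profiles(3),  # identical to benchmark
            "vbpa1": self.region_profiles(3, shift=0.1),
        }
        df = compare_states(states, ref, seed=0)
        v2 = df[df.state == "vbpa2"].composite
        v1 = df[df.state == "vbpa1"].composite
        assert np.allclose(v2, 0.0, atol=1e-9)
        assert np.all(v1.to_numpy() > v2.to_numpy())

    def test_missing_region_rejected(self):
        ref = self.region_profiles(3)
        states = {"pre": self.region_profiles(2)}
        with pytest.raises(ValidationError):
            compare_states(states, ref, seed=0)

    def test_deterministic_table(self):
        ref = self.region_profiles(4)
        states = {"pre": self.region_profiles(4, shift=0.15)}
        a = compare_states(states, ref, seed=1)
        b = compare_states(states, ref, seed=1)
        assert a.equals(b)
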