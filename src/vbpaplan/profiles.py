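"""Velocity-profile clustering and state-vs-benchmark comparison.

Velocity profiles sampled across a vessel diameter at target-lesion
("question") and downstream stations are normalized to the unit square
(position s in [0,1] across the chord, velocity v in [0,1] by the station
maximum) and partitioned by k-means into four clusters, relabeled 1-4 by
ascending centroid position so clusters 1 and 4 are the near-wall flow and
clusters 2 and 3 the central flow of an ideally parabolic profile.

Prediction quality of a virtually dilated state against the post-
intervention benchmark is quantified two ways:

* Euclidean distances between same-label cluster centroids (per cluster
  and their mean);
* a composite score over the central-flow points (clusters 2/3):
  0.2 x Hausdorff distance + 0.4 x 1-D Wasserstein distance of the
  velocity marginals + 0.4 x Procrustes residual (normalized dissimilarity
  after optimal translation/rotation/scaling).

Lower values mean smaller deviation from the benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator
from scipy.spatial.distance import directed_hausdorff
from scipy.stats import wasserstein_distance
from sklearn.cluster import KMeans

from .errors import OutOfRangeError, ValidationError
from .flow import VelocityField

__all__ = [
    "ProfileSample",
    "ProfileClusterSet",
    "ComparisonResult",
    "extract_profile",
    "cluster_profile",
    "centroid_distance",
    "composite_score",
    "compare_states",
]

_N_CLUSTERS = 4
_DEFAULT_WEIGHTS = (0.2, 0.4, 0.4)


@dataclass(frozen=True)
class ProfileSample:
    """One normalized cross-section velocity profile.

    ``points`` holds (s, v) pairs with s in [0,1] across the diameter
    chord (sorted ascending) and v normalized by the recorded maximum
    speed; ``v_scale`` (m/s) and ``chord_length`` (mm) make the
    normalization auditable.
    """

    station: str
    points: np.ndarray  # (n, 2)
    v_scale: float = 1.0
    chord_length: float = 1.0

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 8:
            raise ValidationError("profile needs >= 8 (s, v) points")
        if np.any(np.diff(pts[:, 0]) < 0):
            raise ValidationError("profile s-coordinates must be sorted")
        object.__setattr__(self, "points", pts)


@dataclass(frozen=True)
class ProfileClusterSet:
    """k-means partition of one profile into 4 ordered clusters."""

    profile: ProfileSample
    labels: np.ndarray  # (n,) in {1..4}
    centroids: np.ndarray  # (4, 2), ordered by ascending centroid s
    seed: int
    inertia: float

    def cluster_points(self, *labels) -> np.ndarray:
        sel = np.isin(self.labels, labels)
        return self.profile.points[sel]

    def central_points(self) -> np.ndarray:
        """Points of the central-flow clusters 2 and 3."""
        return self.cluster_points(2, 3)


def extract_profile(fld: VelocityField, vessel, station_s: float,
                    n_points: int = 64, station: str = "question1"
                    ) -> ProfileSample:
    """Sample the velocity magnitude along a diameter chord.

    The chord runs across the vessel at arclength ``station_s`` (the
    vessel is assumed axis-aligned with the field's z axis, as produced by
    the axisymmetric solver); speeds are normalized by the station maximum
    (all zeros for a zero-flow field) and positions by the chord length.
    """
    if n_points < 8:
        raise ValidationError("n_points must be >= 8")
    if not (0.0 <= station_s <= vessel.length):
        raise OutOfRangeError(
            f"station {station_s} mm outside vessel [0, {vessel.length:.1f}] mm"
        )
    radius = float(vessel.radius_at(station_s))
    axes = fld.grid.axes()
    z = fld.grid.origin[2] + station_s  # chord plane
    x = np.linspace(-radius, radius, n_points)
    pts = np.column_stack(
        [x, np.zeros_like(x), np.full_like(x, z)]
    )
    interp = RegularGridInterpolator(
        axes, fld.u, bounds_error=False, fill_value=0.0
    )
    speeds = np.linalg.norm(interp(pts), axis=1)
    vmax = float(speeds.max())
    v = speeds / vmax if vmax > 0 else np.zeros_like(speeds)
    s = (x + radius) / (2.0 * radius)
    return ProfileSample(
        station=station,
        points=np.column_stack([s, v]),
        v_scale=vmax,
        chord_length=2.0 * radius,
    )


def cluster_profile(profile: ProfileSample, seed: int = 0,
                    n_init: int = 10) -> ProfileClusterSet:
    """k-means (k = 4) on the (s, v) points, deterministic under seed.

    Clusters are relabeled 1-4 by ascending centroid s so the labels carry
    the fixed near-wall (1, 4) / central (2, 3) semantics.
    """
    pts = profile.points
    if len(pts) < _N_CLUSTERS:
        raise ValidationError("fewer points than clusters")
    km = KMeans(
        n_clusters=_N_CLUSTERS, n_init=n_init, random_state=seed
    ).fit(pts)
    order = np.argsort(km.cluster_centers_[:, 0], kind="stable")
    relabel = np.empty(_N_CLUSTERS, dtype=int)
    relabel[order] = np.arange(1, _N_CLUSTERS + 1)
    return ProfileClusterSet(
        profile=profile,
        labels=relabel[km.labels_],
        centroids=km.cluster_centers_[order],
        seed=seed,
        inertia=float(km.inertia_),
    )


def centroid_distance(a: ProfileClusterSet, b: ProfileClusterSet):
    """Euclidean distances between same-labeled centroids.

    Returns ``(per_cluster, mean)`` — the four distances in label order
    and their mean.
    """
    if a.centroids.shape != b.centroids.shape:
        raise ValidationError("cluster-count mismatch")
    d = np.linalg.norm(a.centroids - b.centroids, axis=1)
    return d, float(d.mean())


@dataclass(frozen=True)
class ComparisonResult:
    """One state-vs-benchmark comparison at one station."""

    per_cluster_distance: np.ndarray  # (4,)
    mean_distance: float
    hausdorff: float
    wasserstein: float
    procrustes: float
    composite: float
    states: tuple = ("state", "reference")


def _procrustes_residual(x: np.ndarray, ref: np.ndarray,
                         n_resample: int = 100) -> float:
    """Normalized residual after optimal similarity superposition.

    Both point sets are resampled to ``n_resample`` points by linear
    interpolation of v against sorted s, centered, and superposed by the
    optimal translation/rotation/scaling; the residual sum of squares is
    normalized by the reference's centered sum of squares (0 for congruent
    sets, ~1 for unrelated ones).
    """

    def resample(p):
        p = p[np.argsort(p[:, 0], kind="stable")]
        s = np.linspace(p[0, 0], p[-1, 0], n_resample)
        return np.column_stack([s, np.interp(s, p[:, 0], p[:, 1])])

    a = resample(x)
    b = resample(ref)
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    ssb = (b**2).sum()
    if ssb == 0:
        return 0.0 if (a**2).sum() == 0 else 1.0
    # optimal rotation by SVD of the cross-covariance; optimal scale after
    u_, sv, vt = np.linalg.svd(a.T @ b)
    rot = (u_ @ vt).T
    scale = sv.sum() / (a**2).sum() if (a**2).sum() > 0 else 0.0
    resid = ((scale * a @ rot.T - b) ** 2).sum()
    return float(resid / ssb)


def composite_score(x: ProfileClusterSet, ref: ProfileClusterSet,
                    weights=_DEFAULT_WEIGHTS) -> ComparisonResult:
    """Weighted composite deviation of a state from the benchmark.

    Computed on the central-flow points (clusters 2 and 3):
    symmetric Hausdorff distance in (s, v), exact 1-D Wasserstein distance
    of the v marginals, and the Procrustes residual, combined with weights
    (0.2, 0.4, 0.4) which must sum to 1.
    """
    w = tuple(float(v) for v in weights)
    if len(w) != 3 or abs(sum(w) - 1.0) > 1e-9:
        raise ValidationError("weights must be three values summing to 1")
    px = x.central_points()
    pr = ref.central_points()
    if len(px) == 0 or len(pr) == 0:
        raise ValidationError("empty central clusters")
    haus = max(
        directed_hausdorff(px, pr)[0], directed_hausdorff(pr, px)[0]
    )
    wass = wasserstein_distance(px[:, 1], pr[:, 1])
    proc = _procrustes_residual(px, pr)
    comp = w[0] * haus + w[1] * wass + w[2] * proc
    d, dm = centroid_distance(x, ref)
    return ComparisonResult(
        per_cluster_distance=d,
        mean_distance=dm,
        hausdorff=float(haus),
        wasserstein=float(wass),
        procrustes=float(proc),
        composite=float(comp),
    )


def compare_states(states: dict, ref: dict, seed: int = 0) -> pd.DataFrame:
    """Compare every state's profiles against the benchmark per region.

    ``states`` maps state name (e.g. ``pre``, ``vbpa1``, ``vbpa2``) to a
    dict of region -> :class:`ProfileSample` (or pre-clustered
    :class:`ProfileClusterSet`); ``ref`` maps region -> the benchmark
    sample. Every region must be present in every state. Returns a tidy
    table with one row per (region, state) carrying the per-cluster and
    mean centroid distances, the three component metrics and the composite
    score, plus per-state medians across regions in ``df.attrs`` and the
    comparison bookkeeping (regions x states x clusters).
    """
    regions = sorted(ref)
    for name, prof_map in states.items():
        missing = [r for r in regions if r not in prof_map]
        if missing:
            raise ValidationError(f"state {name!r} missing regions {missing}")

    def as_clusters(obj):
        if isinstance(obj, ProfileClusterSet):
            return obj
        return cluster_profile(obj, seed=seed)

    ref_c = {r: as_clusters(ref[r]) for r in regions}
    rows = []
    for name in sorted(states):
        for r in regions:
            cmp_ = composite_score(as_clusters(states[name][r]), ref_c[r])
            rows.append(
                {
                    "region": r,
                    "state": name,
                    "mean_distance": cmp_.mean_distance,
                    **{
                        f"d_cluster{k + 1}": cmp_.per_cluster_distance[k]
                        for k in range(_N_CLUSTERS)
                    },
                    "hausdorff": cmp_.hausdorff,
                    "wasserstein": cmp_.wasserstein,
                    "procrustes": cmp_.procrustes,
                    "composite": cmp_.composite,
                }
            )
    df = pd.DataFrame(rows)
    df.attrs["median_mean_distance"] = (
        df.groupby("state")["mean_distance"].median().to_dict()
    )
    df.attrs["median_composite"] = (
        df.groupby("state")["composite"].median().to_dict()
    )
    df.attrs["n_regions"] = len(regions)
    df.attrs["n_states"] = len(states)
    df.attrs["n_centroid_comparisons"] = (
        len(regions) * len(states) * _N_CLUSTERS
    )
    return df
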