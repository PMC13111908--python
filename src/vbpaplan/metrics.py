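"""Hemodynamic field and scalar metrics.

Vortex identification and banding
    The Q-criterion Q = 1/2 (||Omega||^2 - ||S||^2) (Omega, S the
    antisymmetric/symmetric parts of the velocity-gradient tensor) marks
    regions where rotation dominates strain. Q is normalized by its
    positive maximum over the lumen; vortex voxels (Q* >= q_min) are banded
    by normalized helicity density H = u.omega / (|u||omega|), the cosine
    of the angle between velocity and vorticity: |H| >= 0.2 / 0.5 / 0.8
    define the low / moderate / high helicity bands. Band volumes are voxel
    counts times voxel volume; the composition percentages express the
    moderate and high volumes as fractions of the low-band volume, with the
    low percentage as the remainder.

Wall shear stress
    WSS magnitude per surface face is mu * |d u_t / d n| estimated from
    velocity samples along the inward face normal; SAWSS is the
    surface-area-weighted mean, excluding distal faces above a 5 Pa focal
    anomaly threshold.

Clinical resistance
    PVR = (mPAP - PAWP) / CO in Wood units, reported in dyn s cm^-5
    (x 80).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .errors import (
    EmptyRegionError,
    GradientError,
    SamplingError,
    UndefinedCompositionError,
    ValidationError,
)
from .flow import BLOOD, FluidModel, VelocityField, carreau_viscosity
from .geometry import SurfaceMesh
from .units import DYN_S_CM5_PER_WOOD

__all__ = [
    "VortexBandVolumes",
    "WallShearField",
    "RHCRecord",
    "vortex_fields",
    "vortex_band_volumes",
    "vortex_composition",
    "wall_shear_stress",
    "sawss",
    "strip_sawss",
    "pvr_from_rhc",
]


# ---------------------------------------------------------------------------
# Vortex metrics


@dataclass(frozen=True)
class VortexBandVolumes:
    """Vortex volumes (mm^3) in the low/moderate/high helicity bands."""

    v_low: float
    v_moderate: float
    v_high: float
    q_min: float = 0.2
    h_thresholds: tuple = (0.2, 0.5, 0.8)
    voxel_volume: float = float("nan")  # mm^3

    def as_tuple(self) -> tuple:
        return (self.v_low, self.v_moderate, self.v_high)


def vortex_fields(fld: VelocityField):
    """Normalized Q-criterion and normalized helicity density fields.

    Velocity gradients by second-order central differences on the grid
    (one-sided at domain edges). Returns ``(q_star, h, q_raw)`` where
    ``q_star`` is Q divided by its positive maximum over the mask (all
    zeros if no positive Q), ``h`` in [-1, 1] with 0 where |u||omega| = 0,
    and ``q_raw`` the unnormalized Q in 1/s^2.
    """
    if any(n < 3 for n in fld.grid.shape):
        raise GradientError("need at least 3 nodes per axis for gradients")
    if not fld.mask.any():
        raise ValidationError("empty mask")
    # spacing mm -> m so Q has units 1/s^2
    hx, hy, hz = (h * 1e-3 for h in fld.grid.spacing)
    g = np.empty(fld.grid.shape + (3, 3))
    for comp in range(3):
        g[..., comp, 0], g[..., comp, 1], g[..., comp, 2] = np.gradient(
            fld.u[..., comp], hx, hy, hz
        )
    s_t = 0.5 * (g + np.swapaxes(g, -1, -2))
    o_t = 0.5 * (g - np.swapaxes(g, -1, -2))
    q_raw = 0.5 * (
        (o_t**2).sum(axis=(-1, -2)) - (s_t**2).sum(axis=(-1, -2))
    )

    q_pos_max = q_raw[fld.mask].max(initial=0.0)
    if q_pos_max > 0:
        q_star = q_raw / q_pos_max
    else:
        q_star = np.zeros_like(q_raw)

    # vorticity from the gradient tensor: w_i = eps_ijk dU_k/dx_j
    w = np.empty(fld.grid.shape + (3,))
    w[..., 0] = g[..., 2, 1] - g[..., 1, 2]
    w[..., 1] = g[..., 0, 2] - g[..., 2, 0]
    w[..., 2] = g[..., 1, 0] - g[..., 0, 1]
    dot = (fld.u * w).sum(axis=-1)
    denom = np.linalg.norm(fld.u, axis=-1) * np.linalg.norm(w, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        h_field = np.where(denom > 0, dot / denom, 0.0)
    h_field = np.clip(h_field, -1.0, 1.0)
    return q_star, h_field, q_raw


def vortex_band_volumes(q_star, h, mask, q_min: float = 0.2,
                        h_thresholds=(0.2, 0.5, 0.8),
                        voxel_volume: float = 1.0) -> VortexBandVolumes:
    """Vortex volume (mm^3) per helicity band.

    A voxel belongs to the band at threshold t if it is inside the mask,
    its normalized Q is at least ``q_min`` (vortex gate) and |H| >= t.
    Bands at increasing thresholds are nested super-level sets, so
    v_low >= v_moderate >= v_high by construction.
    """
    for t in (q_min, *h_thresholds):
        if not (0.0 <= t <= 1.0):
            raise ValidationError(f"threshold {t} outside [0, 1]")
    if len(h_thresholds) != 3:
        raise ValidationError("exactly three helicity thresholds required")
    q_star = np.asarray(q_star)
    h = np.asarray(h)
    mask = np.asarray(mask, dtype=bool)
    gate = mask & (q_star >= q_min)
    vols = [
        float(np.count_nonzero(gate & (np.abs(h) >= t))) * voxel_volume
        for t in h_thresholds
    ]
    return VortexBandVolumes(
        v_low=vols[0], v_moderate=vols[1], v_high=vols[2],
        q_min=q_min, h_thresholds=tuple(h_thresholds),
        voxel_volume=voxel_volume,
    )


def vortex_composition(v: VortexBandVolumes) -> tuple:
    """Band composition percentages (low, moderate, high), 2 decimals.

    The moderate and high percentages are the moderate/high volumes as
    fractions of the low-band volume; the low percentage is the remainder
    to 100. Rounding to the two printed decimals happens last. A negative
    low remainder (bands not nested) is reported with a warning.
    """
    if v.v_low <= 0:
        raise UndefinedCompositionError("low-band volume is zero")
    mod = 100.0 * v.v_moderate / v.v_low
    high = 100.0 * v.v_high / v.v_low
    low = 100.0 - mod - high
    if low < 0:
        warnings.warn(
            "inconsistent band volumes: low-band remainder is negative",
            stacklevel=2,
        )
    return (round(low, 2), round(mod, 2), round(high, 2))


# ---------------------------------------------------------------------------
# Wall shear stress


@dataclass
class WallShearField:
    """WSS magnitude (Pa) per face of a surface mesh."""

    surface: SurfaceMesh
    wss: np.ndarray  # (nf,) Pa
    face_area: np.ndarray  # (nf,) mm^2

    def __post_init__(self):
        self.wss = np.asarray(self.wss, dtype=float)
        if np.any(self.wss < 0):
            raise ValidationError("WSS magnitudes must be non-negative")
        if self.wss.shape[0] != self.surface.n_faces:
            raise ValidationError("one WSS value per face required")


def wall_shear_stress(fld: VelocityField, surface: SurfaceMesh,
                      fluid: FluidModel = BLOOD,
                      newtonian_mu: float | None = None,
                      offset_factor: float = 1.5) -> WallShearField:
    """Estimate the WSS magnitude on every surface face.

    The tangential velocity is sampled at ``h = offset_factor * spacing``
    and ``2 h`` along the inward face normal; with the no-slip value at
    the face the one-sided second-order estimate is
    ``|du_t/dn| ~ |4 u1 - u2| / (2 h)``. The default offset keeps the
    samples clear of the interpolation kink at the masked wall. Accuracy
    is limited by how closely the faceted mesh hugs the true surface
    (centroid sagitta): refine ``n_circ`` of the tube mesh for tighter
    estimates. The viscosity is ``newtonian_mu`` if given, else the
    Carreau viscosity at the estimated wall shear rate. Faces sampling
    outside the grid raise :class:`SamplingError`.
    """
    lo = np.asarray(fld.grid.origin)
    axes = fld.grid.axes()
    hi = np.array([a[-1] for a in axes])
    interp = RegularGridInterpolator(
        axes, fld.u, bounds_error=False, fill_value=None
    )
    h_mm = offset_factor * float(min(fld.grid.spacing))

    centroids = surface.face_centroids()
    normals = surface.face_normals()  # outward
    p1 = centroids - h_mm * normals
    p2 = centroids - 2.0 * h_mm * normals
    for p in (p1, p2):
        if np.any(p < lo - 1e-9) or np.any(p > hi + 1e-9):
            raise SamplingError("surface face samples outside the field grid")
    u1 = interp(p1)
    u2 = interp(p2)
    # tangential components (wall velocity is zero by no-slip)
    u1t = u1 - (u1 * normals).sum(axis=1, keepdims=True) * normals
    u2t = u2 - (u2 * normals).sum(axis=1, keepdims=True) * normals
    dudn = np.linalg.norm(4.0 * u1t - u2t, axis=1) / (2.0 * h_mm * 1e-3)

    mu = (
        newtonian_mu
        if newtonian_mu is not None
        else carreau_viscosity(dudn, fluid)
    )
    return WallShearField(
        surface=surface, wss=np.asarray(mu) * dudn,
        face_area=surface.face_areas(),
    )


def sawss(wss: WallShearField, region_mask=None, exclusion: float = 5.0,
          exclusion_scope: str = "distal_only") -> float:
    """Surface-area-weighted mean WSS (Pa) over a face region.

    Focal WSS anomalies above ``exclusion`` Pa are dropped before
    averaging — on distal faces only (default, mirroring the usual distal-
    vessel artifact rule) or everywhere (``exclusion_scope="all"``).
    """
    if exclusion_scope not in ("distal_only", "all", "none"):
        raise ValidationError(f"unknown exclusion scope {exclusion_scope!r}")
    sel = (
        np.ones(wss.surface.n_faces, dtype=bool)
        if region_mask is None
        else np.asarray(region_mask, dtype=bool).copy()
    )
    if exclusion_scope == "distal_only":
        sel &= ~(wss.surface.distal & (wss.wss > exclusion))
    elif exclusion_scope == "all":
        sel &= ~(wss.wss > exclusion)
    if not sel.any():
        raise EmptyRegionError("no faces remain after exclusion")
    a = wss.face_area[sel]
    return float((wss.wss[sel] * a).sum() / a.sum())


def strip_sawss(wss: WallShearField, axis_station: float,
                strip_width: float, **kwargs) -> float:
    """SAWSS over a circumferential strip of given axial width (mm),
    centered at arclength ``axis_station`` — the strip-clipping protocol
    used to compare RPA/LPA wall shear between states."""
    if strip_width <= 0:
        raise ValidationError("strip width must be positive")
    s = wss.surface.face_s
    sel = np.abs(s - axis_station) <= 0.5 * strip_width
    if not sel.any():
        raise EmptyRegionError(
            f"no faces within the {strip_width} mm strip at s={axis_station}"
        )
    return sawss(wss, region_mask=sel, **kwargs)


# ---------------------------------------------------------------------------
# Right-heart catheterization


@dataclass(frozen=True)
class RHCRecord:
    """Right-heart-catheterization measurements of one subject."""

    mpap: float  # mean pulmonary artery pressure, mmHg
    pawp: float  # pulmonary arterial wedge pressure, mmHg
    co: float  # cardiac output, L/min

    def __post_init__(self):
        if self.co <= 0:
            raise ValidationError("cardiac output must be positive")


def pvr_from_rhc(r: RHCRecord) -> float:
    """Pulmonary vascular resistance (mPAP - PAWP) / CO in dyn s cm^-5.

    The Wood-unit quotient is converted with 1 Wood unit = 80 dyn s cm^-5.
    A wedge pressure above mPAP yields a negative value, which is returned
    but flagged with a warning.
    """
    pvr = (r.mpap - r.pawp) / r.co * DYN_S_CM5_PER_WOOD
    if pvr < 0:
        warnings.warn("PAWP exceeds mPAP: negative PVR", stacklevel=2)
    return float(pvr)
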