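"""Virtual balloon pulmonary angioplasty: two dilation strategies.

Both operators edit a vessel's 1-D radius profile and never narrow it:

* :func:`vbpa1_restore` — morphology-restoring dilation. The radius inside a
  lesion window is replaced by a smooth cubic reconstruction extrapolated
  from the healthy profile in windows adjacent to the stenosis,
  approximating the pre-disease lumen. Suited to web lesions, where therapy
  aims at anatomical restoration.
* :func:`vbpa2_rigid_dilate` — rigid homogeneous dilation. An idealized
  cylindrical balloon of given diameter and length is expanded along the
  vessel midline; the lumen is opened to the balloon radius wherever the
  balloon is wider than the native vessel, with smooth cosine shoulders.

With circular cross-sections the 1-D radius profile fully determines the
lumen surface, so spline reconstruction of the profile is equivalent to a
surface-level (NURBS-type) reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicHermiteSpline

from .errors import NoHealthyReferenceError, OutOfRangeError, ValidationError
from .geometry import VesselModel

__all__ = ["BalloonSpec", "DilationReport", "vbpa1_restore", "vbpa2_rigid_dilate",
           "default_lesion_window"]


@dataclass(frozen=True)
class BalloonSpec:
    """Clinical balloon: diameter x length (mm) centered at ``center_s``."""

    diameter: float  # mm
    length: float  # mm
    center_s: float  # mm arclength of balloon center

    def __post_init__(self):
        if self.diameter <= 0 or self.length <= 0:
            raise ValidationError("balloon diameter and length must be positive")

    @property
    def s_min(self) -> float:
        return self.center_s - 0.5 * self.length

    @property
    def s_max(self) -> float:
        return self.center_s + 0.5 * self.length


@dataclass(frozen=True)
class DilationReport:
    """Before/after summary of one virtual dilation."""

    method: str  # "vbpa1" | "vbpa2"
    min_radius_pre: float  # mm
    min_radius_post: float  # mm
    throat_area_pre: float  # mm²
    throat_area_post: float  # mm²
    edited_interval: tuple  # (s_lo, s_hi) mm

    def __post_init__(self):
        if self.min_radius_post < self.min_radius_pre - 1e-12:
            raise ValidationError("dilation must not narrow the vessel")


def _report(method, vessel_pre, vessel_post, interval):
    return DilationReport(
        method=method,
        min_radius_pre=vessel_pre.min_radius(),
        min_radius_post=vessel_post.min_radius(),
        throat_area_pre=float(np.pi * vessel_pre.min_radius() ** 2),
        throat_area_post=float(np.pi * vessel_post.min_radius() ** 2),
        edited_interval=(float(interval[0]), float(interval[1])),
    )


def default_lesion_window(vessel: VesselModel) -> tuple[float, float]:
    """Lesion window covering all recorded lesions, padded by half a lesion
    length on each side (clipped to the vessel)."""
    if not vessel.lesions:
        raise ValidationError("vessel has no recorded lesions; pass lesion_window")
    lo = min(l.s_min - 0.5 * l.length for l in vessel.lesions)
    hi = max(l.s_max + 0.5 * l.length for l in vessel.lesions)
    return (max(lo, 0.0), min(hi, vessel.length))


def vbpa1_restore(vessel: VesselModel, lesion_window: tuple | None = None,
                  healthy_window_len: float | None = None
                  ) -> tuple[VesselModel, DilationReport]:
    """Morphology-restoring dilation of the radius profile.

    Radius samples inside ``lesion_window`` (arclength interval, mm) are
    replaced by a cubic Hermite reconstruction whose end values and slopes
    come from least-squares linear fits to the healthy profile in windows of
    length ``healthy_window_len`` adjacent to the lesion window (default: two
    local diameters per side). The reconstruction is C¹-continuous at the
    window boundaries, reproduces constant and linear healthy profiles
    exactly, and the output radius is ``max(reconstruction, input radius)``
    so the operation never narrows the lumen. Outside the window the profile
    is bit-identical to the input.

    At a vessel end with no healthy window on one side, the fit from the
    other side is extrapolated (one-sided restoration).
    """
    if lesion_window is None:
        lesion_window = default_lesion_window(vessel)
    s_lo, s_hi = float(lesion_window[0]), float(lesion_window[1])
    if not (s_lo < s_hi):
        raise ValidationError("lesion_window must be a non-empty interval")
    s = vessel.s
    r = vessel.radius
    if healthy_window_len is None:
        edge_r = vessel.radius_at(np.clip([s_lo, s_hi], 0, vessel.length))
        healthy_window_len = 4.0 * float(np.max(edge_r))  # 2 local diameters

    left = (s >= s_lo - healthy_window_len) & (s < s_lo)
    right = (s > s_hi) & (s <= s_hi + healthy_window_len)
    if not left.any() and not right.any():
        raise NoHealthyReferenceError(
            "lesion window covers the whole vessel: no healthy samples to fit"
        )

    def _fit(mask):
        ss, rr = s[mask], r[mask]
        if len(ss) == 1:
            return np.array([0.0, rr[0]])  # constant
        return np.polyfit(ss, rr, 1)

    fits = []
    if left.any():
        fits.append(_fit(left))
    if right.any():
        fits.append(_fit(right))
    fit_lo = fits[0]
    fit_hi = fits[-1]

    # cubic Hermite across the window, C¹-matched to the side fits
    vals = [np.polyval(fit_lo, s_lo), np.polyval(fit_hi, s_hi)]
    slopes = [fit_lo[0], fit_hi[0]]
    spline = CubicHermiteSpline([s_lo, s_hi], vals, slopes)

    inside = (s >= s_lo) & (s <= s_hi)
    r_new = r.copy()
    r_new[inside] = np.maximum(spline(s[inside]), r[inside])
    # snap round-off excess so a lesion-free profile is reproduced exactly
    close = np.isclose(r_new, r, rtol=1e-9, atol=0.0)
    r_new[close] = r[close]
    post = vessel.with_radius(r_new)
    return post, _report("vbpa1", vessel, post, (s_lo, s_hi))


def _balloon_profile(balloon: BalloonSpec, s: np.ndarray, shoulder: float) -> np.ndarray:
    """Radius offered by the inflated balloon at each station: D/2 across the
    balloon core, cosine decay to zero over ``shoulder`` mm beyond each end,
    zero farther away."""
    b = np.zeros_like(s)
    core = (s >= balloon.s_min) & (s <= balloon.s_max)
    b[core] = 0.5 * balloon.diameter
    for edge, sign in ((balloon.s_min, -1.0), (balloon.s_max, +1.0)):
        zone = (sign * (s - edge) > 0) & (sign * (s - edge) <= shoulder)
        d = np.abs(s[zone] - edge)
        b[zone] = 0.5 * balloon.diameter * 0.5 * (1.0 + np.cos(np.pi * d / shoulder))
    return b


def vbpa2_rigid_dilate(vessel: VesselModel, balloon: BalloonSpec
                       ) -> tuple[VesselModel, DilationReport]:
    """Rigid homogeneous dilation by an idealized cylindrical balloon.

    Within the balloon extent the radius becomes ``max(local radius, D/2)``
    — a rigid balloon opens the lumen to its own radius but cannot pull a
    wider wall inward. Each end of the plateau is blended by a cosine
    shoulder roughly one local radius long; because the blend is a fixed
    balloon-shape function combined with the vessel by ``max``, applying the
    same balloon twice is exactly idempotent. Stations beyond the blended
    extent are bit-identical to the input.
    """
    if balloon.s_max < 0.0 or balloon.s_min > vessel.length:
        raise OutOfRangeError(
            f"balloon [{balloon.s_min:.2f}, {balloon.s_max:.2f}] mm entirely "
            f"outside vessel [0, {vessel.length:.2f}] mm"
        )
    s = vessel.s
    core = (s >= balloon.s_min) & (s <= balloon.s_max)
    # shoulder one local radius long; floored by the balloon radius so the
    # blend width is invariant under re-application (exact idempotence:
    # max(core radius) is itself idempotent under the max(r, D/2) edit)
    local_r = float(vessel.radius[core].max()) if core.any() else 0.0
    shoulder = max(local_r, 0.5 * balloon.diameter)
    b = _balloon_profile(balloon, s, shoulder)
    r_new = np.maximum(vessel.radius, b)
    post = vessel.with_radius(r_new)
    lo = max(balloon.s_min - shoulder, 0.0)
    hi = min(balloon.s_max + shoulder, vessel.length)
    return post, _report("vbpa2", vessel, post, (lo, hi))
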