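"""Blood rheology and structured-grid velocity fields.

Blood is shear-thinning; the Carreau model interpolates between a zero-shear
viscosity mu0 and an infinite-shear viscosity mu_inf:

    mu(gdot) = mu_inf + (mu0 - mu_inf) * [1 + (lam*gdot)^2]^((n-1)/2)

with relaxation time lam (s) and power-law exponent n. The defaults are the
standard blood constants mu0 = 0.056 Pa s, mu_inf = 0.0035 Pa s,
lam = 3.313 s, n = 0.3568, density 1060 kg/m^3.

Velocity fields live on regular Cartesian grids (mm spacing, m/s velocity)
with an inside-lumen mask; every downstream metric (Q-criterion, helicity,
band volumes, wall shear sampling, profile extraction) operates on this
container. Analytic generators provide exact reference fields in place of an
external CFD solve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ValidationError

__all__ = [
    "FluidModel",
    "BLOOD",
    "carreau_viscosity",
    "GridSpec",
    "VelocityField",
    "analytic_field",
    "ANALYTIC_KINDS",
]


@dataclass(frozen=True)
class FluidModel:
    """Carreau fluid: density (kg/m^3) plus the four rheology constants."""

    density: float = 1060.0  # kg/m^3
    mu0: float = 0.056  # Pa s, zero-shear viscosity
    mu_inf: float = 0.0035  # Pa s, infinite-shear viscosity
    lam: float = 3.313  # s, relaxation time
    n: float = 0.3568  # power-law exponent

    def __post_init__(self):
        if not (self.mu0 > self.mu_inf > 0):
            raise ValidationError("require mu0 > mu_inf > 0")
        if self.lam <= 0:
            raise ValidationError("relaxation time lam must be positive")
        if not (0 < self.n <= 1):
            raise ValidationError("exponent n must lie in (0, 1]")
        if self.density <= 0:
            raise ValidationError("density must be positive")

    def newtonian(self, mu: Optional[float] = None) -> "FluidModel":
        """Constant-viscosity variant (n = 1 makes Carreau return mu0)."""
        mu = self.mu_inf if mu is None else mu
        return FluidModel(density=self.density, mu0=mu, mu_inf=0.5 * mu,
                          lam=self.lam, n=1.0)


#: default blood model
BLOOD = FluidModel()


def carreau_viscosity(gamma_dot, fluid: FluidModel = BLOOD):
    """Dynamic viscosity (Pa s) at shear rate ``gamma_dot`` (1/s).

    Monotone non-increasing in the shear rate and bounded in
    [mu_inf, mu0]; at n = 1 it returns mu0 for every shear rate. Accepts
    scalars or arrays; negative shear rates raise.
    """
    g = np.asarray(gamma_dot, dtype=float)
    if np.any(g < 0):
        raise ValidationError("shear rate must be non-negative")
    if fluid.n == 1.0:
        mu = np.full_like(g, fluid.mu0)
    else:
        mu = fluid.mu_inf + (fluid.mu0 - fluid.mu_inf) * (
            1.0 + (fluid.lam * g) ** 2
        ) ** ((fluid.n - 1.0) / 2.0)
    if np.isscalar(gamma_dot) or np.ndim(gamma_dot) == 0:
        return float(mu)
    return mu


# ---------------------------------------------------------------------------
# Structured-grid velocity fields


@dataclass(frozen=True)
class GridSpec:
    """Regular Cartesian grid: origin and spacing in mm, node counts."""

    origin: tuple  # (3,) mm
    spacing: tuple  # (3,) mm, > 0
    shape: tuple  # (nx, ny, nz) node counts

    def __post_init__(self):
        if len(self.origin) != 3 or len(self.spacing) != 3 or len(self.shape) != 3:
            raise ValidationError("origin, spacing and shape must be 3-vectors")
        if any(h <= 0 for h in self.spacing):
            raise ValidationError("grid spacing must be positive on all axes")
        if any(int(n) < 2 for n in self.shape):
            raise ValidationError("grid needs at least 2 nodes per axis")
        object.__setattr__(self, "origin", tuple(float(x) for x in self.origin))
        object.__setattr__(self, "spacing", tuple(float(h) for h in self.spacing))
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Node coordinate arrays along each axis, mm."""
        return tuple(
            self.origin[k] + self.spacing[k] * np.arange(self.shape[k])
            for k in range(3)
        )

    def meshgrid(self):
        return np.meshgrid(*self.axes(), indexing="ij")

    @property
    def voxel_volume(self) -> float:
        """mm^3 per node cell."""
        return float(np.prod(self.spacing))

    @classmethod
    def from_bounds(cls, lo, hi, shape) -> "GridSpec":
        lo = np.asarray(lo, dtype=float)
        hi = np.asarray(hi, dtype=float)
        shape = tuple(int(n) for n in shape)
        spacing = (hi - lo) / (np.asarray(shape) - 1)
        return cls(origin=tuple(lo), spacing=tuple(spacing), shape=shape)


@dataclass
class VelocityField:
    """Velocity vectors (m/s) on a regular grid (mm) with a lumen mask."""

    grid: GridSpec
    u: np.ndarray  # (nx, ny, nz, 3) m/s
    mask: np.ndarray  # (nx, ny, nz) bool, True inside the lumen
    pressure: Optional[np.ndarray] = None  # (nx, ny, nz) Pa
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.u.shape != self.grid.shape + (3,):
            raise ValidationError(
                f"velocity shape {self.u.shape} != grid shape {self.grid.shape} + (3,)"
            )
        if self.mask.shape != self.grid.shape:
            raise ValidationError("mask shape must match the grid")
        if not np.all(np.isfinite(self.u[self.mask])):
            raise ValidationError("velocity must be finite on masked nodes")
        if self.pressure is not None:
            self.pressure = np.asarray(self.pressure, dtype=float)
            if self.pressure.shape != self.grid.shape:
                raise ValidationError("pressure shape must match the grid")

    def speed(self) -> np.ndarray:
        return np.linalg.norm(self.u, axis=-1)


# ---------------------------------------------------------------------------
# Analytic generators

ANALYTIC_KINDS = (
    "poiseuille",
    "solid_rotation",
    "planar_shear",
    "lamb_oseen",
    "beltrami_abc",
    "swirling_jet",
    "vortex_wake",
)


def analytic_field(kind: str, params: dict, grid_spec: GridSpec) -> VelocityField:
    """Sample an exact analytic velocity field on grid nodes.

    Tube-like kinds (poiseuille, lamb_oseen, swirling_jet) are axis-aligned
    with z and masked to the tube radius; rotation/shear/Beltrami kinds fill
    the whole domain. All generators set u = 0 outside the mask so that
    interpolation near the wall stays continuous.

    Parameters by kind (lengths mm, velocities m/s):

    * ``poiseuille`` — ``radius``, and either ``mean_velocity`` or
      ``flow_lpm``; axial velocity 2*ubar*(1 - (rho/R)^2).
    * ``solid_rotation`` — ``omega`` (rad/s): u = omega x r about z.
    * ``planar_shear`` — ``gamma`` (1/s): u = (gamma*y, 0, 0).
    * ``lamb_oseen`` — ``circulation`` (m^2/s), ``core_radius`` mm, optional
      ``radius`` mask.
    * ``beltrami_abc`` — ``A``, ``B``, ``C`` (m/s), ``wavenumber`` (1/mm):
      ABC flow, an exact Beltrami field (vorticity parallel to velocity).
    * ``swirling_jet`` — ``u_jet`` (m/s), ``swirl`` (dimensionless ratio),
      ``core_radius`` mm, ``radius`` mm mask: Gaussian axial jet with an
      azimuthal swirl component, controllable helicity content.
    * ``vortex_wake`` — ``u_axial`` (m/s), ``kappa`` (peak vortex swirl
      relative to the axial speed), ``n_vortices``, ``core_radius`` mm,
      ``radius`` mm, ``seed``: a parabolic axial stream threaded by
      off-axis streamwise vortex tubes at seeded random positions with
      alternating sense. Inside the vortex cores the velocity aligns with
      the streamwise vorticity, so the helicity-band content is
      controllable: a faster axial stream relative to the swirl (smaller
      ``kappa``) raises the high-helicity share.
    """
    if kind not in ANALYTIC_KINDS:
        raise ValidationError(
            f"unknown analytic kind {kind!r}; choose from {ANALYTIC_KINDS}"
        )
    X, Y, Z = grid_spec.meshgrid()  # mm
    shape = grid_spec.shape
    u = np.zeros(shape + (3,))
    mask = np.ones(shape, dtype=bool)

    if kind == "poiseuille":
        R = float(params["radius"])
        if R <= 0:
            raise ValidationError("radius must be positive")
        if "mean_velocity" in params:
            ubar = float(params["mean_velocity"])
        else:
            from .units import lpm_to_m3s

            area_m2 = np.pi * (R * 1e-3) ** 2
            ubar = lpm_to_m3s(float(params["flow_lpm"])) / area_m2
        rho2 = X**2 + Y**2
        mask = rho2 <= R**2
        u[..., 2] = np.where(mask, 2.0 * ubar * (1.0 - rho2 / R**2), 0.0)

    elif kind == "solid_rotation":
        om = float(params["omega"])
        u[..., 0] = -om * Y * 1e-3
        u[..., 1] = om * X * 1e-3

    elif kind == "planar_shear":
        g = float(params["gamma"])
        u[..., 0] = g * Y * 1e-3

    elif kind == "lamb_oseen":
        gam = float(params["circulation"])  # m^2/s
        rc = float(params["core_radius"]) * 1e-3  # m
        rho = np.sqrt(X**2 + Y**2) * 1e-3  # m
        with np.errstate(divide="ignore", invalid="ignore"):
            utheta = gam / (2.0 * np.pi * rho) * (1.0 - np.exp(-(rho**2) / rc**2))
        utheta = np.where(rho > 0, utheta, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            cx = np.where(rho > 0, X * 1e-3 / rho, 0.0)
            cy = np.where(rho > 0, Y * 1e-3 / rho, 0.0)
        u[..., 0] = -utheta * cy
        u[..., 1] = utheta * cx
        if "radius" in params:
            mask = (X**2 + Y**2) <= float(params["radius"]) ** 2
            u[~mask] = 0.0

    elif kind == "beltrami_abc":
        A = float(params.get("A", 1.0))
        B = float(params.get("B", 1.0))
        C = float(params.get("C", 1.0))
        k = float(params.get("wavenumber", 1.0))  # 1/mm
        x, y, z = k * X, k * Y, k * Z
        u[..., 0] = A * np.sin(z) + C * np.cos(y)
        u[..., 1] = B * np.sin(x) + A * np.cos(z)
        u[..., 2] = C * np.sin(y) + B * np.cos(x)

    elif kind == "swirling_jet":
        uj = float(params.get("u_jet", 1.0))
        sw = float(params.get("swirl", 0.5))
        a = float(params.get("core_radius", 5.0))  # mm
        rho = np.sqrt(X**2 + Y**2)  # mm
        prof = np.exp(-(rho**2) / a**2)
        utheta = sw * uj * (rho / a) * prof
        with np.errstate(divide="ignore", invalid="ignore"):
            cx = np.where(rho > 0, X / rho, 0.0)
            cy = np.where(rho > 0, Y / rho, 0.0)
        u[..., 0] = -utheta * cy
        u[..., 1] = utheta * cx
        u[..., 2] = uj * prof
        if "radius" in params:
            mask = rho <= float(params["radius"])
            u[~mask] = 0.0

    elif kind == "vortex_wake":
        u0 = float(params.get("u_axial", 0.3))
        kappa = float(params.get("kappa", 5.0))
        n_v = int(params.get("n_vortices", 3))
        rc = float(params.get("core_radius", 1.0))  # mm
        R = float(params["radius"])  # mm
        seed = int(params.get("seed", 0))
        rho2 = X**2 + Y**2
        mask = rho2 <= R**2
        u[..., 2] = np.where(mask, 2.0 * u0 * (1.0 - rho2 / R**2), 0.0)
        rng = np.random.default_rng(seed)
        for i in range(n_v):
            ang = rng.uniform(0.0, 2.0 * np.pi)
            rad = rng.uniform(0.2, 0.6) * R
            cx, cy = rad * np.cos(ang), rad * np.sin(ang)
            sgn = 1.0 if i % 2 == 0 else -1.0
            dx, dy = X - cx, Y - cy
            d = np.sqrt(dx**2 + dy**2)
            # Gaussian vortex tube: peak tangential speed kappa*u0 at d=rc
            g = (d / rc) * np.exp(0.5 * (1.0 - (d / rc) ** 2))
            ut = sgn * kappa * u0 * g
            with np.errstate(divide="ignore", invalid="ignore"):
                u[..., 0] += np.where(d > 0, -ut * dy / d, 0.0)
                u[..., 1] += np.where(d > 0, ut * dx / d, 0.0)
        u[~mask] = 0.0

    return VelocityField(grid=grid_spec, u=u, mask=mask,
                         meta={"kind": kind, "params": dict(params)})
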