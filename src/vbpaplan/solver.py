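"""Steady laminar incompressible axisymmetric flow in a stenosed vessel.

A desk-scale stand-in for a full 3-D CFD solve: the vessel is treated as an
axisymmetric body of revolution described by its radius profile r = R(z),
and the steady Navier-Stokes equations are solved in stream-function /
vorticity form on a body-fitted grid (axial coordinate xi = z, radial
coordinate eta = r/R(z) in [0, 1]).

With u_z = (1/r) dpsi/dr and u_r = -(1/r) dpsi/dz, continuity is satisfied
identically and the two unknown scalars obey

    E^2 psi = psi_rr - psi_r / r + psi_zz = -r * omega
    u_z omega_z + u_r omega_r - u_r omega / r
        = nu * (omega_rr + omega_r / r - omega / r^2 + omega_zz)

where omega is the azimuthal vorticity. Boundary conditions: fully developed
(parabolic) inflow, zero-gradient outflow, symmetry on the axis, and no-slip
on the wall with the wall vorticity recovered from the stream function
(Thom's formula along the wall normal). The nonlinear system is solved by
Picard iteration with under-relaxation: alternate sparse linear solves for
psi and omega (first-order upwind convection in mapped coordinates) until
the vorticity fixed-point residual drops below tolerance.

The axial pressure distribution follows from integrating the axial momentum
equation along the centerline; the pressure drop is inlet-minus-outlet.

Shear-thinning rheology enters through a scalar effective viscosity,
the Carreau viscosity at the characteristic wall shear rate 8*ubar/d of the
tightest station; the Newtonian default uses the infinite-shear viscosity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.interpolate import RegularGridInterpolator

from .errors import ConvergenceError, ValidationError
from .flow import BLOOD, FluidModel, GridSpec, VelocityField, carreau_viscosity
from .units import lpm_to_m3s

__all__ = ["SolverConfig", "SolveResult", "solve_steady_axisym"]

_RE_LIMIT = 500.0


@dataclass(frozen=True)
class SolverConfig:
    """Numerical parameters of the axisymmetric solve.

    ``nz`` x ``nr`` grid nodes (axial x radial, minimum 16 x 8);
    ``relaxation`` is the Picard under-relaxation factor on vorticity;
    ``tolerance`` the fixed-point residual target (default 1e-6, mirroring
    the usual CFD residual criterion). ``newtonian_only`` freezes the
    viscosity at the fluid's infinite-shear value instead of evaluating the
    Carreau model at the characteristic shear rate.
    """

    nz: int = 96
    nr: int = 24
    relaxation: float = 0.4
    max_iterations: int = 400
    tolerance: float = 1.0e-6
    fluid: FluidModel = field(default_factory=lambda: BLOOD)
    newtonian_only: bool = True
    output_shape: tuple = (33, 33, 65)  # revolved 3-D export grid

    def __post_init__(self):
        if self.tolerance <= 0:
            raise ValidationError("tolerance must be positive")
        if self.nz < 16 or self.nr < 8:
            raise ValidationError("resolution must be at least 16 x 8")
        if not (0 < self.relaxation <= 1):
            raise ValidationError("relaxation must lie in (0, 1]")


@dataclass
class SolveResult:
    """Converged axisymmetric solution plus its revolved 3-D export.

    Axisymmetric arrays are indexed (z, r-like eta); SI units (m, m/s, Pa).
    """

    field: VelocityField  # revolved onto a Cartesian grid (mm / m/s)
    z: np.ndarray  # (nz,) m
    eta: np.ndarray  # (nr,) wall-normalized radius
    radius: np.ndarray  # (nz,) m wall radius R(z)
    u_z: np.ndarray  # (nz, nr) m/s
    u_r: np.ndarray  # (nz, nr) m/s
    psi: np.ndarray  # (nz, nr) m^3/s / (2 pi)
    omega: np.ndarray  # (nz, nr) 1/s
    p_axis: np.ndarray  # (nz,) Pa along the centerline
    delta_p: float  # Pa, inlet minus outlet
    mu: float  # Pa s effective viscosity used
    residuals: list  # per-iteration fixed-point residuals
    iterations: int = 0

    def flux_profile(self) -> np.ndarray:
        """Volume flux (m^3/s) through each cross-section by quadrature of
        2*pi*u_z*r dr — the discrete mass-conservation diagnostic."""
        r = self.eta[None, :] * self.radius[:, None]
        return 2.0 * np.pi * np.trapezoid(self.u_z * r, r, axis=1)


def _d1(x: np.ndarray) -> sp.csr_matrix:
    """Three-point first-derivative matrix on an arbitrary node vector."""
    n = len(x)
    D = sp.lil_matrix((n, n))
    for i in range(n):
        if i == 0:
            j = (0, 1, 2)
        elif i == n - 1:
            j = (n - 3, n - 2, n - 1)
        else:
            j = (i - 1, i, i + 1)
        xi = x[list(j)] - x[i]
        # Lagrange derivative weights at x[i]
        w = np.zeros(3)
        for a in range(3):
            others = [b for b in range(3) if b != a]
            denom = np.prod([xi[a] - xi[b] for b in others])
            w[a] = sum(
                np.prod([0.0 - xi[c] for c in others if c != b]) for b in others
            ) / denom
        D[i, list(j)] = w
    return D.tocsr()


def _d2(x: np.ndarray) -> sp.csr_matrix:
    """Three-point second-derivative matrix on an arbitrary node vector."""
    n = len(x)
    D = sp.lil_matrix((n, n))
    for i in range(n):
        if i == 0:
            j = (0, 1, 2)
        elif i == n - 1:
            j = (n - 3, n - 2, n - 1)
        else:
            j = (i - 1, i, i + 1)
        x0, x1, x2 = x[list(j)] - x[i]
        # second derivative of the quadratic through the three points
        w = np.array(
            [
                2.0 / ((x0 - x1) * (x0 - x2)),
                2.0 / ((x1 - x0) * (x1 - x2)),
                2.0 / ((x2 - x0) * (x2 - x1)),
            ]
        )
        D[i, list(j)] = w
    return D.tocsr()


def _upwind_pair(x: np.ndarray) -> tuple[sp.csr_matrix, sp.csr_matrix]:
    """Backward and forward first-difference matrices (first order)."""
    n = len(x)
    Db = sp.lil_matrix((n, n))
    Df = sp.lil_matrix((n, n))
    for i in range(n):
        ib = max(i - 1, 0)
        jf = min(i + 1, n - 1)
        if i > 0:
            Db[i, i] = 1.0 / (x[i] - x[ib])
            Db[i, ib] = -1.0 / (x[i] - x[ib])
        else:
            Db[i, jf] = 1.0 / (x[jf] - x[i])
            Db[i, i] = -1.0 / (x[jf] - x[i])
        if i < n - 1:
            Df[i, jf] = 1.0 / (x[jf] - x[i])
            Df[i, i] = -1.0 / (x[jf] - x[i])
        else:
            Df[i, i] = 1.0 / (x[i] - x[ib])
            Df[i, ib] = -1.0 / (x[i] - x[ib])
    return Db.tocsr(), Df.tocsr()


def solve_steady_axisym(vessel, inlet_flow: float,
                        config: Optional[SolverConfig] = None) -> SolveResult:
    """Solve steady laminar flow through one axisymmetric vessel.

    ``vessel`` supplies the radius-vs-arclength profile (mm; any centerline
    curvature is ignored — the segment is straightened); ``inlet_flow`` is
    the volumetric flow in L/min. Raises :class:`ValidationError` if the
    inlet Reynolds number exceeds 500 (laminar steady regime only) and
    :class:`ConvergenceError` (carrying the residual trace) if Picard
    iteration stalls.
    """
    config = config or SolverConfig()
    nz, nr = config.nz, config.nr

    L = vessel.length * 1e-3  # m
    z = np.linspace(0.0, L, nz)
    s_mm = z * 1e3
    R = np.maximum(vessel.radius_at(s_mm), 1e-9) * 1e-3  # m
    eta = np.linspace(0.0, 1.0, nr)

    Q = lpm_to_m3s(inlet_flow)  # m^3/s
    r_in = R[0]
    ubar_in = Q / (np.pi * r_in**2)

    # effective viscosity: Carreau at the characteristic wall shear of the
    # tightest station, or the infinite-shear (Newtonian) value
    r_min = float(R.min())
    if config.newtonian_only or Q == 0.0:
        mu = config.fluid.mu_inf
    else:
        ubar_t = Q / (np.pi * r_min**2)
        gdot_c = 8.0 * ubar_t / (2.0 * r_min)
        mu = carreau_viscosity(gdot_c, config.fluid)
    rho = config.fluid.density
    nu = mu / rho

    Re = rho * ubar_in * 2.0 * r_in / mu if Q > 0 else 0.0
    if Re > _RE_LIMIT:
        raise ValidationError(
            f"inlet Reynolds number {Re:.0f} exceeds the laminar limit {_RE_LIMIT:.0f}"
        )

    # --- differentiation operators on the mapped (xi, eta) grid ----------
    Dxi = _d1(z)
    Deta = _d1(eta)
    N = nz * nr
    Iz = sp.identity(nz, format="csr")
    Ie = sp.identity(nr, format="csr")
    Kxi = sp.kron(Dxi, Ie, format="csr")  # d/dxi
    Keta = sp.kron(Iz, Deta, format="csr")  # d/deta

    Rg = np.repeat(R, nr)  # R(z) per node, z-major ordering
    dRdz = Dxi @ R
    dRg = np.repeat(dRdz, nr)
    etag = np.tile(eta, nz)
    rg = etag * Rg  # physical radius per node

    Sg = sp.diags(etag * dRg / Rg)  # eta R'/R
    Dz = (Kxi - Sg @ Keta).tocsr()  # d/dz at fixed r
    Dr = (sp.diags(1.0 / Rg) @ Keta).tocsr()  # d/dr

    Dzz = (Dz @ Dz).tocsr()
    Drr = (Dr @ Dr).tocsr()

    idx = np.arange(N).reshape(nz, nr)
    axis_nodes = idx[:, 0]
    wall_nodes = idx[:, -1]
    inlet_nodes = idx[0, :]
    outlet_nodes = idx[-1, :]
    interior = np.ones(N, dtype=bool)
    for b in (axis_nodes, wall_nodes, inlet_nodes, outlet_nodes):
        interior[b] = False

    with np.errstate(divide="ignore"):
        inv_r = np.where(rg > 0, 1.0 / rg, 0.0)

    # --- psi system: E^2 psi = -r omega ----------------------------------
    Apsi = (Drr - sp.diags(inv_r) @ Dr + Dzz).tolil()
    psi_wall = Q / (2.0 * np.pi)
    psi_in = Q / (np.pi * r_in**2) * (
        (eta * r_in) ** 2 / 1.0 - (eta * r_in) ** 4 / (2.0 * r_in**2)
    )  # ubar*(r^2 - r^4/(2R^2)) with ubar = Q/(pi R^2)
    # Dirichlet rows
    for n_ in axis_nodes:
        Apsi.rows[n_], Apsi.data[n_] = [n_], [1.0]
    for n_ in wall_nodes:
        Apsi.rows[n_], Apsi.data[n_] = [n_], [1.0]
    for n_ in inlet_nodes:
        Apsi.rows[n_], Apsi.data[n_] = [n_], [1.0]
    # outlet: zero axial gradient of psi
    Kxi_l = Kxi.tolil()
    for n_ in outlet_nodes:
        if n_ in axis_nodes or n_ in wall_nodes:
            continue
        Apsi.rows[n_] = list(Kxi_l.rows[n_])
        Apsi.data[n_] = list(Kxi_l.data[n_])
    Apsi = Apsi.tocsc()
    psi_lu = spla.splu(Apsi)

    def solve_psi(omega_vec):
        b = -rg * omega_vec
        b[axis_nodes] = 0.0
        b[wall_nodes] = psi_wall
        b[inlet_nodes] = psi_in
        out_free = [n_ for n_ in outlet_nodes if n_ not in (idx[-1, 0], idx[-1, -1])]
        b[out_free] = 0.0
        return psi_lu.solve(b)

    # axis limit: fit u_z = u0 + c r^2 to the first interior nodes (using
    # psi directly amplifies its small near-axis error by 1/r^2)
    _axis_fit = np.linalg.pinv(
        np.column_stack([np.ones(3), eta[1:4] ** 2])
    )

    def velocities(psi_vec):
        uz = inv_r * (Dr @ psi_vec)
        ur = -inv_r * (Dz @ psi_vec)
        uz = uz.reshape(nz, nr)
        ur = ur.reshape(nz, nr)
        coef = uz[:, 1:4] @ _axis_fit.T
        uz[:, 0] = coef[:, 0]
        ur[:, 0] = 0.0
        uz[:, -1] = 0.0  # no-slip
        ur[:, -1] = 0.0
        return uz.ravel(), ur.ravel()

    # --- omega transport: upwinded convection in mapped coordinates ------
    Keta_b, Keta_f = _upwind_pair(eta)
    Kxi_b, Kxi_f = _upwind_pair(z)
    Kxi_bb = sp.kron(Kxi_b, Ie, format="csr")
    Kxi_ff = sp.kron(Kxi_f, Ie, format="csr")
    Keta_bb = sp.kron(Iz, Keta_b, format="csr")
    Keta_ff = sp.kron(Iz, Keta_f, format="csr")

    Ldiff = (Drr + sp.diags(inv_r) @ Dr - sp.diags(inv_r**2) + Dzz).tocsr()

    omega = np.zeros(N)
    omega_in = 4.0 * ubar_in * (eta * r_in) / r_in**2  # -du_z/dr, parabolic
    residuals: list = []

    def axial_pressure(uz_vec, ur_vec):
        """Mean axial pressure gradient per section from the momentum
        equation at interior nodes, integrated to p(z) with p(outlet)=0."""
        if Q == 0.0:
            return np.zeros(nz)
        lap = Drr @ uz_vec + inv_r * (Dr @ uz_vec) + Dzz @ uz_vec
        conv = uz_vec * (Dz @ uz_vec) + ur_vec * (Dr @ uz_vec)
        dpdz_n = (mu * lap - rho * conv).reshape(nz, nr)
        w = rg.reshape(nz, nr)[:, 1:-1]  # area weight, axis/wall excluded
        dpdz = (dpdz_n[:, 1:-1] * w).sum(axis=1) / w.sum(axis=1)
        p = np.concatenate(
            [[0.0], np.cumsum(0.5 * (dpdz[1:] + dpdz[:-1]) * np.diff(z))]
        )
        return p - p[-1]

    if Q == 0.0:
        psi = solve_psi(omega)
        uz, ur = velocities(psi)
        return _package(
            vessel, config, z, eta, R, uz, ur, psi, omega, mu, rho,
            np.zeros(nz), residuals, 0,
        )

    dn_wall = (eta[-1] - eta[-2]) * R / np.sqrt(1.0 + dRdz**2)  # normal spacing

    # --- coupled (psi, omega) Picard iteration ---------------------------
    # The no-slip wall vorticity (Thom's formula) is kept *implicit*: it is
    # a linear relation between omega and psi at the wall, so psi and omega
    # are solved together in one 2N x 2N sparse system per iteration, and
    # only the convection coefficients (velocities) are lagged. Lagging the
    # wall vorticity instead is the classic source of grid-dependent
    # oscillatory divergence in psi-omega methods.
    B11 = Apsi  # psi block with BC rows already applied (csc)
    D12 = sp.diags(rg).tolil()  # +r*omega in the interior psi equation
    for b_nodes in (axis_nodes, wall_nodes, inlet_nodes, outlet_nodes):
        for n_ in b_nodes:
            D12.rows[n_], D12.data[n_] = [], []
    B12 = D12.tocsr()

    # wall rows of the omega equations: omega_w - 2 (psi_w - psi_{w-1}) /
    # (R dn^2) = 0; the inlet-wall corner keeps the inlet Dirichlet value
    B21 = sp.lil_matrix((N, N))
    wall_coeff = 2.0 / (R * dn_wall**2)
    for k, n_ in enumerate(wall_nodes):
        if n_ == idx[0, -1]:
            continue
        B21[n_, n_] = -wall_coeff[k]
        B21[n_, n_ - 1] = wall_coeff[k]
    B21 = B21.tocsr()

    b_psi = np.zeros(N)
    b_psi[wall_nodes] = psi_wall
    b_psi[inlet_nodes] = psi_in
    b_psi[axis_nodes] = 0.0
    out_free = [n_ for n_ in outlet_nodes if n_ not in (idx[-1, 0], idx[-1, -1])]
    b_psi[out_free] = 0.0

    psi = solve_psi(omega)
    uz, ur = velocities(psi)
    relax = config.relaxation
    converged = False
    # upwind directions switch discretely with velocity signs; once the
    # iteration is nearly converged, freeze them to break the tiny limit
    # cycle the switching would otherwise sustain near sign-change nodes
    frozen = None
    freeze_at = max(1.0e-3, 10.0 * config.tolerance)
    for it in range(config.max_iterations):
        # contravariant convection velocities in (xi, eta)
        U_xi = uz
        U_eta = (ur - etag * dRg * uz) / Rg

        if frozen is None:
            sz = U_xi >= 0.0
            se = U_eta >= 0.0
        else:
            sz, se = frozen

        Cz = sp.diags(np.where(sz, U_xi, 0.0)) @ Kxi_bb + sp.diags(
            np.where(~sz, U_xi, 0.0)
        ) @ Kxi_ff
        Ce = sp.diags(np.where(se, U_eta, 0.0)) @ Keta_bb + sp.diags(
            np.where(~se, U_eta, 0.0)
        ) @ Keta_ff
        B22 = (Cz + Ce - sp.diags(ur * inv_r) - nu * Ldiff).tolil()

        b_om = np.zeros(N)
        for n_ in axis_nodes:
            B22.rows[n_], B22.data[n_] = [n_], [1.0]
        for k, n_ in enumerate(wall_nodes):
            if n_ == idx[0, -1]:
                continue
            B22.rows[n_], B22.data[n_] = [n_], [1.0]
        for k, n_ in enumerate(inlet_nodes):
            B22.rows[n_], B22.data[n_] = [n_], [1.0]
            b_om[n_] = omega_in[k]
        for n_ in outlet_nodes:
            if n_ in (idx[-1, 0], idx[-1, -1]):
                continue
            B22.rows[n_] = list(Kxi_l.rows[n_])
            B22.data[n_] = list(Kxi_l.data[n_])
            b_om[n_] = 0.0

        A = sp.bmat([[B11, B12], [B21, B22.tocsr()]], format="csr")
        b_full = np.concatenate([b_psi, b_om])
        # equilibrate: psi ~ Q/(2 pi) while omega ~ 1-10 and the wall-
        # coupling entries are ~1/dn^2; without scaling the round-off floor
        # sits orders of magnitude above the convergence tolerance
        col = np.concatenate([np.full(N, psi_wall), np.ones(N)])
        A = A @ sp.diags(col)
        row = np.asarray(abs(A).max(axis=1).todense()).ravel()
        row[row == 0] = 1.0
        A = sp.diags(1.0 / row) @ A
        x = spla.spsolve(A.tocsc(), b_full / row)
        psi_new, omega_new = x[:N] * psi_wall, x[N:]

        scale = max(np.abs(omega_new).max(), 1e-30)
        res = float(np.abs(omega_new - omega).max() / scale)
        residuals.append(res)
        if frozen is None and res < freeze_at:
            frozen = (sz, se)
        omega = omega + relax * (omega_new - omega)
        psi = psi + relax * (psi_new - psi)
        uz, ur = velocities(psi)
        if res < config.tolerance:
            converged = True
            break

    if not converged:
        raise ConvergenceError(
            f"vorticity iteration stalled at residual {residuals[-1]:.3e} "
            f"after {config.max_iterations} iterations",
            residuals=residuals,
        )

    return _package(
        vessel, config, z, eta, R, uz, ur, psi, omega, mu, rho,
        axial_pressure(uz, ur), residuals, len(residuals),
    )


def _package(vessel, config, z, eta, R, uz, ur, psi, omega, mu, rho,
             p_axis, residuals, iterations) -> SolveResult:
    nz, nr = config.nz, config.nr
    UZ = uz.reshape(nz, nr)
    UR = ur.reshape(nz, nr)
    delta_p = float(p_axis[0])

    field3d = _revolve(z, eta, R, UZ, UR, p_axis, config.output_shape)
    field3d.meta.update(
        {"solver": "axisym_psi_omega", "mu": mu, "delta_p": delta_p}
    )
    return SolveResult(
        field=field3d, z=z, eta=eta, radius=R, u_z=UZ, u_r=UR,
        psi=psi.reshape(nz, nr), omega=omega.reshape(nz, nr),
        p_axis=p_axis, delta_p=delta_p, mu=float(mu),
        residuals=residuals, iterations=iterations,
    )


def _revolve(z, eta, R, UZ, UR, p_axis, shape) -> VelocityField:
    """Map the axisymmetric solution onto a Cartesian grid (mm, m/s)."""
    nx, ny, nzc = shape
    Rmax = float(R.max()) * 1e3  # mm
    L = float(z[-1]) * 1e3
    grid = GridSpec.from_bounds(
        (-Rmax, -Rmax, 0.0), (Rmax, Rmax, max(L, 1e-9)), (nx, ny, nzc)
    )
    X, Y, Z = grid.meshgrid()  # mm
    zq = np.clip(Z.ravel() * 1e-3, z[0], z[-1])
    rho = np.sqrt(X**2 + Y**2).ravel() * 1e-3  # m
    Rq = np.interp(zq, z, R)
    etaq = np.where(Rq > 0, rho / Rq, 2.0)

    uz_i = RegularGridInterpolator((z, eta), UZ, bounds_error=False, fill_value=0.0)
    ur_i = RegularGridInterpolator((z, eta), UR, bounds_error=False, fill_value=0.0)
    pts = np.column_stack([zq, np.clip(etaq, 0.0, 1.0)])
    uzq = uz_i(pts)
    urq = ur_i(pts)
    inside = etaq <= 1.0
    uzq[~inside] = 0.0
    urq[~inside] = 0.0

    with np.errstate(divide="ignore", invalid="ignore"):
        cx = np.where(rho > 0, X.ravel() * 1e-3 / rho, 0.0)
        cy = np.where(rho > 0, Y.ravel() * 1e-3 / rho, 0.0)
    u = np.zeros(grid.shape + (3,))
    u[..., 0] = (urq * cx).reshape(grid.shape)
    u[..., 1] = (urq * cy).reshape(grid.shape)
    u[..., 2] = uzq.reshape(grid.shape)
    mask = inside.reshape(grid.shape)
    pressure = np.interp(np.clip(Z * 1e-3, z[0], z[-1]), z, p_axis)
    return VelocityField(grid=grid, u=u, mask=mask, pressure=pressure)
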