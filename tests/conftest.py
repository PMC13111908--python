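"""Shared fixtures: canonical vessels, fields and solver runs.

Expensive flow solves are session-scoped so the oracle comparisons and the
property checks reuse the same converged solutions.
"""

import numpy as np
import pytest

from vbpaplan.flow import GridSpec, analytic_field
from vbpaplan.geometry import LesionSpec, apply_lesion, build_vessel
from vbpaplan.solver import SolverConfig, solve_steady_axisym
from vbpaplan.units import lpm_to_m3s

TUBE_RADIUS = 10.0  # mm
TUBE_LENGTH = 100.0  # mm
MU_NEWT = 0.0035  # Pa s
RHO = 1060.0  # kg/m^3


def reynolds_flow_lpm(re, radius_mm=TUBE_RADIUS, mu=MU_NEWT, rho=RHO):
    """Flow (L/min) giving the requested inlet Reynolds number."""
    r = radius_mm * 1e-3
    ubar = re * mu / (rho * 2.0 * r)
    return ubar * np.pi * r**2 * 60000.0


@pytest.fixture(scope="session")
def straight_tube():
    return build_vessel([[0, 0, 0], [0, 0, TUBE_LENGTH]], TUBE_RADIUS, 101)


@pytest.fixture(scope="session")
def ring_lesioned_tube(straight_tube):
    return apply_lesion(
        straight_tube,
        LesionSpec(kind="ring", center_s=50.0, length=40.0, severity=0.75),
    )


@pytest.fixture(scope="session")
def solver_config():
    return SolverConfig(nz=64, nr=20)


@pytest.fixture(scope="session")
def poiseuille_solution(straight_tube, solver_config):
    """Converged tube solve at Re = 100 plus its exact references."""
    q_lpm = reynolds_flow_lpm(100.0)
    sol = solve_steady_axisym(straight_tube, q_lpm, solver_config)
    q = lpm_to_m3s(q_lpm)
    r = TUBE_RADIUS * 1e-3
    return {
        "sol": sol,
        "q_lpm": q_lpm,
        "q_m3s": q,
        "ubar": q / (np.pi * r**2),
        "dp_exact": 8.0 * MU_NEWT * (TUBE_LENGTH * 1e-3) * q / (np.pi * r**4),
        "wss_exact": 4.0 * MU_NEWT * q / (np.pi * r**3),
    }


@pytest.fixture(scope="session")
def poiseuille_field():
    """Analytic parabolic tube flow on a 64^3 grid (mask = tube)."""
    grid = GridSpec.from_bounds(
        (-TUBE_RADIUS, -TUBE_RADIUS, 0.0),
        (TUBE_RADIUS, TUBE_RADIUS, TUBE_LENGTH),
        (65, 65, 65),
    )
    return analytic_field(
        "poiseuille",
        {"radius": TUBE_RADIUS, "mean_velocity": 0.1},
        grid,
    )
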