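"""Lumped Poiseuille-resistance solve on a pulmonary vessel tree.

A desk-scale surrogate for flow redistribution after balloon dilation: each
tree segment is a hydraulic resistor R = 8 mu L / (pi r^4) (integrated over
the radius profile for non-uniform segments), the root carries the cardiac
output, and every leaf sees a prescribed outlet pressure. Solving the
Kirchhoff equations yields per-segment flows, nodal pressures, the
right-to-left pulmonary artery (RPA/LPA) flow split — the perfusion-
imbalance index — and a total resistance in clinical units (dyn s cm^-5).

Viscosity defaults to the Carreau value at each segment's characteristic
wall shear rate 8*ubar/d, fixed-point iterated with the flow solution so
the rheology is consistent across the tree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dilation import BalloonSpec, vbpa1_restore, vbpa2_rigid_dilate
from .errors import SegmentLookupError, TopologyError, ValidationError
from .flow import BLOOD, FluidModel, carreau_viscosity
from .geometry import VesselModel, VesselTree
from .units import DYN_S_CM5_PER_PA_S_M3, lpm_to_m3s, m3s_to_lpm, pa_to_mmhg

__all__ = [
    "NetworkSolution",
    "segment_resistance",
    "solve_network",
    "apply_vbpa_to_tree",
]


@dataclass
class NetworkSolution:
    """Flows, pressures and derived indices of one tree solve."""

    flow: dict  # segment id -> L/min
    pressure_pa: dict  # node id (segment distal end) -> Pa; "inlet" for root
    pressure_mmhg: dict
    resistance: dict  # segment id -> Pa s/m^3
    rpa_lpa_ratio: float
    total_resistance: float  # dyn s cm^-5
    mu: dict  # segment id -> Pa s used
    inlet_flow: float  # L/min

    def pressure_drop(self) -> float:
        """Inlet pressure minus the flow-weighted mean outlet pressure, Pa."""
        q_tot = sum(self.flow[l] for l in self._leaves)
        p_out = (
            sum(self.flow[l] * self.pressure_pa[l] for l in self._leaves) / q_tot
            if q_tot > 0
            else 0.0
        )
        return self.pressure_pa["inlet"] - p_out

    _leaves: list = None  # populated by solve_network


def segment_resistance(length: float, radius, mu: float,
                       arclength=None) -> float:
    """Hydraulic resistance of one segment, Pa s / m^3.

    For a scalar radius this is the Poiseuille closed form
    ``8 mu L / (pi r^4)`` (length and radius in mm, mu in Pa s). For a
    radius profile, the resistance integral ``int 8 mu / (pi r(s)^4) ds``
    is evaluated by trapezoidal quadrature over ``arclength`` (defaults to
    uniform spacing over ``length``).
    """
    if length <= 0:
        raise ValidationError("length must be positive")
    r = np.asarray(radius, dtype=float)
    if np.any(r <= 0):
        raise ValidationError("radius must be positive")
    if r.ndim == 0:
        return 8.0 * mu * (length * 1e-3) / (np.pi * (float(r) * 1e-3) ** 4)
    s = (
        np.linspace(0.0, length, len(r))
        if arclength is None
        else np.asarray(arclength, dtype=float)
    )
    integrand = 8.0 * mu / (np.pi * (r * 1e-3) ** 4)
    return float(np.trapezoid(integrand, s * 1e-3))


def _vessel_resistance(vessel: VesselModel, mu: float) -> float:
    return segment_resistance(
        vessel.length, vessel.radius, mu, arclength=vessel.s
    )


def _segment_viscosity(vessel: VesselModel, q_lpm: float,
                       fluid: FluidModel) -> float:
    """Carreau viscosity at the mean wall shear rate estimate 8*ubar/d,
    using the segment's mean radius."""
    r_m = float(np.mean(vessel.radius)) * 1e-3
    q = lpm_to_m3s(max(q_lpm, 1e-9))
    ubar = q / (np.pi * r_m**2)
    gdot = 8.0 * ubar / (2.0 * r_m)
    return carreau_viscosity(gdot, fluid)


def solve_network(tree: VesselTree, fluid: FluidModel = BLOOD,
                  mu: float | None = None,
                  rheology_iterations: int = 4) -> NetworkSolution:
    """Solve the linear resistor network of a vessel tree.

    Unknowns are the junction pressures (one per segment distal end) plus
    the inlet pressure; equations are mass conservation at every junction,
    the prescribed cardiac output through the root, and the prescribed
    outlet pressures at the leaves. With ``mu=None`` the per-segment
    viscosity is the Carreau value at the segment's wall shear estimate,
    fixed-point iterated ``rheology_iterations`` times (flows re-solved
    with updated viscosities); passing ``mu`` freezes a single Newtonian
    value.
    """
    sids = list(tree.segments)
    if not sids:
        raise TopologyError("empty tree")
    q_in = lpm_to_m3s(tree.inlet_flow)

    # initial viscosity guess: infinite-shear value
    mus = {sid: (mu if mu is not None else fluid.mu_inf) for sid in sids}
    n_pass = 1 if mu is not None else max(1, rheology_iterations)

    flows: dict = {}
    for _ in range(n_pass):
        res = {
            sid: _vessel_resistance(tree.segments[sid].vessel, mus[sid])
            for sid in sids
        }
        flows, p_node = _linear_solve(tree, res, q_in)
        if mu is None:
            mus = {
                sid: _segment_viscosity(
                    tree.segments[sid].vessel, m3s_to_lpm(flows[sid]), fluid
                )
                for sid in sids
            }

    gen1 = tree.generation_1()
    if "right" in gen1 and "left" in gen1 and flows.get(gen1["left"], 0) > 0:
        ratio = flows[gen1["right"]] / flows[gen1["left"]]
    else:
        ratio = float("nan")

    leaves = tree.leaves()
    p_out = (
        sum(flows[l] * p_node[l] for l in leaves) / q_in if q_in > 0 else 0.0
    )
    total_r = (
        (p_node["inlet"] - p_out) / q_in * DYN_S_CM5_PER_PA_S_M3
        if q_in > 0
        else 0.0
    )

    sol = NetworkSolution(
        flow={sid: m3s_to_lpm(q) for sid, q in flows.items()},
        pressure_pa=dict(p_node),
        pressure_mmhg={k: pa_to_mmhg(v) for k, v in p_node.items()},
        resistance=res,
        rpa_lpa_ratio=float(ratio),
        total_resistance=float(total_r),
        mu=dict(mus),
        inlet_flow=tree.inlet_flow,
    )
    sol._leaves = leaves
    return sol


def _linear_solve(tree: VesselTree, res: dict, q_in: float):
    """Pressure unknowns: 'inlet' + one per segment distal node."""
    sids = list(tree.segments)
    unknowns = ["inlet"] + sids
    pos = {u: i for i, u in enumerate(unknowns)}
    n = len(unknowns)
    A = np.zeros((n, n))
    b = np.zeros(n)
    leaves = set(tree.leaves())

    def upstream_node(sid):
        p = tree.segments[sid].parent
        return "inlet" if p is None else p

    # row 0: flow through root equals cardiac output
    root = tree.root
    g = 1.0 / res[root]
    A[0, pos["inlet"]] += g
    A[0, pos[root]] -= g
    b[0] = q_in

    for sid in sids:
        i = pos[sid]
        if sid in leaves:
            A[i, pos[sid]] = 1.0
            b[i] = tree.outlet_pressure[sid]
            continue
        # conservation at the distal node of sid:
        # inflow (upstream -> sid) = sum of child flows
        g = 1.0 / res[sid]
        A[i, pos[upstream_node(sid)]] += g
        A[i, pos[sid]] -= g
        for c in tree.children.get(sid, []):
            gc = 1.0 / res[c]
            A[i, pos[sid]] -= gc
            A[i, pos[c]] += gc

    p = np.linalg.solve(A, b)
    p_node = {u: float(p[pos[u]]) for u in unknowns}
    flows = {
        sid: (p_node[upstream_node(sid)] - p_node[sid]) / res[sid]
        for sid in sids
    }
    return flows, p_node


def apply_vbpa_to_tree(tree: VesselTree, segment_id: str, method: str,
                       balloon: BalloonSpec | None = None,
                       **kwargs) -> VesselTree:
    """Return a new tree with one segment virtually dilated.

    ``method`` is ``"vbpa1"`` (morphology restoration; extra keyword
    arguments are passed through, e.g. ``lesion_window``) or ``"vbpa2"``
    (rigid balloon dilation; requires ``balloon``). Only the named
    segment's vessel changes; dilation never increases its resistance.
    """
    if segment_id not in tree.segments:
        raise SegmentLookupError(segment_id)
    vessel = tree.segments[segment_id].vessel
    if method == "vbpa1":
        new_vessel, _ = vbpa1_restore(vessel, **kwargs)
    elif method == "vbpa2":
        if balloon is None:
            raise ValidationError("vbpa2 requires a balloon spec")
        new_vessel, _ = vbpa2_rigid_dilate(vessel, balloon)
    else:
        raise ValidationError(f"unknown method {method!r}")
    return tree.replace_segment(segment_id, new_vessel)
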