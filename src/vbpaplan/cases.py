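"""Synthetic patient cases and the end-to-end planning pipeline.

A synthetic case emulates the study design this toolkit targets: a
bifurcating pulmonary tree (main pulmonary artery = generation 0, right
and left pulmonary arteries = generation 1, binary splits down to
generation 7) with right-dominant disease — focal stenoses of web or ring
morphology on right-side segmental branches — plus a catheterization
record and a clinically sized balloon per lesion. The right generation-1
branch is larger than the left (flow fraction 0.55, the normal
right-dominant split), radii contract by the symmetric Murray factor
2^(-1/3) per generation, and segment lengths are four local radii.

The pipeline runs the full planning loop on such a case: virtual dilation
by both strategies, a benchmark state built from the healthy geometry with
a small residual stenosis (the post-intervention stand-in), per-state
axisymmetric flow solves driven by the pre-state segment flow (the
benchmark convention: pre-intervention cardiac output on every geometry),
lumped-network flow splits, wall-shear and vortex metrics, and the
profile-clustering comparison of each state against the benchmark.

Vortex banding needs swirl, which steady axisymmetric solutions cannot
carry (velocity and vorticity are everywhere orthogonal, so normalized
helicity vanishes identically). Helicity metrics are therefore computed on
a parameterized vortical-wake surrogate downstream of the residual throat:
streamwise vortex tubes in an axial stream, with the vortex count and the
axial-jet-to-swirl ratio tied to the state's residual stenosis so that a
tighter residual throat yields more vortex volume and a larger
high-helicity share.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .dilation import BalloonSpec, vbpa1_restore, vbpa2_rigid_dilate
from .errors import PipelineStageError, ValidationError
from .flow import GridSpec, analytic_field
from .geometry import LesionSpec, VesselTree, apply_lesion, build_tree, tube_surface_mesh
from .metrics import (
    RHCRecord,
    pvr_from_rhc,
    sawss,
    strip_sawss,
    vortex_band_volumes,
    vortex_composition,
    vortex_fields,
    wall_shear_stress,
)
from .network import solve_network
from .profiles import compare_states, extract_profile
from .solver import SolverConfig, solve_steady_axisym

log = logging.getLogger("vbpaplan")

__all__ = ["CaseBundle", "PipelineConfig", "make_synthetic_case", "run_pipeline"]

#: normal right/left flow fraction of the right lung
_RIGHT_FRACTION = 0.55
_MPA_RADIUS = 13.0  # mm
_GENERATIONS = 7
_LESION_GENERATION = 3
_N_LESIONS = 3
_LENGTH_PER_RADIUS = 4.0
#: diffuse right-sided distal narrowing (secondary microvasculopathy):
#: radius factor applied to right-side segments of generation >= 5
_MICROVASC_TAPER = 0.9
_MICROVASC_GENERATION = 5
#: balloon diameter as a fraction of the healthy lumen diameter
_BALLOON_SIZING = 0.9


@dataclass
class CaseBundle:
    """One synthetic patient case: anatomy, lesions, balloon plan, RHC."""

    tree: VesselTree  # diseased (pre) tree
    tree_spec: dict  # healthy tree specification (JSON-able)
    lesions: dict  # segment id -> LesionSpec
    balloons: dict  # segment id -> BalloonSpec
    rhc: RHCRecord
    kind: str
    severity: float
    seed: int
    meta: dict = field(default_factory=dict)

    @property
    def lesion_segments(self) -> list:
        return sorted(self.lesions)


def _tree_spec(co: float, microvasc_taper: float = _MICROVASC_TAPER) -> dict:
    """Declarative tree spec with a right-dominant generation-1 split.

    ``microvasc_taper`` < 1 narrows right-side segments beyond generation
    4, emulating the secondary distal microvasculopathy of the diseased
    lung; it is part of the patient's background anatomy and persists in
    the post-intervention benchmark (focal dilation does not treat it).
    """
    shrink = 2.0 ** (-1.0 / 3.0)
    r_right = _MPA_RADIUS * _RIGHT_FRACTION ** (1.0 / 3.0)
    r_left = _MPA_RADIUS * (1.0 - _RIGHT_FRACTION) ** (1.0 / 3.0)
    segments = [
        {
            "id": "mpa",
            "parent": None,
            "length": _LENGTH_PER_RADIUS * _MPA_RADIUS,
            "radius": _MPA_RADIUS,
            "stations": 41,
        }
    ]

    def grow(parent_id, parent_radius, gen, side):
        if gen > _GENERATIONS:
            return
        r = parent_radius * shrink
        r_eff = r
        if side == "right" and gen >= _MICROVASC_GENERATION:
            r_eff = r * microvasc_taper
        for k in range(2):
            sid = f"{parent_id}.{k}"
            segments.append(
                {
                    "id": sid,
                    "parent": parent_id,
                    "length": _LENGTH_PER_RADIUS * r,
                    "radius": r_eff,
                    "stations": 41,
                    "side": side,
                }
            )
            grow(sid, r, gen + 1, side)

    for side, r1 in (("right", r_right), ("left", r_left)):
        sid = "rpa" if side == "right" else "lpa"
        segments.append(
            {
                "id": sid,
                "parent": "mpa",
                "length": _LENGTH_PER_RADIUS * r1,
                "radius": r1,
                "stations": 41,
                "side": side,
            }
        )
        grow(sid, r1, 2, side)

    return {
        "segments": segments,
        "inlet_flow": co,
        "outlet_pressure": 0.0,
    }


def make_synthetic_case(kind: str = "web", severity: float = 0.75,
                        seed: int = 0) -> CaseBundle:
    """Generate a deterministic right-dominant synthetic case.

    ``kind`` selects the lesion morphology (``web``: short diaphragm of
    axial length 0.4 local diameters; ``ring``: smooth narrowing of 2.5
    local radii), ``severity`` the fraction of lumen area removed at each
    throat. Three lesions are placed on right-side generation-3 branches,
    mirroring the multi-segment targets of a typical intervention; each
    carries a conservatively sized balloon (diameter = 90% of the healthy
    lumen diameter, length = 3 lesion lengths). The RHC record is drawn from
    clinically plausible distributions (mPAP ~ 50 +/- 5, PAWP ~ 12 +/- 2
    mmHg, CO ~ 5.2 +/- 0.6 L/min) under the given seed.
    """
    if kind not in ("web", "ring"):
        raise ValidationError(f"kind must be 'web' or 'ring', got {kind!r}")
    if not (0.0 < severity < 1.0):
        raise ValidationError("severity must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    mpap = float(np.clip(rng.normal(50.0, 5.0), 35.0, 70.0))
    pawp = float(np.clip(rng.normal(12.0, 2.0), 6.0, 18.0))
    co = float(np.clip(rng.normal(5.2, 0.6), 3.5, 7.0))
    rhc = RHCRecord(mpap=round(mpap, 1), pawp=round(pawp, 1), co=round(co, 2))

    spec = _tree_spec(rhc.co)
    tree = build_tree(spec)

    # right generation-3 segments, deterministic order
    gen3_right = sorted(
        sid
        for sid, seg in tree.segments.items()
        if seg.generation == _LESION_GENERATION and seg.side == "right"
    )
    targets = gen3_right[:_N_LESIONS]

    if kind == "ring":
        # an extended circumferential narrowing needs a long host segment
        # (lesion + restoration window + healthy reference on both sides)
        for s in spec["segments"]:
            if s["id"] in targets:
                s["length"] = 8.0 * s["radius"]
        tree = build_tree(spec)

    lesions: dict = {}
    balloons: dict = {}
    for sid in targets:
        vessel = tree.segments[sid].vessel
        r_local = float(vessel.radius[0])
        if kind == "web":
            length = 0.4 * 2.0 * r_local  # <= half the local diameter
        else:
            length = 2.5 * r_local
        center = 0.5 * vessel.length
        lesion = LesionSpec(
            kind=kind, center_s=center, length=length, severity=severity
        )
        tree = tree.replace_segment(sid, apply_lesion(vessel, lesion))
        lesions[sid] = lesion
        # conservative clinical sizing: balloon at 90% of the healthy
        # lumen diameter, so rigid dilation leaves a small residual
        balloons[sid] = BalloonSpec(
            diameter=_BALLOON_SIZING * 2.0 * r_local,
            length=min(3.0 * length, vessel.length),
            center_s=center,
        )

    meta = {
        "tool_version": __version__,
        "generator": {
            "right_fraction": _RIGHT_FRACTION,
            "mpa_radius_mm": _MPA_RADIUS,
            "generations": _GENERATIONS,
            "lesion_generation": _LESION_GENERATION,
            "n_lesions": _N_LESIONS,
            "microvasc_taper": _MICROVASC_TAPER,
            "microvasc_generation": _MICROVASC_GENERATION,
            "balloon_sizing": _BALLOON_SIZING,
        },
    }
    return CaseBundle(
        tree=tree, tree_spec=spec, lesions=lesions, balloons=balloons,
        rhc=rhc, kind=kind, severity=severity, seed=seed, meta=meta,
    )


# ---------------------------------------------------------------------------
# Pipeline


@dataclass(frozen=True)
class PipelineConfig:
    """Numerical knobs of the end-to-end run (not study conditions)."""

    solver_nz: int = 64
    solver_nr: int = 20
    residual_severity: float = 0.1  # benchmark's residual stenosis
    vortex_grid: int = 48
    n_profile_points: int = 64
    n_circ: int = 48
    strip_width: float = 10.0  # mm, circumferential strip for SAWSS
    # swirl-to-axial ratio of the wake surrogate: a tighter residual
    # throat drives a faster axial jet through the streamwise vortex
    # cores (smaller kappa), raising the high-helicity share
    wake_kappa_base: float = 5.5
    wake_kappa_gain: float = 3.0

    def hash(self, seed: int) -> str:
        payload = {"config": asdict(self), "seed": seed, "version": __version__}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


_STATES = ("pre", "vbpa1", "vbpa2", "vpost")


def _state_vessels(case: CaseBundle, sid: str, residual: float,
                   healthy_tree: VesselTree) -> dict:
    """The four per-state geometries of one lesioned segment."""
    pre = case.tree.segments[sid].vessel
    v1, _ = vbpa1_restore(pre)
    v2, _ = vbpa2_rigid_dilate(pre, case.balloons[sid])
    lesion = case.lesions[sid]
    vpost_lesion = LesionSpec(
        kind=lesion.kind, center_s=lesion.center_s,
        length=lesion.length, severity=residual,
    )
    # benchmark: healthy geometry with a small residual stenosis
    healthy = healthy_tree.segments[sid].vessel
    vpost = apply_lesion(healthy, vpost_lesion)
    return {"pre": pre, "vbpa1": v1, "vbpa2": v2, "vpost": vpost}


def _straighten(vessel):
    """Axis-aligned copy (centerline along +z from the origin) so surface
    meshes and profile chords register with the revolved solver field."""
    from .geometry import Centerline, VesselModel

    pts = np.column_stack(
        [np.zeros_like(vessel.s), np.zeros_like(vessel.s), vessel.s]
    )
    return VesselModel(
        centerline=Centerline.from_points(pts),
        radius=vessel.radius,
        lesions=vessel.lesions,
        name=vessel.name,
    )


def _residual_stenosis(vessel) -> float:
    """Fraction of the reference area still missing at the throat."""
    r_ref = float(vessel.radius[0])
    return max(0.0, 1.0 - (vessel.min_radius() / r_ref) ** 2)


def _wake_field(vessel, u_mean: float, cfg: PipelineConfig, seed: int):
    """Vortical-wake surrogate downstream of the residual throat.

    Residual narrowing strengthens the disturbance: more vortex tubes and
    a faster axial jet relative to their swirl (lower kappa), which shifts
    vortex volume into the higher helicity bands.
    """
    residual = _residual_stenosis(vessel)
    r_ref = float(vessel.radius[0])
    kappa = max(cfg.wake_kappa_base - cfg.wake_kappa_gain * residual, 2.0)
    n_v = 3 + int(round(3.0 * residual))
    n = cfg.vortex_grid
    grid = GridSpec.from_bounds(
        (-r_ref, -r_ref, 0.0),
        (r_ref, r_ref, 4.0 * r_ref),
        (n, n, n),
    )
    return analytic_field(
        "vortex_wake",
        {
            "u_axial": u_mean,
            "kappa": kappa,
            "n_vortices": n_v,
            "core_radius": 0.18 * r_ref,
            "radius": r_ref,
            "seed": seed,
        },
        grid,
    )


def run_pipeline(case: CaseBundle, config: PipelineConfig | None = None,
                 out_dir=None) -> dict:
    """Run dilation, flow, metrics and comparison for one case.

    Returns a report dict with per-state network indices (RPA/LPA flow
    ratio, total resistance), per-segment pressure drops, SAWSS, vortex
    band volumes and composition, the profile comparison table (also under
    ``comparisons`` as records) and the case PVR. With ``out_dir`` the
    report (JSON), the comparison table (CSV) and a run log are written;
    outputs embed the config hash and are byte-reproducible under a fixed
    seed.
    """
    config = config or PipelineConfig()
    cfg_hash = config.hash(case.seed)
    t_start = time.time()
    report: dict = {
        "config_hash": cfg_hash,
        "tool_version": __version__,
        "seed": case.seed,
        "kind": case.kind,
        "severity": case.severity,
        "rhc": asdict(case.rhc),
        "pvr_dyn_s_cm5": pvr_from_rhc(case.rhc),
        "states": {},
        "segments": {},
    }

    def stage(name):
        log.info("stage %-10s +%.1fs", name, time.time() - t_start)

    # --- per-state trees and network solves ------------------------------
    stage("network")
    try:
        healthy_tree = build_tree(case.tree_spec)
        state_vessels = {
            sid: _state_vessels(
                case, sid, config.residual_severity, healthy_tree
            )
            for sid in case.lesion_segments
        }
        trees = {"pre": case.tree}
        for state in ("vbpa1", "vbpa2", "vpost"):
            t = case.tree
            for sid in case.lesion_segments:
                t = t.replace_segment(sid, state_vessels[sid][state])
            trees[state] = t
        net = {state: solve_network(t) for state, t in trees.items()}
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("network", str(exc)) from exc

    for state in _STATES:
        report["states"][state] = {
            "rpa_lpa_ratio": net[state].rpa_lpa_ratio,
            "total_resistance_dyn_s_cm5": net[state].total_resistance,
        }

    # --- per-segment solves, metrics, profiles ---------------------------
    solver_cfg = SolverConfig(nz=config.solver_nz, nr=config.solver_nr)
    profiles: dict = {s: {} for s in ("pre", "vbpa1", "vbpa2")}
    ref_profiles: dict = {}
    for sid in case.lesion_segments:
        stage(f"segment {sid}")
        vessels = state_vessels[sid]
        q_pre = net["pre"].flow[sid]  # pre-state flow for every geometry
        seg_report: dict = {"inlet_flow_lpm": q_pre}
        lesion = case.lesions[sid]
        for state, tree_vessel in vessels.items():
            vessel = _straighten(tree_vessel)
            try:
                sol = solve_steady_axisym(vessel, q_pre, solver_cfg)
            except Exception as exc:  # noqa: BLE001
                raise PipelineStageError(f"solve:{sid}:{state}", str(exc)) from exc

            try:
                mesh = tube_surface_mesh(
                    vessel, n_circ=config.n_circ,
                    distal_from_s=0.75 * vessel.length, region=sid,
                )
                wss = wall_shear_stress(
                    sol.field, mesh, newtonian_mu=sol.mu
                )
                seg_sawss = sawss(wss)
                lesion_strip = strip_sawss(
                    wss, lesion.center_s,
                    min(config.strip_width, vessel.length),
                )
            except Exception as exc:  # noqa: BLE001
                raise PipelineStageError(f"wss:{sid}:{state}", str(exc)) from exc

            try:
                u_mean = sol.field.u[..., 2][sol.field.mask].mean()
                wake = _wake_field(vessel, float(u_mean), config, case.seed)
                q_star, h, _ = vortex_fields(wake)
                bands = vortex_band_volumes(
                    q_star, h, wake.mask,
                    voxel_volume=wake.grid.voxel_volume,
                )
                comp = vortex_composition(bands)
            except Exception as exc:  # noqa: BLE001
                raise PipelineStageError(f"vortex:{sid}:{state}", str(exc)) from exc

            seg_report[state] = {
                "delta_p_pa": sol.delta_p,
                "min_radius_mm": vessel.min_radius(),
                "residual_stenosis": _residual_stenosis(vessel),
                "sawss_pa": seg_sawss,
                "strip_sawss_pa": lesion_strip,
                "vortex_volumes_mm3": list(bands.as_tuple()),
                "vortex_composition_pct": list(comp),
                "solver_iterations": sol.iterations,
            }

            # profiles at the lesion ("question") and downstream stations
            try:
                for tag, s_station in (
                    ("question", lesion.center_s),
                    (
                        "downstream",
                        min(
                            lesion.center_s + 1.5 * lesion.length,
                            0.95 * vessel.length,
                        ),
                    ),
                ):
                    region = f"{tag}:{sid}"
                    prof = extract_profile(
                        sol.field, vessel, s_station,
                        n_points=config.n_profile_points, station=region,
                    )
                    if state == "vpost":
                        ref_profiles[region] = prof
                    else:
                        profiles[state][region] = prof
            except Exception as exc:  # noqa: BLE001
                raise PipelineStageError(
                    f"profiles:{sid}:{state}", str(exc)
                ) from exc

        report["segments"][sid] = seg_report

    # --- comparison vs the benchmark -------------------------------------
    stage("compare")
    try:
        table = compare_states(profiles, ref_profiles, seed=case.seed)
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("compare", str(exc)) from exc

    report["comparisons"] = table.to_dict(orient="records")
    report["comparison_medians"] = {
        "mean_distance": table.attrs["median_mean_distance"],
        "composite": table.attrs["median_composite"],
    }
    report["n_regions"] = table.attrs["n_regions"]
    report["n_centroid_comparisons"] = table.attrs["n_centroid_comparisons"]
    report["runtime_s"] = round(time.time() - t_start, 2)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report_path = out / "report.json"
        report_clean = dict(report)
        report_clean.pop("runtime_s")  # keep outputs byte-reproducible
        report_path.write_text(json.dumps(report_clean, indent=1, sort_keys=True))
        table.to_csv(out / "comparisons.csv", index=False)
        (out / "run.log").write_text(
            f"config_hash={cfg_hash}\nseed={case.seed}\nversion={__version__}\n"
        )
    return report
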