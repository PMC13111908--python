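# Methods

This note documents the models, numerical choices and known limitations of
`vbpaplan`. It is the design record: everything here is implemented and
exercised by the test suite; no empirical claim is made beyond what the
tests and `scripts/acceptance.py` themselves compute.

## Vessel representation

A vessel segment is a 3-D centerline with a circular cross-section of
radius r(s) at every arclength station s (mm). This representation was
chosen over voxel or free-form surfaces because every operation in the
planning loop — lesioning, both dilation strategies, strip clipping,
profile extraction — is axially parameterized; with circular sections the
1-D radius profile fully determines the lumen, so profile-level spline
editing is equivalent to surface-level reconstruction. Non-circular lumens
and wall mechanics are out of scope.

Lesions remove a fraction `severity` ∈ (0,1) of the local lumen *area* at
the throat; the radius factor is √(1 − severity·w(s)) with an axial weight
w(s) ∈ [0,1] supported on `[center ± length/2]`:

* **web** — a diaphragm: product-of-tanh plateau with steep shoulders
  (shoulder time-scale length/12, plateau edges at ±0.375·length),
  normalized so the throat weight is exactly 1. Webs must be short
  (length ≤ local diameter), rings long (length > local diameter); the
  constructor enforces the morphology.
* **ring** — a raised-cosine dip over the full lesion length.

Outside the lesion support the radius is bit-identical to the input; the
property suite asserts this exactly.

Tube surfaces are swept with parallel-transport frames (no Frenet torsion
artifacts), split into `2·n_circ·(stations−1)` outward-wound lateral
triangles, optionally capped (watertight; signed volume positive). Faces
carry centroid arclength, a distal flag and a free-form region tag.

Trees are rooted, acyclic, generation-labelled by depth (main pulmonary
artery = 0), with side labels propagated from the generation-1 split and
an optional fully-developed-flow inlet extension on the root (default off;
10 local diameters when requested, the usual rule of thumb).

## Virtual dilation

**vBPA1 (morphology restoration).** Radius samples in healthy windows
(default two local diameters per side) adjacent to the lesion window
(default lesion extent ± half a lesion length) are fitted by least-squares
lines; a cubic Hermite spans the window with the side fits' values and
slopes, giving C¹ continuity. Constant and collinear healthy profiles are
reproduced exactly (machine precision), which is the basis of the
restoration tests. Two deliberate guards: the output is
max(reconstruction, input) so dilation can never narrow the lumen even
where the spline undershoots near window edges, and round-off excess below
1 part in 10⁹ is snapped back so a lesion-free vessel is returned
bit-identically. At a vessel end the one-sided fit extrapolates.

**vBPA2 (rigid dilation).** The balloon contributes a fixed shape function
B(s): D/2 across its length, cosine decay to zero over one shoulder width;
the output is max(r(s), B(s)) — a rigid balloon opens the lumen to its own
radius but cannot pull a wider wall inward (the toolkit's resolution of a
question the operation itself leaves open). The shoulder width is
max(largest station radius inside the balloon core, D/2): "one local
radius" in spirit, but defined through quantities invariant under the edit
itself, which makes re-application of the same balloon *exactly*
idempotent — an invariant the test suite checks bit-wise.

## Fluid model and flow solvers

Blood: Carreau, μ(γ̇) = μ∞ + (μ₀−μ∞)[1+(λγ̇)²]^((n−1)/2), with the
standard constants μ₀ = 0.056 Pa·s, μ∞ = 0.0035 Pa·s, λ = 3.313 s,
n = 0.3568; density 1060 kg/m³. μ is bounded in [μ∞, μ₀], monotone
non-increasing, and returns μ₀ identically at n = 1.

**Axisymmetric solver.** Steady, laminar, incompressible flow through one
straightened vessel, in stream-function–vorticity form on a body-fitted
grid (ξ = z, η = r/R(z)). Differentiation matrices are built per axis
(three-point Lagrange, arbitrary spacing) and mapped by the chain rule;
convection is first-order upwind in the mapped contravariant velocities.
Boundary conditions: fully developed parabolic inflow, zero-gradient
outflow, axis symmetry, and no-slip with the wall vorticity tied to the
stream function through Thom's relation *inside* the linear system — the
coupled 2N×2N solve per Picard iteration is what makes the iteration
robust, because lagging the wall vorticity is the classic source of
grid-dependent oscillatory divergence in ψ–ω methods. Three further
numerical choices matter:

* the coupled matrix is column-scaled (ψ by Q/2π) and row-equilibrated;
  without this the round-off floor sits orders of magnitude above the
  10⁻⁶ residual target (wall-coupling entries scale as 1/Δn²);
* upwind directions are frozen once the residual falls below max(10⁻³,
  10·tol), breaking the tiny limit cycle that discrete sign switching
  sustains near stagnant nodes;
* the axis velocity is recovered from a least-squares fit of
  u_z = u₀ + c·r² over the first interior nodes rather than from ψ/r²,
  which would amplify the near-axis stream-function error.

Pressure: the mean axial gradient per section is evaluated from the full
axial momentum balance at interior nodes (area-weighted), then integrated
to p(z) with 0 Pa at the outlet — the reduced-order outflow assumption
used throughout. Defaults: 96×24 nodes, under-relaxation 0.4, residual
tolerance 10⁻⁶ (the conventional CFD criterion), 400 iterations max;
non-convergence raises with the residual trace attached. The inlet
Reynolds number is capped at 500 (laminar steady regime). Verified
accuracy at the default grid (acceptance script): velocity profile 0.6%
L², pressure drop 2.1% vs 8μLQ/πr⁴, per-section flux error 0.56%
(stream-function boundary values make flux conservation structural).
Carreau coupling enters as a scalar effective viscosity at the
characteristic wall shear rate 8ū/d of the tightest station — a deliberate
simplification that keeps the constant-ν ψ–ω form valid; the Newtonian
default uses μ∞.

**Resistance network.** Each segment is R = ∫ 8μ/(πr(s)⁴) ds (trapezoid;
closed form for uniform radius). Unknown junction pressures (plus the
inlet) solve the Kirchhoff system with the cardiac output prescribed at
the root and outlet pressures at the leaves. Per-segment viscosity is
Carreau at the wall shear estimate 8ū/d, fixed-point iterated (4 passes)
with the flows so the rheology is consistent tree-wide. Total resistance
is reported in dyn·s·cm⁻⁵ (1 Wood unit = 80 dyn·s·cm⁻⁵; 1 Pa·s/m³ =
10⁻⁵ dyn·s·cm⁻⁵) and, over a conduit tree with 0 Pa outlets, reflects only
the resolved generations — it tracks intervention trends, not clinical
PVR magnitudes, which are dominated by the unresolved microvasculature.

## Hemodynamic metrics

**Vortex banding.** Velocity gradients by second-order central
differences (one-sided at edges); Q = ½(‖Ω‖²−‖S‖²) in Frobenius norms
(so pure shear gives Q ≡ 0 and solid rotation Q = ω² exactly, both tested
analytically). Q is normalized by its positive maximum over the lumen
mask (zeros if none). Normalized helicity H = u·ω/(|u||ω|) ∈ [−1,1],
defined 0 where the denominator vanishes. A voxel is vortex if Q* ≥ q_min
(default 0.2); bands are the nested super-level sets |H| ≥ 0.2/0.5/0.8
(low/moderate/high), volumes are voxel counts × voxel volume. Both gates
are parameters because the low/moderate/high banding can be read either
as Q-iso levels or helicity levels; the helicity reading is the default.
Composition percentages: moderate% = v_mod/v_low, high% = v_high/v_low,
low% = 100 − moderate% − high%, rounded to two decimals *after* the
arithmetic. This formula reproduces every column of the reference
band-volume table the acceptance suite carries, to the printed two
decimals; a negative low remainder (possible if bands were reported
non-nested) attaches a warning rather than an error.

**Wall shear stress.** Per face, WSS = μ·|du_t/dn| with the tangential
velocity sampled at 1.5 and 3 grid spacings along the inward normal and
the no-slip value at the face: |4u₁ − u₂|/2h. The 1.5-spacing offset
keeps samples clear of the interpolation kink at the masked wall; accuracy
is limited by the faceted mesh's centroid sagitta (≈ 3δ/2h relative), so
the oracle test uses n_circ = 64 (2.8% vs 4μQ/πr³) and the pipeline
n_circ = 48. SAWSS is the area-weighted mean after excluding distal faces
above 5 Pa (focal-anomaly rule; scope switchable to all faces or none);
strip variants restrict to faces whose centroid arclength falls in a
circumferential band. PVR = (mPAP−PAWP)/CO × 80; a wedge pressure above
mPAP yields a flagged negative value rather than an error.

**Profile comparison.** Velocity magnitude along a diameter chord,
normalized to (s, v) ∈ [0,1]² (position by chord length, velocity by the
station maximum; the normalization constants are recorded on the sample).
k-means with k = 4, 10 restarts, seeded; clusters relabeled 1–4 by
ascending centroid s so 1/4 are near-wall and 2/3 central flow, and label
alignment across states is by this ordering (not Hungarian matching),
matching the fixed cluster semantics. Deviation from the benchmark is
summarized as (a) Euclidean distances between same-label centroids, per
cluster and their mean (mean is the headline; all four are emitted), and
(b) the composite score on the central-flow points:
0.2·symmetric Hausdorff + 0.4·Wasserstein + 0.4·Procrustes, weights
validated to sum to 1. Wasserstein is the exact 1-D distance on the
v-marginals (sorted samples — deterministic, no transport solver);
Procrustes is the residual sum of squares after optimal
translation/rotation/scaling of equal-size sets (resampled to 100 points
by sorted-s interpolation), normalized by the reference's centered sum of
squares — scale-free, 0 for congruent sets. For a pure velocity shift δ
the decomposition is exact: Wasserstein = δ, Hausdorff = δ (when point
spacing exceeds δ), Procrustes ≈ 0, composite = 0.6δ; the acceptance
suite asserts this closed form.

## Synthetic cases

The generator emulates a right-lesion-dominant CTEPH study design:

| parameter | default | rationale |
|---|---|---|
| MPA radius | 13 mm | adult main pulmonary artery |
| generations | 0–7 | segmentation depth of the target anatomy |
| right flow fraction | 0.55 | normal right-dominant perfusion (healthy tree ratio 1.22) |
| radius contraction | 2^(−1/3) per generation | symmetric Murray's law |
| segment length | 4 radii (8 for ring hosts) | pulmonary artery proportions; ring lesions plus restoration windows need the longer host |
| lesions | 3, right generation-3 branches | multi-segment intervention targets |
| severity | 0.75 area removal | severe focal stenosis |
| web length | 0.4 local diameters | short diaphragm |
| ring length | 2.5 local radii | extended narrowing |
| microvasculopathy | right radii ×0.9, generations ≥5 | secondary distal disease; depresses the pre ratio to ≈0.84, inside the clinically observed 0.75–0.94 band, and persists in the benchmark (dilation does not treat it) |
| balloon sizing | 0.9 × healthy diameter | conservative clinical sizing; leaves rigid dilation with a 19% area residual so the two strategies are distinguishable |
| RHC record | mPAP 50±5, PAWP 12±2 mmHg, CO 5.2±0.6 L/min | severe pre-capillary hypertension, seeded |
| benchmark residual | 0.1 severity | post-intervention lumens are rarely perfect |

The pipeline runs the four states (pre, vBPA1, vBPA2, benchmark) through
the network and the per-segment axisymmetric solver, all driven by the
*pre*-state segment flow — the benchmark convention that isolates the
geometric effect from cardiac-output changes. Because steady axisymmetric
swirl-free solutions have u ⊥ ω pointwise (H ≡ 0), helicity banding is
computed on a **vortical-wake surrogate**: a parabolic axial stream
threaded by seeded off-axis streamwise vortex tubes (Gaussian cores,
alternating sense). Its two knobs map from the state's residual stenosis:
vortex count 3 + round(3·residual), and axial-to-swirl ratio κ = 5.5 −
3·residual (floored at 2) — a tighter residual throat drives a faster jet
through the vortex cores, aligning velocity with the streamwise vorticity
and raising the high-helicity share, the phenomenology reported for
diseased pulmonary trunks. The surrogate is a synthetic stand-in with
controllable vortex/helicity content, not a solution of the governing
equations; banding results on it demonstrate the metric pipeline and
relative trends, not patient hemodynamics.

What the synthetic data do **not** emulate: curved and non-circular
patient lumens, bifurcation secondary flows, pulsatility, wall
compliance, and genuinely three-dimensional vortex dynamics. Passing
tests therefore validate the geometry operators, the metric definitions
and the comparison machinery against closed forms and invariants — they
do not certify predictive accuracy on patient anatomies.

## Determinism and reproducibility

All randomness flows from explicit integer seeds (case generation, wake
placement, k-means restarts). Pipeline outputs embed a SHA-256 hash of the
numerical configuration and seed; re-running with the same seed reproduces
`report.json` and `comparisons.csv` byte-for-byte, asserted in the
acceptance suite. The acceptance script (`scripts/acceptance.py --seed N
--out results.json`) recomputes clinical arithmetic, analytic oracles and
pipeline trends from scratch; reported problem sizes are the grid/tree
sizes actually used, chosen so the whole script completes in well under a
minute.

## Known limitations

* The axisymmetric solver handles one straightened segment; bifurcation
  flow and 3-D patient geometries are out of scope by design.
* RANS-style turbulence closures are not implemented; flows are laminar
  steady (inlet Re ≤ 500), consistent with the mean-state focus.
* The conduit-tree resistance ignores distal microvascular beds beyond
  the taper surrogate, so absolute resistances are far below clinical
  PVR; only relative changes are meaningful.
* Printed clinical PVR tables are reproduced only where they are
  self-consistent with their own inputs; the stated formula is
  implemented without adjustment.
* WSS accuracy degrades with coarse surface meshes (centroid sagitta) and
  near strong curvature; SAWSS comparisons across states use identical
  meshing so the bias cancels.
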