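# Methods

`portaflow` models the hemodynamics of a portal-vein anastomotic stenosis in
a living-donor liver-transplant recipient, before balloon angioplasty and at
two follow-up timepoints (1 week, 6 months).  The package replaces the
patient's CT-reconstructed lumen — which is not publicly available — with a
parametric axisymmetric idealization carrying the clinically measured
dimensions, and solves steady laminar non-Newtonian flow through it with
physiological outlet loading.  This note records the model, its assumptions,
the numerical choices, and what the idealization can and cannot show.

## Geometry idealization

The right portal trunk is modeled as a body of revolution: radius function
R(z) built from cosine (C¹) segments — a straight inlet run, an optional
dilation ramp, a plateau at the pre-stenotic maximum, a cosine constriction
to the anastomotic throat over half the stenosis length, a cosine recovery to
the downstream trunk bore, and a straight run to the outlet.  Cosine blending
gives zero slope at every junction, so the minimum radius is attained exactly
at the throat and the profile has no curvature kinks that would seed spurious
separation.

Per-timepoint presets (diameters in mm, velocities in cm/s):

| timepoint | throat | pre-stenotic max | trunk | inlet peak velocity |
|-----------|--------|------------------|-------|---------------------|
| preop     | 5.1    | 15.2             | 8.8   | 13.45               |
| week1     | 8.0    | 12.0             | 8.8   | 13.32               |
| month6    | 8.0    | 11.0             | 8.8   | 15.13               |

Throat, pre-stenotic and Doppler values are the measured ones.  Choices made
once where no measurement exists:

* **Inlet bore = pre-stenotic maximum.**  The Doppler peak was measured in
  the pre-stenotic segment, so the inlet plane is placed there and the
  measured peak imposed directly on the section it belongs to.  This also
  keeps the inlet volumetric flow consistent across timepoints
  (Q = πR²·peak/2 falls slightly from week 1 to month 6 as the lumen
  normalizes, rather than rising with the velocity).
* **Downstream trunk 8.8 mm** — the area-equivalent single conduit of the
  two branch bores (5.0 and 7.3 mm).
* **Stenosis length 10 mm, total trunk length 60 mm, branch lengths 30 mm**
  — anatomically plausible placeholders, flagged as such in the config.

The mesh is a structured quad grid: uniform axial stations at the maximum
cell size (default 0.65 mm, the grid-independent size of the study protocol)
and per-station radial nodes stacking an exact geometric-progression wall
layer (first height 0.065 mm, ratio 1.2, five layers; total 0.4837 mm) over a
near-uniform core.  The radial cell count is fixed across stations, so the
core contracts smoothly through the throat.  y⁺ of the first cell centroid
(half the first layer height — the reference point of a cell-centred scheme)
evaluates to ≈1.7 at the preop peak wall shear stress, i.e. the viscous
sublayer is resolved.

## Rheology

Blood is an incompressible Carreau–Yasuda fluid, ρ = 1060 kg/m³:

    μ(γ̇) = μ∞ + (μ0 − μ∞)·[1 + (λγ̇)^a]^((n−1)/a)

with the canonical whole-blood set μ0 = 0.056 Pa·s, μ∞ = 3.45 mPa·s,
λ = 3.313 s, a = 2, n = 0.3568 (config-overridable; a Newtonian model is
also available).  Shear rate is the strain-rate magnitude √(2 D:D) including
the azimuthal (hoop) component u_r/r.  Absolute viscous quantities (wall
shear, viscous pressure loss) depend on this parameter choice; ratios and
trends are much less sensitive.  The portal regime is strongly shear-thinning:
at the ~10–100 s⁻¹ rates of the trunk the effective viscosity is 2–3× the
high-shear plateau.  Pipe Reynolds numbers stay far below 2000 (≈766 at the
preop throat with μ∞), so the flow is treated as laminar throughout.

## Flow solver

Collocated finite volumes on the structured axisymmetric grid.  Cells are
full revolved rings: all face areas carry the 2πr factor, so face mass fluxes
are true flow rates and continuity telescopes to exact global mass
conservation (measured imbalance ~10⁻¹² relative).  Steady states are reached
by pseudo-transient continuation; each inner iteration is a Chorin-type
projection:

1. **Predictor** — explicit first-order-upwind axial advection and central
   axial diffusion; radial advection and diffusion are *implicit* (one
   tridiagonal solve per axial column, vectorized across columns).  The
   implicit radial sweep removes the viscous stability limit of the 65 µm
   wall cells, which would otherwise force pseudo-time steps three orders of
   magnitude smaller.  The azimuthal diffusion sink −μu_r/r² of the radial
   momentum equation is folded into the implicit diagonal.  Viscous terms use
   the Laplacian (constant-μ) form with the local Carreau–Yasuda viscosity;
   the transpose-gradient term of the full stress divergence is neglected, a
   standard simplification that does not affect the verification suite.
2. **Pressure Poisson solve** — the operator depends only on the mesh and is
   LU-factorized once per run; Neumann at inlet/wall/axis, Dirichlet at the
   outlet.  Because the face-flux correction uses the same compact stencil,
   the corrected fluxes are discretely divergence-free every iteration and
   cell-to-cell pressure decoupling (checkerboarding) is suppressed.
3. **Correction** — face fluxes and cell velocities updated; corrected
   fluxes advect the next iteration.

The splitting error of the projection vanishes at the fixed point, so the
converged field satisfies the discrete momentum and continuity equations
simultaneously.  The inner pseudo-time step is set from the axial CFL bound
with a conservative a-priori velocity estimate (mass-conservation
amplification through the throat); inner steps are grouped into outer steps
of dt = 0.005 s (up to 1000 of them, per the study protocol) at which
viscosity, outlet coupling, monitors and residuals are refreshed.

**Boundary conditions.**  Inlet: prescribed profile, parabolic with
centerline equal to the Doppler peak by default — the unique fully developed
laminar profile consistent with a stated maximum (a plug option exists);
inlet face fluxes are exact annular integrals of the profile.  Walls: rigid,
no-slip.  Axis: symmetry (zero-area degenerate faces).  Outlet: pressure from
the Windkessel coupling (below), zero-gradient velocity.

**Convergence** requires the residual (maximum velocity change per outer
step, normalized by the inlet peak) to fall below 10⁻⁵ *and* the outlet flow
and pressure monitors to vary by less than 0.1% over the trailing 100 outer
steps.  The residual threshold is interpreted as a normalized quantity; the
monitor window/tolerance are package choices (the protocol names monitor
stabilization without a number).  Runs are bitwise deterministic: zero
initial fields, fixed iteration counts, no randomness anywhere — so no seeds
are needed or used.

**Wall shear stress** is recovered post hoc per wall facet from a one-sided
quadratic fit of the wall-tangential velocity at the two outermost cell
centroids (exact for a parabolic profile), evaluated with μ(γ̇_w).

### Verification

On a straight tube (R = 2.5 mm, L = 20 mm, Newtonian μ = 3.5 mPa·s,
Q = 10⁻⁵ m³/s) against the Poiseuille closed forms at the
default-layered 0.4 mm mesh: pressure drop within 0.9%, wall shear within
1.2%, mass imbalance ~10⁻¹²%.  A uniform refinement ladder (R/8…R/16, wall
layer scaled with the mesh so refinement is geometrically similar) shows the
plane-to-plane pressure-drop error decreasing monotonically and consecutive
indicator differences below the 1% grid-independence criterion.  Stokes-regime
linearity (pressure drop ∝ inlet velocity) holds to <1%.  Note two
discretization facts exposed by the suite: *facet maxima* of WSS include
one-sided boundary-cell artifacts at the inlet/outlet (interior values are
the accurate ones), and a shear-thinning fluid legitimately blunts the
imposed parabola along a straight tube (centerline decays a few percent), so
closed-form checks are run Newtonian.

## Windkessel outlets

Each branch terminal is a three-element Windkessel: Rc in series with
(Rd ∥ C), referenced to Pd = 0 Pa — a gauge, so every reported pressure is
relative.  Clinically calibrated values: RAPV Rc = 2.7175e8, Rd = 1.9017e9;
RPPV Rc = 2.4875e8, Rd = 1.8697e9 Pa·s/m³; C = 9.4916e-9 m³/Pa for both.
The compliance ODE C·dPc/dt = Q − (Pc − Pd)/Rd is advanced by backward Euler
(unconditionally stable, first-order, verified against the analytic
exponential; time constant Rd·C ≈ 18.05 s for RAPV).

Because the axisymmetric domain ends at the trunk, the single computational
outlet carries the steady-equivalent parallel combination of the two branch
terminals; the branch split itself is delegated to the 0D network.  The
default solver coupling is **quasi-steady** — P = Pd + Q·(Rc+Rd), the ODE
fixed point — because the compliance time constant (≈18 s) far exceeds the
5 s pseudo-time window, so a transient-coupled outlet pressure could never
satisfy the monitor-stability criterion, and at a steady state compliance is
invisible anyway.  The transient backward-Euler coupling remains available
(`wk3_coupling: transient`) for time-resolved studies.

## 0D network

Branch flows are solved on a lumped trunk–bifurcation–terminal network:
integrated Poiseuille resistances ∫8μ/(πr⁴)dz per segment (quadrature over
arbitrary radius profiles), a stenosis element combining that viscous
resistance with a Borda–Carnot expansion loss
Kt·(ρ/2)·V_s|V_s|·(1 − As/A0)² (Kt = 1 by default), and steady Windkessel
terminals.  Segment viscosity is the Carreau–Yasuda value at the Poiseuille
wall shear rate 8V/D, refreshed every Newton iterate.  A damped Newton
iteration on the leaf flows (finite-difference Jacobian, relative step 10⁻³)
drives the junction pressure mismatch below 10⁻⁸ Pa; mass conservation holds
by construction, and linear configurations converge in a single step.

With the calibrated terminals the two branch path resistances are nearly
equal, so the network predicts an anterior/posterior split ≈0.975 — not the
≈0.5 observed in the patient.  The clinical asymmetry is a patient-geometry
and parenchymal-resistance effect that a terminal-resistance divider cannot
produce; the comparison tables document this discrepancy rather than tuning
the terminals to hide it.

## Clinical metrics

* Region extents come from the profile features: pre-stenotic = everything
  upstream of the constriction, stenotic = the constriction support,
  post-stenotic = one throat-diameter window downstream of the stenosis exit;
  extents are recorded in every report.
* Probe planes: pre-stenotic at the axial position of maximum radius (the
  position nearest the stenosis when the maximum is a plateau), stenotic at
  the throat, post-stenotic one throat diameter past the stenosis exit.
  Plane pressures are cross-sectional area averages with the 2πr weighting;
  planes inside a boundary half-cell are linearly extrapolated from the two
  outermost cell columns.
* Peak regional velocity is the maximum velocity magnitude over the region's
  cross-sections (Doppler-peak semantics); WSS extrema are taken over the
  wall surface.
* PVV ratio = stenotic/pre-stenotic peak; WSS ratio = post-/pre-stenotic
  maximum; trans-stenotic gradient = pre-plane minus post-plane average
  pressure (also in mmHg, 133.322 Pa/mmHg); percent reduction =
  100·(earlier − later)/earlier.

## What the idealization shows — and what it does not

The synthetic geometry reproduces the *mechanism*: a ≈9:1 area contraction
accelerates the jet, steepens near-wall gradients, and concentrates the
pressure loss at the anastomosis; dilating the throat from 5.1 to 8 mm
removes the jet, collapses the gradient by >90%, and drops peak WSS by an
order of magnitude — the same trajectory as the clinical case.  At the
default settings the preop gradient evaluates to ≈1.7 mmHg against the
1.8 mmHg catheter pull-back.  It does **not** reproduce patient-specific
absolutes: there is no bifurcation recirculation, no out-of-plane curvature,
no branch-bed asymmetry, and the measured 2:1 branch split is out of reach of
the 0D terminals (above).  Accordingly the tests assert trends, closed-form
verifications and metric arithmetic, never the patient's 3D field values,
which appear only as labelled comparison rows.

## Problem sizes and tolerances

Default study meshes are ≈1500 cells (93 axial × 13–16 radial at 0.65 mm
with the five-layer wall stack) — the axisymmetric reduction needs three
orders of magnitude fewer cells than the patient's 3D hybrid meshes while
resolving the same near-wall physics; a timepoint converges in 100–150 outer
steps (a few seconds).  Verification meshes range from 216 to 2048 cells.
Numerical tolerances: solver residual 10⁻⁵ (10⁻⁸ in refinement ladders),
monitor span 10⁻³ over 100 steps, network mismatch 10⁻⁸ Pa, quadrature
relative error ~10⁻¹⁰.  Degenerate inputs are handled explicitly: zero
inflow returns the exact null field at the reference pressure; equal
diameters give a straight tube whose meshed volume matches πR²L to machine
precision; a mesh size below the first wall-layer height is rejected.

## Known limitations

Axisymmetric (no secondary flow, no bifurcation hemodynamics); rigid walls;
steady inflow (portal pulsatility neglected, consistent with the low
pulsatility of portal flow); first-order upwind advection (monotone but
diffusive — jet peaks are slightly smeared at the default resolution);
Laplacian viscous form; single-case presets.  Facet-maximum WSS near domain
ends carries one-sided-stencil noise; interior extrema are reliable.
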