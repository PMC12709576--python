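# Methods

## The physical model

A copepod fecal pellet is idealised as a rigid 2D ellipse (short semi-axis
`A` = width/2, long semi-axis `B` = length/2) sedimenting in a quiescent
rectangular water column of 2000 × 6000 μm. The fluid obeys the
incompressible laminar Navier–Stokes equations with gravity:

    ρ (∂u/∂t + (u·∇)u) = −∇p + ∇·[ μ(∇u + ∇uᵀ) − (2/3) μ (∇·u) I ] + ρ g
    ∇·u = 0

The `(2/3) μ (∇·u) I` term vanishes identically for incompressible flow but
is retained in the operators at no cost. At the scales involved
(terminal speeds of tens of m/day, pellet widths of tens of μm) the
Reynolds number is of order 10⁻²–10⁻³, so the flow is Stokes-dominated;
the convective term is carried (linearised at the previous step's
velocity) but is numerically negligible, which one of the unit tests
demonstrates directly (< 2 % effect on the interface traction).

Boundary conditions: no-slip on the left/right walls; open top and bottom
with the natural (traction) condition `σ·n = −p_hydro n`, where
`p_hydro = ρ_f g (H − y)` compensates the hydrostatic head so the column
behaves as a window into a vertically extended ocean; full rigid-body
no-slip on the pellet interface, `u = U + ω × r`. A configuration switch
(`literal_interface`) restricts the interface coupling to the vertical
solid velocity only, for comparison with the vertical-only condition some
descriptions of this class of model print.

The pellet carries three density models: none (1140 kg/m³, the typical
fecal-pellet density), uniform polystyrene admixture (area-weighted
arithmetic mean of 1140 and 1050 kg/m³ — the incorporation ratio is read
as an area fraction), and a nonuniform band at one end of the long axis.
The band is bounded by a chord perpendicular to the long axis; by default
the chord is placed so the end cap covers exactly 27.6 % of the ellipse
area (chord at 0.360 B from the centre, solved from the closed-form cap
area). A literal quarter-of-the-long-axis band is available via
`band_axis_fraction = 0.25`; it covers 19.6 % of the area — the stated
27.6 % figure drives the mass and torque physics, so area is what the
default matches. Mass, centre of mass and rotational inertia of the
banded pellet come from exact cap integrals (the inertia cap term by 1D
quadrature).

## Discretisation

Taylor–Hood P2/P1 triangles, assembled vectorised in numpy with a 7-point
(degree-5) Gauss rule. The mesh is an unstructured Delaunay triangulation
of a graded point cloud: an area-matched polygon on the ellipse (vertices
scaled slightly outward so the polygon area equals πAB exactly, keeping
discrete buoyancy and body weight consistent), geometric rings coarsening
away from the interface, a jittered background grid, and the rectangle
boundary. Triangles inside the pellet are removed and the interface
polyline is verified to be resolved edge-by-edge. Default resolution
gives ~1950 cells for the base pellet in the full column — matching the
reference discretisation scale of this problem class — and `mesh_scale`
refines or coarsens everything together.

Interface forces are evaluated with variationally consistent reactions
(the assembled momentum residual tested against the interface shape
functions), which is superconvergent compared to direct stress
evaluation; a per-edge pointwise traction evaluator is provided for
diagnostics. Hydrostatic equilibrium (linear pressure, zero velocity) is
an exact discrete solution of this formulation, so the Archimedes check —
traction on a stationary ellipse equals ρ_f πAB g — holds to machine
precision, as does the discrete continuity constraint (the pressure-space
projection of ∇·u); the unprojected L2 divergence is ~3 % of the
velocity-gradient norm at default resolution, consistent with the
element order.

## Time stepping and coupling

Backward Euler in time with a 1 ms step through the release transient
(the step-size cap used by the study this model reimplements). The fluid
problem is linear per step once convection is frozen, so the hydrodynamic
load on the pellet is an affine function `F(U) = F₀ + A U` of the
end-of-step rigid velocity `U = (vx, vy, ω)`. One sparse LU factorisation
per geometry state serves four right-hand sides — the zero-interface-
motion solution plus three unit rigid modes — giving `F₀` and the 3×3
matrix `A`; the rigid update `M(U′−U)/dt = F₀ + A U′ + W` is then solved
exactly. This implicit interface coupling is unconditionally stable at
the solid/fluid density ratio ≈ 1.1, where a loosely staggered
(partitioned) iteration hits the classic added-mass instability; it costs
the same as a partitioned scheme with sub-iterations but needs none.

Two geometry-update policies exist. `smooth` moves the mesh every step:
interior nodes follow precomputed harmonic (Laplace) unit-displacement
modes, interface nodes are snapped to the exact rigid map, and quality
degradation triggers a full remesh with linear interpolation of the
fields. `remesh_only` (default) exploits the Stokes regime: the discrete
geometry is frozen between remesh events and intermediate steps reuse the
factorisation, costing one triangular solve each; the pose may drift half
a semi-width (configurable) before a remesh at the current pose. The two
policies agree on the interface force to well under the discretisation
error (unit-tested at 2 %), because a micrometre-scale geometry lag is
invisible at wall distances of ~1000 μm.

Long runs enlarge the step after the resolved release transient
(doubling at remesh events up to 8 ms by default in the desk protocol):
the implicit coupling is unconditionally stable and the remaining
dynamics — the slow viscous development of the channel-scale return flow,
time constant ρW²/μ ≈ 4 s — is fully resolved at that step.

## The steady oracle and what the solver reproduces

The terminal-velocity oracle solves a single steady Stokes problem
(dynamic pressure, homogeneous open boundaries) with the pellet towed at
a prescribed velocity, extracts the linear drag coefficient `k` from the
consistent reaction, and solves `k v = Δρ πAB g` by a secant iteration
(one update suffices — Stokes drag is linear). The oracle places the
pellet mid-column by default: steady drag near the open top boundary is
lower (the boundary truncates the channel return flow), and mid-column is
representative of the terminal phase. Transient and oracle agree to
better than 1 % at matched depth — a genuine cross-check, since the
coupling loop, time stepping and boundary handling are exercised only in
the transient path.

Two properties of this finite open column are worth knowing when
comparing against infinite-channel references. First, drag lies ~20 %
below the Faxén wall-corrected value for an infinite channel and
converges to it as the column is lengthened (verified directly); the
open ends relieve the piston-like back-pressure a sealed channel would
build. Second, the zero-tangential-traction open condition does not
reproduce pressure-driven Poiseuille flow exactly (the classic
symmetric-stress do-nothing artifact); the channel-flow unit test
therefore prescribes the parabolic profile on the ends and verifies the
interior solve returns it to < 1 %.

The base case (20 × 100 μm at 1140 kg/m³) settles at ≈ 34 m/day in this
model, ~13 % below the 39.1 m/day the original study reports — within the
tolerance band used here, and internally consistent to < 1 % with the
independent steady oracle. Banded (nonuniform) pellets reorient: a light
band at one end shifts the centre of mass toward the other end and the
buoyancy–weight couple rotates the long axis toward vertical, lowering
drag — reproducing the "falls more vertically" behaviour. The three
reported nonuniform speed changes (−31.8 / −18.6 / +12.0 % at band
densities 950/1050/1200 kg/m³) are mutually inconsistent with any single
rotation behaviour under a bulk-density Stokes model: with full rotation
this model gives ≈ −35 %, ≈ −7 % and ≈ +30 %; with no rotation,
−47.6 / −22.5 / +15.1 % follow from Δρ proportionality alone. The 950
case matches the reported value; the 1050 and 1200 cases cannot match
simultaneously under either behaviour, and the model reports its faithful
values rather than forcing agreement.

## Desk-scale protocol

Headline comparisons run at `mesh_scale 0.8` (~1250 cells for the base
pellet), 1 ms steps through release and 8 ms afterwards, a 4 s window for
uniform-density pellets (the post-burn-in mean is then within ~1 % of the
steady speed), and full-column descents (cap 20 s) for the rotating
banded pellets, whose righting plays out over seconds. Burn-in uses the
95 %-of-terminal onset rule: samples are dropped until the vertical speed
first reaches 95 % of the mean over the final half of the record. The
sensitivity analysis perturbs one factor at a time by ±2.5 % (pellet
density, pellet size — length and width jointly, water density, water
viscosity) and ranks factors by mean |% speed change|; in oracle mode the
closed forms are exact (density +2.5 % → +25.9 % via Δρ 110 → 138.5;
viscosity +2.5 % → −2.44 % via 1/1.025).

## Morphometry and statistics

Pellet volume uses the equivalent-ellipsoid formula
`V = (4/3)π (L/2)(W/2)²` (with π, which the magnitudes of the reported
mean volumes require). Production rate is the summed volume per
individual per day in 10⁶ μm³ units; empty replicates return a flagged
zero, and fragments count as pellets. Group comparisons gate on
Shapiro–Wilk normality (recorded, not used to switch tests) and apply the
unpaired Wilcoxon rank-sum test by default — the design has no pairing,
so the signed-rank test is available only for explicitly paired inputs.
All-tied degenerate samples return p = 1 with a tie flag. No
formalin-shrinkage correction is applied.

## Synthetic data generator

The generator emulates the 27-treatment exposure design (control + 2 bead
classes × 4 concentrations, × 3 diatom levels, 6 replicates × 3
copepods × 24 h). Pellet lengths are truncated normal with parameters
*solved* so the truncated mean and sd equal the configured targets (45.6
± 23.6, 100.6 ± 34.2, 142.5 ± 34.4 μm by diatom level); widths follow
lengths proportionally (ratio 0.162, CV 0.229, interpolated from the
control marginals since per-cell widths are not printed). Plastic
exposure scales pellet volume through a per-(class, concentration)
multiplier table and a 10 % debris sub-population of short fragments
(length × 0.3), which also produces the negative skew of the exposed
volume distributions. Pellet counts are Poisson with expectations set by
a production-rate table anchored to the printed rates (0.13 and 4.58 ×10⁶
μm³/ind/day for the no-food and high-food controls; 0.11 and 1.00 for the
no-food 5000 μg/L NP and MP cells) and interpolated elsewhere — the
interpolated cells are a modelling choice, not data.

The six pooled volume-reduction targets (23.6 % NP and 65 % MP by class;
27 / 35.8 / 42.3 / 49.5 % by concentration, all against the shared
control) are mutually inconsistent under a balanced design: the
equal-weight means of the implied multipliers differ by 5.65 points, and
production-count weighting cannot reconcile them without count ratios
that contradict the printed production rates. The calibration therefore
uses the max-norm-optimal even-split allocation — every pooled marginal
reduction sits exactly 2.825 points from its target, the closest any
single multiplier table can come to all six at once — and the recovery
tests verify the pipeline reproduces each within 3 points.

Two generation modes exist. The default draws everything independently
(replicates and treatments). A common-random-base calibration mode shares
the base dimension draws across the nine class × concentration cells
within each (diatom level, replicate) and closes the loop exactly —
debris is picked by volume-ordered systematic sampling and the dimension
scale is set so each replicate's realised volume total equals the
configured multiplier times the shared base total — so treatment/control
volume ratios recover the configured table with no Monte-Carlo noise.
Replicates remain independent in both modes. Fluorescence intensities
follow a power law in concentration attenuated by diatom level, with a
zero-centred noise floor for controls.

What the generator does not emulate: measurement error in ImageJ length
tracing, within-replicate correlation from shared vials, the curved
(folded-line) pellet geometry, or any mechanistic link between production
rate and pellet size. Passing round-trip tests therefore demonstrates
that the analysis pipeline recovers known calibration, not that the
calibration describes real pellets.

## Known limitations

2D: drag per unit depth in a channel is not the 3D drag on a spheroid,
so absolute sinking rates carry the 2D confinement geometry (as in the
study being reimplemented); only relative changes should be compared
across geometry families. The open-boundary condition truncates the
return flow (see above), making drag depth-dependent within ~1 channel
width of the ends. The rigid-body model excludes deformation, porosity
and degradation. The time-to-depth arithmetic is the plain `depth/speed`
formula; it does not reproduce the 8.34- and 59.2-day delays printed in
the source study, and no attempt is made to force it to.
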