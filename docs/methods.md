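# Methods

`atriumfsi` is a desk-scale re-implementation of a coupled left-atrium /
mitral-valve fluid–structure interaction analysis: an immersed-boundary /
finite-element (IB/FE) solver, a fibre-reinforced hyperelastic atrial
material with prescribed active tension, a rule-based atrial fibre
architecture, a calibrated synthetic idealized-geometry generator
standing in for patient CT anatomy, six physiological/pathological
scenario drivers, and the haemodynamic analysis layer (energy budget,
volume accounting, strains, pathlines, appendage residence time).

## Governing model

The fluid occupies a fixed Cartesian box Ω with velocity **u**(x,t),
pressure p(x,t) and body force **f**(x,t) obeying incompressible
Navier–Stokes,

    ρ(∂u/∂t + u·∇u) = −∇p + μ∇²u + f,    ∇·u = 0,

with blood treated as Newtonian (ρ = 1 g·cm⁻³, μ = 0.04 g·cm⁻¹·s⁻¹).
The structure is a Lagrangian elastic body with reference coordinates
**X** and current position **χ**(X,t).  Its nodal force density **F** is
the weak-form projection of the first Piola–Kirchhoff stress Pᵉ,

    ∫ F·V dX = −∫ Pᵉ : ∇ₓV dX    for all test functions V,

and the two frames are coupled through a regularized delta kernel δ_h:
forces are spread, f(x) = Σ F_a δ_h(x−χ_a) m_a (nodal lumping of the
reference measure m_a), and structure points move with the interpolated
fluid velocity, ∂χ/∂t = Σ u δ_h — the no-slip condition at the
interface.  Spreading and interpolation share one stencil plan, so the
discrete power identity Σ f·u h^d = Σ F·U holds to round-off and total
force is conserved exactly (partition of unity).

### Constitutive model

Passive atrial wall (and, with separate parameters, the valve leaflets):

    W = a/(2b)·{exp[b(I₁−3)]−1} + a₁/(2b₁)·{exp[b₁(I₄−1)²]−1}
        + β/4·log²(I₃)

with I₁ = tr C, I₃ = det C, I₄ = e·C e, C = FᵀF and unit fibre
direction e.  Fibres bear extension only: the I₄ terms are switched off
when I₄ < 1.  The stress carries an additional non-variational term so
that P(F = I) = 0 exactly:

    P = a e^{b(I₁−3)} F − a e^{b(I₁−3)} F⁻ᵀ
        + 2a₁(I₄−1) e^{b₁(I₄−1)²} F e⊗e + β log(I₃) F⁻ᵀ.

Defaults: a = 8.0 kPa, b = 5.57, a₁ = 6.0 kPa, b₁ = 4.06, β = 500 kPa.
Active contraction adds P_act = J·T·F(e⊗e) with
T = T_active(t)[1 + γ(λ−1)], λ = √I₄, γ = 4.9.  T_active(t) is a
squared-sine bump, peak 56.2 kPa, occupying late diastole
(onset 0.64 s, duration 0.16 s in a 0.8 s cycle whose origin is
ventricular-systole onset); only the peak value is a published number,
so the bump shape and window are package choices placed to produce the
atrial kick at end diastole.  In 2D the kinematics are plane strain
(unit out-of-plane stretch), so F = I still gives I₁ = 3, I₃ = I₄ = 1
and a stress-free reference.

The log-I₃ penalty enforces only near-incompressibility of the solid;
per-element J drift is observable in the deformation state rather than
asserted against a fixed bound.

### Discretization

* Eulerian: uniform staggered (MAC) grid; second-order centred
  divergence/gradient/Laplacian; advective terms by a piecewise-parabolic
  (PPM-style) upwind reconstruction — unlimited interface interpolation
  for convergence studies, Colella–Woodward monotonization inside coupled
  runs.  Pressure projection in non-incremental form with a cached sparse
  LU factorisation, so prescribed open-patch pressures are realised
  directly and the post-projection divergence is at round-off (far below
  the 10⁻⁸·max|u|/h contract).  A two-stage (midpoint) fluid step is
  available and gives second-order Taylor–Green convergence.
* Boundary conditions per box face: no-slip wall, periodic, or an open
  patch with prescribed normal traction and zero tangential velocity
  (the tangential condition on the pressure-driven tube mounts is a
  package choice; only the normal condition is dictated by the model).
* Lagrangian: linear tetrahedra (one-point quadrature), bilinear quads
  and trilinear hexahedra (2×2(×2) Gauss).  Thin walls carry at least
  two element layers.
* Kernels: the classical 4-point IB kernel by default; 3-point and
  quintic-B-spline 6-point variants selectable.  All satisfy discrete
  partition of unity and the first-moment condition (exact linears).
* Coupling loop: explicit two-stage midpoint (forces from the half-step
  configuration drive the full step) as the integrator default; the
  scenario driver uses the explicit Euler variant of the same loop for
  its production runs, halving the per-step cost at the testbed's small
  time steps.  An instability detector aborts when the fluid kinetic
  energy grows more than tenfold in a single step.
* Constraints: rigid housings/mounts are realised as stiff penalty
  tethers to (possibly moving) target positions; chordae are
  tension-only nonlinear springs (linear + quadratic stiffening) whose
  rest lengths are set by the normal anatomy so they are slack through
  the opening/closing swing and arrest eversion past the annulus plane.

## Synthetic geometry

The idealized LA replaces the patient CT mesh.  A superellipsoidal
chamber (icosphere parametrization) carries six circular orifices (four
pulmonary veins, appendage, mitral annulus) cut as geodesic caps with
their boundary loops projected onto exact rings; cylindrical PV stubs, a
tapered appendage pouch (windsock profile, closed tip), and a two-layer
tetrahedral wall extruded along smoothed vertex normals.  Deterministic
fixed-point calibration drives the measured quantities onto the target
anatomy: chamber cavity volume 107.3 mL (global scale), orifice areas
2.5/2.0/1.8/2.5 cm² (PVs), 4.6 cm² (appendage) via the cap angles, pouch
volume 12.6 mL via its length, and area-weighted mean wall thickness
1.5 mm via the thickness-field scale.  Cavity volumes are
divergence-theorem surface integrals over the endocardial patch closed
by planar caps across the orifice rings.  The non-uniform thickness
field is a smooth tanh blend, thicker posterior and superior walls
(amplitudes 0.6/0.4 of the base), floored at 0.55× the mean; uniform
variants (1.5 mm, 2.2 mm) are constant.  At concave junction creases the
outward extrusion is locally relaxed (deterministically, by shrinking
the offending vertices' offset) until every tetrahedron is positive;
elsewhere the wall thickness is exact.

Fibre rules partition the wall into six sections — left/right PV
collars (two cap angles wide), an MV-plane band (two annulus cap angles),
the appendage, and an anterior (Bachmann) / posterior-superior
(septopulmonary) split of the remainder — and assign wall-tangent unit
vectors: circumferential about each vein or the pouch axis, parallel to
the annulus plane, circumferential about the superior-inferior axis on
the anterior wall, and an oblique (default 45°) roof-to-septum
trajectory.  Labels and vectors are assigned per surface facet, so
transmural element stacks are identical (no transmural rotation).
Section boundary widths and the obliquity are configuration parameters;
only the qualitative layout is published.  A nearest-neighbour transfer
maps fibres between overlapping meshes.

The simplified parametric valve has two leaflets (anterior longer than
posterior) hanging from a fixed annulus ring toward ten chordae origins
in two papillary clusters; the regurgitation variant displaces the
origins toward the atrium by a configured offset (default 2.8 cm), which
lifts the rest free edge past the annulus plane.  The published leaflet
constitutive law is not restated in the source material, so leaflets
reuse the exponential family above with independent parameters.

## 2D testbed and scenarios

Coupled production runs use a fast 2D chamber-with-flaps testbed: an
elliptical chamber wall (two quad layers, circumferential fibres,
ds ≤ 0.45h) with two pulmonary-vein gaps feeding rigid channels to the
top box face, a mitral gap feeding a rigid outflow channel to the
bottom face, two flap leaflets hinged at the gap edges in the open
(diastolic) position, chordae springs, and baffles sealing the
ventricular pressure plenum.  The ambient region vents through the top
face, so the pericardial-like reference tracks pulmonary-vein pressure.
Pressure drive: periodic cubic splines through phase-anchored control
points — systole [0, 0.30), early/mid/late diastole thereafter in an
0.8 s cycle — with a ventricular trace spanning ~2.5–30 mmHg and a
pulmonary-vein trace ~9–11.5 mmHg.  These magnitudes are testbed
choices (the published ventricular systolic pressures apply to the 3D
anatomy; at the testbed's wall-thickness-to-radius ratio a reduced
systolic peak produces physiological transmural loads).  Runs start
with a 0.1 s linear ramp of boundary pressures and tether stiffness,
then at least two cycles; metrics are reported from the second.

Six cases differ from the normal case in exactly one stated parameter:
zero active tension (AF), chordae origins displaced atrium-ward (MVR),
rule-based fibre flag, and uniform wall thickness at 1.0× or ~1.47× the
non-uniform mean.  Case definitions are enforced by config validation
and verified by config diffing.

Default numerics for the testbed: 48×60 cells on a 6.4×8.0 cm box
(h ≈ 0.133 cm), fixed step Δt ≤ 1.1·10⁻⁴ s additionally limited by an
advective CFL of 0.4, 5 ms metric sampling.  These sizes keep a full
two-cycle case around a minute of wall-clock time while retaining every
qualitative feature of interest: reservoir filling during systole,
conduit outflow in diastole, the active late-diastolic emptying dip and
its disappearance without activation, valve closure versus regurgitant
flooding, and the thickness-dependence of wall strain.

## Metrics

Kinetic energy KE = Σ ½ρ|u|²h^d and dissipation
D = Σ μ(∇u+∇uᵀ):∇u h^d over the chamber-interior cell mask (ray-parity
test of cell centres against the deformed midline polygon in 2D).
Volume accounting per cycle: emptying = max−min of the cavity trace;
regurgitant = ∫ reverse transmitral flux during systole; stroke =
∫ forward transmitral flux; conduit = stroke − emptying + regurgitant
(signed identity, exact by construction), cross-checked by an
independent diastolic-throughflow estimate whose discrepancy is
reported.  Strains: ε¹ is the largest eigenvalue of the Green–Lagrange
tensor E = ½(C−I) (volume-weighted averages); fibre strain is √I₄ − 1.
Orifice traces are area-weighted normal velocities and fluxes on fixed
sampling patches (into-the-atrium positive for PVs, out for the MV).
Pathlines are RK4-integrated through time-interpolated velocity
samplers; the residence time is the mean in-region duration of particles
that have exited by the final time (an explicit undefined flag when none
exit); the stagnation fraction is the percentage of region cells with
|u| below 10 cm/s.

## What the synthetic data does and does not show

The generator reproduces the published scalar anatomy (volumes, orifice
areas, mean thickness) and the qualitative fibre layout, not the
patient's shape; the 2D testbed reproduces the phase structure and
direction-of-effect physiology of the six cases, not their absolute
haemodynamics.  Accordingly the tests check exactly printed quantities
(the volume-accounting identity, geometry calibration, constitutive
point values) at tight tolerances, solver behaviour against closed-form
oracles (Poiseuille, Taylor–Green, transfer identities, ring
conservation), and the pathological cases only as signed contrasts
(AF: no late-diastolic dip; MVR: larger regurgitant volume and higher
systolic chamber pressure; uniform thickness: lower average fibre
strain).  Published absolute pressures, velocities, energies, residence
times and strain maps require the patient geometry and cluster-scale 3D
resolution and are treated as qualitative references only.

## Numerical choices and limitations

* The energy-bookkeeping identity (dKE/dt + D = spread-force power)
  is verified on a resolved smooth forced flow; across an immersed
  interface the centred-difference dissipation cannot see the O(1)
  velocity-gradient kink at grid scale, so interface-dominated problems
  do not close the budget at desk resolution.
* Valve closure is flow-mediated; a hydraulic gap of order one grid
  cell remains at coaptation (tied to the kernel regularization width),
  so a small normal-case regurgitant volume is expected and the
  pathological comparison is relative.
* Tether stiffness (2.5·10⁵ dyn/cm per node) keeps constraint violation
  well below 0.1 mm under testbed loads while respecting the explicit
  stability limit.
* The appendage is present in the 3D geometry (volumes, fibre rules,
  residence-time machinery) but the 2D testbed has no pouch; residence
  time and stagnation operators are exercised on analytic flows.
* No turbulence model, non-Newtonian rheology, adaptive refinement,
  electrophysiology, leaflet prestrain, or annulus motion.
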