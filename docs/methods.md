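# Methods

`morphoflex` has two halves that meet on synthetic data: a 2D
visco-elastic finite-element model of a chain of pressurized brain
vesicles, and the image-analysis chain used to quantify time-lapse
videos of the embryonic head (PIV, rigid hinge-rotation fitting,
strain rates, stack registration, cardiography, vessel casts).  This
note records the model, its assumptions, the numerical choices, and
what the synthetic benchmarks do and do not demonstrate.

## The vesicle-chain model

**Geometry.** The early head is a row of `n` congruent circular
cavities (radius `R = 1`, the length unit) inside a thin tissue shell
(thickness 0.1 by default), separated by solid columns (width 0.2)
that stand in for the contractile cell belts of the inter-vesicle
valleys, and clamped along a flat vertical face at the posterior
(neck) end.  `x` increases posteriorly, `y` dorsally; ventral
(forward, physiological) flexure moves the free anterior end toward
negative `y`.  The exterior boundary is the outward offset of the
cavities bridged flat over each column, which produces the valley
profile.  The domain is meshed with linear triangles: boundary
vertices are placed explicitly on the analytic curves (so the mesh is
exactly mirror-symmetric about the chain axis at start), interior
vertices on a hexagonal lattice at the target edge length (0.05,
giving at least two elements across the shell), and connectivity
comes from a Delaunay triangulation filtered to the domain.

**Constitutive law.** The tissue is a compressible viscous material:
`sigma = 2 mu dev(eps_dot) + eta tr(eps_dot) I`, with shear viscosity
`mu` and dilational viscosity `eta` (both 1 by default; living tissue,
unlike a Newtonian liquid, changes area under normal stress, which is
what `eta` expresses).  The strain rate is the symmetrized velocity
gradient — the symmetric form is required for frame indifference.
Inertia is neglected: each step solves static equilibrium for the
velocity (P1 elements, sparse direct solve) with zero velocity on the
clamp; the per-step problem is linear, the trajectory is not, because
the mesh is advected with the velocity (Lagrangian update) and the
loads follow the moving boundary.

**Loads.** Each cavity carries a uniform internal pressure `P = 1`.
Shell tension `T` enters through the Laplace term `T*kappa`, with
`kappa` the boundary curvature computed per vertex as the reciprocal
circumradius of the vertex and its two loop neighbours (3-point
moving-average smoothed; the pointwise value is noisy at mesh scale).
On a circular cavity `kappa = 1/R`, so `T = P R` exactly cancels the
load — the solver reproduces this balance to machine precision, which
is the strongest single test of the traction assembly.  A tangential
surface shear, uniform along the exterior and oriented from the apex
toward the neck, represents the stress gradient in the sagittal belt.

Two loading modes bundle the signs:

* **ELECTRIC** (stimulation): effective cavity pressure `P - T*kappa`
  and the shear on the *dorsal* exterior.  Outcome: vesicles shrink,
  head uplifts (retrograde/dorsal flexure).  The stepwise schedule
  `T = 0, 0.02, 0.04, 0.06, 0.08` reproduces the progressive uplift.
* **BLOOD** (hemodynamic, the default): effective pressure
  `P + T*kappa` (a pressurized capillary plexus relaxes the cover over
  the vesicles) and the shear on the *ventral* exterior (the large
  vessels run under the neural tube).  Outcome: vesicles dilate, head
  rocks forward (ventral).

In a mirror-symmetric chain, pressure alone cannot select a bending
direction (the solver's velocity field is exactly mirror-symmetric);
the surface shear is the symmetry breaker, and its side decides the
sense of flexure.  The default (tension-free, BLOOD-mode) run is the
physiological one: dilation with forward flexure.  A single vesicle
dilates essentially without bending; a chain bends because each column
acts as a hinge and the increments add, with dilation decreasing
posteriorly toward the clamp.

**Default load/stepping parameters.** The shear magnitude and the
timestep are the two genuinely free numbers, and both were set by the
model's own mechanics rather than by any reported value. The chain is
orders of magnitude more compliant in bending than in dilation, so a
shear of 5e-4 (dimensionless, against `P = 1`) makes the two rates
comparable over a run; much larger values rotate the chain long before
it dilates. The explicit Lagrangian update is conditionally stable:
above a critical timestep a spurious sign-alternating "flapping" mode
of the floppy chain grows geometrically. `dt = 2e-4` sits a factor of
about 2.5 below that threshold for the default loads and `n <= 10`,
and runs converge (halving `dt` changes trajectories negligibly).
Default runs take 400 recorded steps after a 150-step burn-in.

**Burn-in.** The idealized initial condition — perfectly circular
thin shells meeting sharp valley notches — creeps abnormally fast
under the shear for a short initial period, until the valleys inflate
and the hinges acquire their working stiffness.  This fast transient
is an artifact of the idealized start, not part of the phenomenology
of interest, so the first 150 steps settle the geometry and the
recorded trajectory (times, flexure reference) begins after them.
With the transient excluded, the ten-vesicle run shows the expected
shape: the flexure angle grows slowly and nearly linearly at small
bending, then accelerates (the torque of the posteriorly-directed
shear grows as the tip drops, and the dilating chain lengthens its own
lever arm), and the angle–mean-diameter relation is close to a
straight line (r > 0.95) — the allometry with time eliminated.

**Remeshing.** If the minimum triangle angle drops below 10 degrees
or any area below 1e-4, the interior is re-seeded and re-triangulated;
boundary vertices are never moved.  Element inversion that remeshing
cannot repair raises a step-size error instead of continuing silently.

**Morphometrics.** The flexure angle is the signed rotation of the
chord joining the most-posterior to the most-anterior cavity centroid
(clamp centroid to cavity centroid for a single vesicle); centroids
are robust to boundary noise where apex tangents are not.  Positive is
dorsal.  Diameters are equivalent-circle diameters from the polygon
area of each cavity loop.  The two-regime breakpoint is a continuous
single-knot piecewise-linear least-squares fit with the knot chosen
exhaustively on the time grid.

## Video analysis

All image operations use array coordinates internally (origin
top-left, y down) and report angles counterclockwise-positive in the
visual y-up sense; the conversion is a single sign.

**PIV.** A grid of reference points (16 px spacing) with 32-px
interrogation windows, searched over ±10 px in the second frame by
normalized cross-correlation; the correlation surface is computed in
a batched form (zero-padded FFT numerator, integral-image
normalization), the peak refined to subpixel by parabolic
interpolation.  A perfect integer-shift peak (NCC = 1) is returned
unrefined, so integer displacements are recovered exactly.  Points
with peak correlation below 0.5 are masked.

**Rigid fitting and strain.** The hinge rotation is the exact 2D
orthogonal-Procrustes fit of grid points to displaced points; the
rotation center is the fixed point of the fitted transform.  Strain
rates come from an affine least-squares fit `u = A(x - x̄) + b` over
valid vectors: linear (radial) rate `tr(A)/2/dt`, areal rate
`tr(A)/dt`, rotation from the antisymmetric part.  Contraction is
negative.

**Registration.** Frames are aligned to the first by cross-correlation
over translation, with rotation found by golden-section search (±15
degrees, 0.01-degree refinement).  Frames are demeaned and
Hann-windowed before correlation — embryo-like textures are smooth and
edge effects otherwise bias the peak toward zero shift.  The final
resample is cubic.

**Cardiography.** The ROI trace is detrended by a 2 s moving median;
beats are peaks with prominence at least 25% of the detrended range
(thresholds chosen for the 60 fps, 2–4 Hz embryonic range); the rate
uses the span between first and last peak; thrust is reported only as
a comparative proxy (mean maximal rising slope per beat).

**Vessel casts.** Blood-flow stacks are registered, then min-projected
over a 300-frame window (the middle of the plausible 200–600 range);
dark advected erythrocytes accumulate into the vessel path.

## Synthetic benchmarks — what they show and what they do not

The generators render seeded band-limited noise textures (8 px
correlation length, 2% additive noise) under exactly known motion:
rigid hinge rotation at 1.5 deg/min sampled at one frame per 10 s,
isotropic contraction at 0.02/min, composed episodes, a 2 Hz heart at
60 frames/s, and particle advection along a vessel polyline.
Generators use bilinear resampling of a padded base texture and share
no code with the analysis modules, so recovery is a genuine round
trip; every stack is a pure function of its arguments including the
seed.

Passing these benchmarks shows the estimators are unbiased and
precise under the stated motion models, noise level and sampling.  It
does not show robustness to the complications of real embryo videos:
non-rigid residual motion, illumination drift, occlusion by the yolk
sac, out-of-plane motion, or texture evolution from development
itself.  The benchmark tolerances (rotation 5%, strain 10%, heart
rate 2%, path coverage 90%) are recovery specifications for the
synthetic conditions, not accuracy claims for live data.

## Known limitations

* The tissue model has no elastic memory, no contact between
  vesicles, no growth; a dilation run eventually self-intersects and
  must stop.
* The bending direction of the tension-free chain is set by the side
  the surface shear acts on, not emergent from dorsoventral anatomy
  (the model is mirror-symmetric by construction).
* The explicit update limits the usable shear magnitude; strongly
  shear-dominated regimes would need an implicit moving-boundary
  scheme.
* Simulated figure shapes are qualitative: the model's free
  parameters (viscosities, shear, step counts) are not calibrated to
  any measured embryo, only their ratios are chosen to place bending
  and dilation on comparable timescales.
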