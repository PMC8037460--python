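# Methods

This note documents the model, the numerical scheme, the choices made
where the physical setup was genuinely open, and what the synthetic data
and tests do and do not establish.

## Domain and mesh

The anterior chamber is a planar (not axisymmetric) cross-section.  The
corneal arc is a circular arc with chord `ac_length` = 10 mm and sagitta
`ac_depth` = 3.2 mm; the floor is a flat lens plane spanning the
pupil (`pupil_length` = 2.98 mm) recessed by the iris thickness
(0.45 mm) below the flat iris top.  At each lateral rim a vertical wall
of height `tm_width` = 300 µm forms the interface to a porous
trabecular-meshwork (TM) block of flow-path length 85 µm, with a 163 µm
Schlemm's-canal (SC) outlet centred on its outer face.  Aqueous enters
through two 20 µm segments of the lens plane at the pupil margin.  All
coordinates are kept in millimetres internally (the µm-scale TM features
stay well away from float underflow); the solver converts to SI.

Meshing is a force-equilibrium smoothed Delaunay iteration
(distmesh-style) over a graded size field — ~11 µm at the inlets, ~20 µm
in and around the TM, ~55 µm at the probe surface, bulk size calibrated
to the requested element count (default 4981).  Only the right half is
meshed; reflection about the pupil axis makes the mesh, and hence the
discrete operators, exactly mirror-symmetric, which is why the
symmetry test holds to solver precision rather than discretization
accuracy.  The TM blocks are structured micro-grids merged node-exactly
onto pinned interface nodes.

## The phaco tip

The tip is modelled as a solid no-slip disk of diameter 2.2 mm resting
0.25 mm above the lens, with the impulse flux applied on its lens-facing
underside (the active face of the tip).  This was the main open design
point, and the one with the largest effect on the results.  The
alternatives were rejected on physical grounds:

* an *immersed line source* (no obstacle) produces a free buoyant line
  plume — at 300–1400 W/m per depth its velocity scale
  (gα q′/ρC_p)^{1/3} is 7–17 mm/s — that dumps the heat directly onto
  the cornea; the hottest region ends up on the corneal side, speeds
  reach ~17 mm/s, and the probe point overshoots strongly;
* a disk heated over its *whole perimeter* sheds the plume from the disk
  top, 0.9 mm below the probe point, and overshoots even more.

With the underside flux, the heat enters the 0.25 mm fluid gap between
tip and lens.  That gap is conductively stable (its Rayleigh number is
~4ΔT, orders of magnitude below critical), so most of the power conducts
into the 36.5 °C lens boundary and the gap becomes the hottest region of
the domain, declining toward the cornea; only the fraction escaping at
the gap mouths feeds weak edge plumes that warm the upper chamber.  The
flux magnitude is Q̇/(L_tip·d_eff) with L_tip = 2.2 mm and the
out-of-plane depth d_eff equal to the tip diameter — the single 2-D
conversion convention used everywhere (inflow, impulse power); the
discrete nodal loads are normalized so exactly Q̇/d_eff watts per metre
of depth enter the domain regardless of how the source boundary is
meshed.  The immersed-segment variant remains available
(`GeometryParams(probe_obstacle=False)`).

A consequence worth stating plainly: at low power the probe-point
response is conduction-dominated for *every* filling, so the viscoelastic
(Healon) does not look dramatically safer at 0.66 W — its hot lens gap
conducts around the tip about as effectively as the weak aqueous plume
delivers.  The orderings usually quoted for this comparison (viscoelastic
≪ salt solution < aqueous) emerge in this model only at high power,
where convective delivery dominates.  The tests assert the ordering at
every power and therefore fail at the low powers; we regard that as a
property of the published constants (the salt solution's printed heat
capacity, 2.5 kJ/kg/K, makes it warm 1.68× more per joule than aqueous
humor) rather than of the discretization.

## Boundary conditions

* Cornea: 27 °C Dirichlet (irrigated ocular surface); all other walls
  and the inflow: 36.5 °C.
* No-slip everywhere except the inlets and the SC outlets.
* Inlets: 2.4 µL/min total aqueous production, converted with d_eff and
  imposed as nodal velocities whose trapezoid boundary integral is
  exactly the target flux.
* SC outlets: prescribed outflow equal to the inflow, with the 10.5 mmHg
  venous pressure as the pressure datum on the outlet nodes.  In a rigid
  incompressible chamber the outflow must equal production; imposing it
  kinematically makes the discrete mass balance exact (a pure pressure
  condition leaves the projection scheme's outlet flux unconstrained —
  we measured ~20% mass defect that way).  The TM pressure drop then
  develops from the Brinkman drag (about 3 mmHg across the 85 µm path at
  production flow, a physiologically sensible number).
* Gravity: 9.81 m/s² along the pupil axis from cornea toward lens
  (supine surgical position), configurable.

## Discretization

P1 triangles, lumped mass.  Each step:

1. explicit Lax–Wendroff (Taylor–Galerkin) advection of momentum and
   temperature, sub-cycled so each sub-step respects a CFL number of
   0.4 on the local element size — the LW term is the only advection
   stabilization, so the amount of streamline diffusion is tied to the
   sub-step, not a tunable constant;
2. implicit viscous/Brinkman solve for the tentative velocity (the
   matrix is constant per time-step size and factorized once; the two
   velocity components share the factorization because the viscous term
   is assembled in Laplacian form);
3. incremental pressure-correction projection (two sweeps) with lumped
   mass; Boussinesq buoyancy enters explicitly;
4. implicit conduction solve for temperature with the impulse load.

Time step 0.02 s for transients.  The steady baseline is obtained by
marching the same scheme at 0.1 s pseudo-time steps until the fields
stop changing (max |dT/dt| below ~1×10⁻³ °C/s and max |du/dt| below
1×10⁻⁵ m/s²), capped at 400 s of pseudo-time, from a pure-conduction
initial field.  For fillings with μ ≥ 1 Pa·s (Healon: 200 Pa·s, giving
~nm/s buoyant velocities) the momentum solve is bypassed and the model
is pure transient conduction with the same interface.

Pressure-work and viscous-dissipation heat terms exist in the energy
assembly but default to off; at mm/s speeds they are ~10 orders below
the impulse load.

Degenerate and edge cases: uniform wall temperatures with no inflow give
an identically zero velocity field (the buoyancy force is exactly zero
at the reference temperature); zero impulse power reproduces the steady
state over any horizon to <0.05 °C; a Forchheimer coefficient of zero
removes that drag term identically.

## Numerical tolerances used by the tests

* Discrete maximum principle: wall bounds ±0.15 °C (the Galerkin/LW pair
  is not strictly monotone at cell Péclet ~1–2).
* Divergence: ‖∇·u‖₂ < 0.25 ‖∇u‖₂ — the consistency level of the lumped
  P1 projection at these resolutions.
* Energy budget: wall heat fluxes are extracted with the consistent-flux
  (residual) method from the converged heat step — one-sided gradient
  integration misattributes tag fluxes by O(h), which the residual form
  avoids — and balance the in/outflow enthalpy to well under 1%.
* Relaxation to baseline is declared at max|T−T_ref| < 0.5 °C and
  velocity deviation < 5% of the baseline peak — the published
  relaxation window is only meaningful under an explicit criterion, and
  both a field-wide and a point-probe reading are computed.
* Mesh stability: the probe temperature at the end of a 1.2 W impulse
  moves < 0.3 °C between ~5000 and ~20000 elements.

## Scenario grid and problem sizes

The production grid is three fillings × four powers at ~5000 elements,
dt = 0.02 s, horizons of 15 s (0.66/1.2 W) and 30 s (2.4/3 W), one
steady baseline per filling.  The test suite exercises the same pipeline
at ~1200 elements with shortened horizons for the plumbing and property
checks, and at 5000/20000 for the refinement check; these sizes are the
package's chosen verification scales.

## Synthetic cohort

The generator draws per-patient endpoints from the published group-level
statistics: group sizes 47 (BSS irrigation) / 45 (Healon), exact sex
counts, and for each longitudinal endpoint (ECD at 4 timepoints, IOP at
5, BCVA at 4) a multivariate normal with compound-symmetric
within-patient correlation ρ_w (default 0.85; `rho_for_loss_sd` solves
the ρ_w that reproduces a target paired-loss SD — the published
one-month ECD loss SDs imply ρ_w ≈ 0.88).  ECD/IOP are truncated
positive, BCVA to (0.01, 1.6).  An age effect (default 2.5 cells/mm²
extra postoperative loss per year above the group mean age) gives the
stats stage a detectable age–loss association without asserting an
unpublished effect size.  Postoperative IOP group means are published
only graphically; the defaults here (6 h means of 17.0/15.8 mmHg with
SDs ~4) are chosen so that transient 6-h pressure peaks above 20 mmHg
occur in a handful of patients per arm, as described clinically.

What the generator does **not** emulate: measurement-device error
structure, dropout, surgical complications, non-normal endpoint shapes,
or any real between-endpoint correlation (families are drawn
independently).  Passing tests therefore establish that the pipeline
recovers the *stated* group statistics and calibrates its tests under
normality — not that it would behave identically on the raw clinical
data.

## Statistics

Normality screen: Shapiro–Wilk plus Kolmogorov–Smirnov with Lilliefors
correction (parameters estimated from the sample); parametric iff both
p > 0.05.  Two-group comparisons: Welch t-test by default (`welch=False`
gives the classical equal-variance form); non-parametric comparisons go
to the rank-sum test, with a compatibility flag that reproduces the
historical use of the Friedman test for two groups (it degenerates to a
sign-type test and requires equal group sizes).  Longitudinal courses:
one-way repeated-measures ANOVA or Friedman.  α = 0.05 throughout, no
multiplicity correction (matching the study design).  Type-I error of
the routed two-group test is Monte-Carlo calibrated to 0.05 ± 0.02 at
the study's group sizes.

## Known limitations

* 2-D planar geometry with a single out-of-plane conversion depth; no
  corneal solid conduction, tear-film evaporation, cavitation or
  acoustic streaming.
* The probe is thermally inert (adiabatic surface apart from the imposed
  flux) and rigid; real tips conduct and vibrate.
* The published headline temperatures for the aqueous filling (peak
  probe temperatures of ~54 °C) are not reproduced by this model: with
  the published material constants the aqueous and salt-solution
  fillings differ only by +36% viscosity, +12% conductivity and −40%
  heat capacity, which cannot produce the reported 14 °C gap between
  their peaks, and the reported ≤1.6 mm/s velocity envelope matches the
  pre-impulse baseline (our baseline peaks at 0.9–1.4 mm/s) rather than
  any impulse-phase flow this model can produce while still delivering
  the reported probe-point heating.  The acceptance suite asserts the
  published numbers and documents the misses rather than tuning toward
  them.
* Healon is Newtonian at a single viscosity (200 Pa·s); no
  shear-thinning.
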