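# Methods

## Model and assumptions

The package solves ciliary pumping of a Casson fluid in an axisymmetric
tube under the envelope model: the discrete cilia tips are replaced by a
continuous impermeable waving surface carrying their velocities. Tips
move on elliptical paths; the envelope travels as a metachronal wave of
speed *c* and wavelength λ. All governing equations are reduced under
the lubrication approximation — wavelength much larger than the tube
radius (β = a/λ small) and negligible inertia (Re ≪ 1) — in the frame
moving with the wave, where the flow is steady and the flux q is
constant along the tube.

Assumptions inherited from that reduction:

* the pressure is uniform across the tube section (∂p/∂r = 0), so the
  shear stress is exactly linear in radius, τ = (r/2) dp/dz;
* the wall boundary conditions enter at leading order in β:
  w(h) = −1 − 2πεαβ cos 2πz and u(h) = w(h)·dh/dz. The exact
  (unapproximated) elliptical tip velocities are available in
  `geometry.cilia_tip_velocity` for kinematic illustration but are not
  used by the flow solution;
* the plug radius H_p is an independent constant input, as in all the
  parameter studies this package reproduces. The pointwise conversions
  H_p = 2τ₀/|dp/dz| and τ₀ = H_p|dp/dz|/2 are provided as utilities;
  solving the self-consistent z-dependent plug problem is out of scope.

The Casson constitutive law is implemented in its standard form
√τ = √τ₀ + √(μγ̇) above yield. Several printed sources typeset this
family of solutions with the radicals lost; every formula here is
re-derived from the constitutive law, and the flux denominator is
checked identically against the classical Casson–Poiseuille bracket
F(m) = 1 − (16/7)m^½ + (4/3)m − m⁴/21, which pins down the only
self-consistent reading (in particular, the −H_p⁴/168 term of
D(h, H_p) sits outside the h³ bracket). The radial wall velocity's
second term is αβ(2πε)² sin 2πz cos 2πz: this is the O(β) expansion of
the exact tip kinematics and the unique reading under which the
stationary wave-frame wall is a streamline (u(h) = w(h) dh/dz), which
the stream-function wall invariant ψ(h, z) = q/2 requires. The stream
function itself is obtained by exact radial integration of the
piecewise profile rather than from any printed closed form.

## Parameters

| symbol | meaning | domain | default |
|---|---|---|---|
| ε | cilia length / mean radius (envelope amplitude) | 0 ≤ ε < 1 | 0.25 |
| α | eccentricity of the elliptical tip path | α ≥ 0 | 0.4 |
| β | wavenumber a/λ | β > 0 | 0.4 |
| H_p | plug-flow radius (yield-stress surrogate) | 0 ≤ H_p < 1 − ε | 0 |
| Q̄ or Δp | driving condition (one of the two) | — | scenario-specific |

All are dimensionless; the defaults are the workhorse values of the
parameter studies (ε = 0.25, α = β = 0.4 with H_p swept over
{0, 0.01, 0.05, 0.09}). The constraint H_p < 1 − ε keeps the plug
inside the narrowest section. Dimensional work uses SI scales
(`DimensionalScales`): mean radius a (m), wave speed c (m/s),
wavelength λ (m), viscosity μ (Pa·s), density ρ (kg/m³), yield stress
τ₀\* (Pa). The ductus-efferentes preset fixes a = 50 μm, c = 200 μm/s
(20 beats/s × 10 μm), β = 0.1, with water-like μ = 10⁻³ Pa·s and
ρ = 10³ kg/m³ giving Re = 10⁻³, deep in the creeping-flow regime that
justifies the lubrication limit.

## Numerical choices

* **I₁, I₂ quadrature.** Composite trapezoid on equispaced periodic
  nodes — spectrally accurate for these smooth periodic integrands —
  doubling from 256 to at most 16384 points until two refinements agree
  to 10⁻¹⁰ (typically converged at 512). Non-convergence raises rather
  than returning a degraded value.
* **Thresholds.** The favorable-gradient threshold is closed-form: the
  cubic −(1+εc)²(1+2πεαβc) in c = cos 2πz is maximized over its
  endpoints and interior stationary point; a dense-scan version serves
  as the oracle in tests. The cilia-length crossing flux is the affine
  intersection of two characteristics, cross-checked by Brent root
  finding (tolerance 10⁻⁹) with bracket expansion.
* **Stream function and radial velocity.** Closed-form antiderivatives
  in r; u = −(1/r)∂ψ/∂z differentiated analytically by chain rule
  through h(z), w(h)(z) and dp/dz(z). Finite differences of ψ appear
  only as test oracles. The axis value u(0) is the symmetry limit 0.
* **Trapping census.** Field on a 401 × 401 grid per wavelength
  (r ∈ [0, 1+ε], masked outside the tube with ψ held at its wall value
  q/2); marching-squares contours at 30 evenly spaced ψ levels strictly
  between the field extrema. A closed contour is a bolus candidate if it
  touches neither the axis nor the wall (two-cell margins). Because the
  bolus straddles the widest section at z = 0 (mod 1), contouring runs
  on a two-period extension and candidates are counted in the interior
  window 0.5 ≤ z̄ < 1.5 — one full wavelength — which sidesteps the
  periodic-boundary wrap test entirely. Nested contours are collapsed to
  their outermost polygon (shapely containment); the bolus count is the
  number of outermost polygons and the area their shoelace sum. Grids
  below 64 points per direction are rejected as contour-ambiguous.
  The reported area depends mildly (few %) on the level set sampling;
  the count is grid-stable, and both monotone trends (area down in H_p,
  up in ε) are robust.
* **Stagnation points.** Axis zeros of w by bracketed Brent iteration;
  interior points by scanning grid cells where both velocity components
  change sign, polishing each with a damped Newton solve, deduplicating
  to 10⁻⁵ and ordering by z then r. A degenerate zero *line* of w (the
  uniform tube at q = 0, where w = 1 − 2r² vanishes on r = 1/√2 at
  every z but u ≡ 0 has no sign change) is deliberately not reported as
  isolated stagnation points.
* **Ties and degenerate inputs.** ε = 0 fields are reported as zero
  boluses by definition; the crossing flux rejects ε pairs with equal
  members or equal I₂.

## Design choices

* The wave frame is the default everywhere; lab-frame axial velocity is
  w + 1, and the lab flow rate obeys Q(z) = q + h² identically.
* The plug radius uses |dp/dz|: a signed plug radius is meaningless and
  the gradient changes sign along z.
* Two flux-scale conventions coexist in the source material (2πa²c in
  the nondimensionalization, πa²c in the physiological application);
  the package exposes both and defaults to πa²c for dimensional flow
  rates because only that choice reproduces the published worked
  numbers (e.g. Q̄ = 1.110356 → 0.006279 mL/h at a = 50 μm,
  c = 200 μm/s).
* **Documented discrepancy.** For the ductus scenario (ε = 0.3,
  β = 0.1, Δp = −5.5, Newtonian), the published nondimensional flow
  rate is Q̄ = 1.110356, but evaluating the characteristic gives
  Q̄ ≈ 0.75–0.79 for any tip eccentricity α ∈ [0, 1] (α is not stated
  in the source scenario). The solver is not tuned toward the published
  value: `ductus_report` prints its own prediction and the literature
  value side by side with their relative gap, and only the *unit
  conversion* of the published Q̄ is treated as a checkable quantity.
* Figure presets whose legend value lists are not printed in the source
  captions (the ε list of fig2b; the α, β, Δp and Q̄ lists of figs 3,
  4b, 5, 7, 9) use documented reconstructions bracketing the stated
  fixed values; they are package defaults, overridable per call.
* The velocity-profile crossing radii quoted in the source discussion
  (≈0.58 for the H_p sweep, ≈0.83 for the α sweep) are figure-read
  values; the package computes profiles from which a crossing radius
  can be measured but does not assert those numbers.

## Problem sizes

Default resolutions — 512-point converged quadrature, 401² trapping
grids, 200-draw flux-identity sweeps — were chosen so a full analysis
(all thresholds, the trapping sweeps of the streamline panels, and the
acceptance recomputation) completes in seconds on one core while
leaving every reported digit quadrature-converged.

## Limitations

* Leading lubrication order only: no finite-β or finite-Re corrections,
  and no resolution of the sub-layer hydrodynamics of individual cilia.
  Results apply to slow, long-wavelength metachronal pumping.
* H_p constant in z means the yield surface does not respond to the
  local pressure gradient; near stations where dp/dz → 0 a true Casson
  plug would widen unboundedly, a regime this model does not represent.
* The trapping census measures areas of ψ level-set polygons, not
  material transport; Lagrangian drift and reflux are out of scope.
* The model is an idealized rigid-envelope description: it does not
  model absorption or secretion along the duct, nor fit experimental
  flow measurements.
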