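# Methods

This note documents the models implemented in `strutdiff`, the choices
made where the underlying physics or published precedent left the design
open, and the known limits of what the test suite demonstrates.

## 1. FRAP analysis

### Model

A disk of radius ω (micrometers) is photobleached instantaneously and
uniformly in a thin fluorophore-loaded film; recovery of the mean
fluorescence over the disk is timed.  For free 2D diffusion the
normalized recovery of a uniform-disk bleach has the closed form

    f(t) = e^(−2τ/t) [I₀(2τ/t) + I₁(2τ/t)],   τ = ω² / (4D),

whose half-time satisfies D·t½/ω² ≈ 0.224.  The analysis stage inverts
that relation: measure t½, report D = 0.224·ω²/t½ (cm²/s, with the
μm→cm conversion centralized in `strutdiff.units`).  The 0.224 constant
is independently validated in the test suite by root-finding on the
closed form (0.2236, asserted to ±0.001).

### Normalization

Raw traces are normalized as f(t) = (F(t) − F₀)/(F_pre − F₀), where
F_pre is the mean pre-bleach intensity and F₀ the first post-bleach
sample; times are shifted so the bleach end is t = 0.  This is the
standard full-recovery convention: f starts at 0, approaches 1, and is
invariant to rescaling all intensities by a positive constant (asserted
as a property test).  The mobile fraction is assumed to be 1; an
amplitude-fitting option exists but is off by default.

### Half-time extraction

Default: piecewise-linear interpolation of the first upward crossing of
f = 0.5, optionally after a centered moving average (off by default).
This is assumption-free but inherits sampling noise near the crossing;
with 2% intensity noise single-curve estimates of D scatter by ~5–15%.
Alternative: least-squares fit of the uniform-disk closed form
(`method="soumpasis_fit"`), which uses the whole curve and is markedly
less noise-sensitive.  Replicate curves can be averaged pointwise on a
common time grid (linear interpolation; per-point SD reported), the
usual practice when 5–7 bleaches are collected per condition.

### Obstruction-model rescaling

Diffusion through a random fiber network attenuates as
D/D₀ = exp(−φ_v·r_s/r_f) (fiber volume fraction φ_v, fiber radius r_f,
solute radius r_s).  A single measured ratio identifies only the lump
κ = φ_v/r_f = −ln(D/D₀)/r_s; the package exposes exactly that lump and
refuses to pretend otherwise (a helper computes φ_v from κ only when the
caller supplies a fiber radius, and is documented as derived).  Any
other solute rescales as D_new = D₀_new·exp(−κ·r_new), equivalently
(D/D₀)_ref^(r_new/r_ref).  Worked example: a 1.2 nm macromolecular probe
measured at D/D₀ = 0.59 implies κ = 0.4397 nm⁻¹, and for oxygen
(r = 0.14 nm, D₀ = 2.68×10⁻⁵ cm²/s at 37 °C) predicts
2.52×10⁻⁵ cm²/s — 94% of the value in water.  The obstruction model is
known to overestimate D for small solutes; the rescaled oxygen value
should be read as an upper-range estimate.

## 2. Synthetic FRAP generator

The generator solves the 2D diffusion equation for the bleach *deficit*
u = 1 − c with initial condition u = bleach_fraction inside the disk,
0 outside, and reads out the mean concentration over the disk per frame.

* **Solver.** Default is spectral: the deficit is expanded in a sine
  (far-field/open) or cosine (reflecting) basis per axis via DST/DCT-II
  on the cell-centered grid and each frame is obtained by exact modal
  decay e^(−D|k|²t) — no time-step error, and total fluorophore is
  conserved to machine precision in fully closed geometries.  A
  forward-Euler finite-difference mode (stability bound dt ≤ h²/4D,
  enforced) is retained purely as an independent cross-check; the two
  agree to <1% on shared scenarios.
* **Defaults.** ω = 50 μm spot, 2.5 μm grid (ω/h = 20), 600 μm domain
  (12 ω), 0.25 s frames for 40 s.  Bleach depth 0.5 — the normalized
  curve is provably independent of it, which the tests assert.
  Measurement noise is zero-mean Gaussian on the *normalized* signal
  (default σ = 0.02), seeded.
* **Idealizations.** Instantaneous uniform-depth bleach (real pulses of
  a few hundred ms against ~4 s half-times), pure 2D diffusion (film
  thickness comparable to the spot is *not* modeled, matching the 2D
  uniform-disk analysis formula), no photophysics beyond additive
  Gaussian noise.  Passing parameter-recovery tests therefore shows the
  analysis inverts this idealized generator, not that real microscope
  data are free of bleach-profile, thickness or photofading biases.
* **Confinement.** A line pattern of finite width is modeled with
  reflecting long edges.  The confinement comparison runs confined and
  open boundary conditions on the *identical* grid, isolating the
  boundary effect from voxelization differences; reflecting edges bounce
  the deficit back, so confined recovery can only be slower.  At the
  fabricated line width (~309 μm) against a 50 μm spot the effect is
  far below measurement noise, supporting the use of the infinite-film
  formula for such measurements.

## 3. Scaffold geometry

One lateral period (pitch × pitch) of an infinite flat scaffold built
from 50-μm-tall layers of parallel rectangular struts, each layer
rotated 90°, stacked to 1000 μm; struts of the same orientation are
vertically aligned (lattice) or offset by half a pitch every second
repeat (staggered/zigzag — the half-pitch offset is an inference from
the published schematic, not a stated value).  The strut volume fraction
α fixes the strut width w = α·pitch; bands are centered in the period so
the geometry is mirror-symmetric about the period mid-planes, which is
what the symmetric lateral boundary conditions require.  When the
lateral voxel counts are even, `symmetry_reduce` cuts the domain to the
quarter period, an exact reduction that the production runs use.

The pitch is the one genuinely free geometric parameter: it is not a
published value.  The default, 600 μm, makes the strut width at α = 50%
equal 300 μm, matching the measured width of the fabricated nanofibrous
lines.  Results depend on it strongly (see §6); it is a first-class
config knob.

Voxelization is exact (achieved α equals target α to the voxel) whenever
voxel_size divides pitch, strut width and band offset; otherwise the
band edges round to voxel centers and the error is bounded by one voxel
slab, which the tests check by brute-force counting.

## 4. Oxygen / growth solver

### Model

Quasi-static oxygen with Michaelis–Menten consumption in the culture
domain,

    ∇·(D∇C) = ρ·V_max·C/(K_m + C),

with C = C₀ on the top (media-exposed) face, zero flux at the bottom
wall and lateral mirror faces; D = D_t in culture, D_s in strut, cells
(and hence consumption) only in culture.  Cell growth by Monod kinetics
expressed as a *doubling* rate r_g = r_g,max·C/(K+C) with
r_g,max = 1/t_d, so base-2 exponentiation is the correct update
(base-e would misread the doubling-time definition):
ρ → min(ρ_max, ρ·2^((r_g−k_d)·Δt)).

Constants (SI internally; converted once at load): V_max = 3.3×10⁻¹⁶
mol·cell⁻¹·s⁻¹, K_m = 3.79×10⁻³ mol/m³, K = 3×10⁻³ mol/m³ (3 nmol/mL),
C₀ = 0.1 mol/m³, ρ₀ = 2.1×10¹¹ and ρ_max = 1.5×10¹⁴ cell/m³,
t_d = 36.5 h, D_t = 2.0×10⁻⁵ cm²/s, D_s ∈ [0, 2.68×10⁻⁵] cm²/s,
D_w = 2.68×10⁻⁵ cm²/s.

### The decay extension k_d

Pure Monod growth is non-negative, yet the phenomenon being modeled
shows the bottom-surface density *declining* after an early peak — an
impossibility without a loss term.  The minimal extension is a constant
first-order decay k_d subtracted from the doubling rate; default
k_d = 0.1·r_g,max, configurable, k_d = 0 supported (peak-time metrics
are then undefined and flagged).  The decay sets the oxygen level a
population can just sustain, C* = K·k_d/(r_g,max − k_d) ≈ 3.3×10⁻⁴
mol/m³ at the default: at steady state, culture with C > C* is
confluent and culture with C < C* is empty.  There is no claim that the
original study used this same loss form.

### Numerics

* Cell-centered finite volumes, 7-point stencil, harmonic-mean face
  diffusivities — exact for piecewise-constant D, and D_s = 0 produces
  exactly zero-flux strut faces.  Top Dirichlet by a ghost value at
  distance h/2 (transmissibility 2Dh).
* The nonlinear sink is handled by Picard iteration with the coefficient
  frozen at the current iterate: s = ρV_max/(K_m + C_old).  Every
  linearized operator is then a strictly diagonally dominant M-matrix,
  iterates stay positive, and the fixed point is the physical solution
  even in the stiff zero-order limit C ≫ K_m (a projected-Newton
  linearization was evaluated and rejected: clipping a Newton step onto
  [0, C₀] can lock the iteration onto a spurious all-zero state when
  K_m → 0).  Damping 0.7 engages on stagnation.  Convergence: max
  update < 10⁻⁶·C₀ (Table-scale problems need 2–5 iterations with warm
  starts; the deliberately stiff zero-order test needs ~200).
* The linear systems are nondimensionalized by the peak transmissibility
  and solved by Jacobi-preconditioned conjugate gradients (rtol 10⁻⁸),
  warm-started from the previous oxygen field.  Isolated voxels (strut
  interiors at D_s = 0) are pinned to C₀, their physically arbitrary
  initial value.
* Verification: the solver reproduces the zero-order closed form
  C₀(1−z/L)², L = √(2D_tC₀/ρ_maxV_max) ≈ 90 μm, within 3% at 5 μm
  voxels, the first-order cosh profile within 1%, returns exactly C ≡ C₀
  for ρ ≡ 0, and matches an independent implicit-Euler transient
  integration run to equilibrium within 10⁻³·C₀.
* Coupling: oxygen equilibrates over L²/D ~ seconds while the population
  evolves over t_d = 36.5 h, a ~10⁴ timescale separation, so each 2 h
  growth step uses the quasi-steady oxygen field (operator splitting).
  The transient oxygen mode exists only as a test oracle.
* The density cap is a hard min at ρ_max, matching a "predetermined
  maximum" rather than a logistic crowding term.

### Steady-state detection

A run is steady when the max per-voxel density change, relative to
ρ_max and expressed per day, drops below ε = 10⁻³ — but only after that
activity measure has first *exceeded* ε.  Without the arming condition
the criterion fires spuriously at seeding, where the population
(ρ₀/ρ_max ≈ 0.0014) is so small that even exponential growth moves less
than 10⁻³·ρ_max per day.  Runs are capped at a configurable t_end
(50 days for the desk-scale study) and flagged if the criterion was
not met.

## 5. Metrics

* **Depth profile**: per-voxel-slab mean density over culture voxels
  (strut voxels excluded; cell-free slabs flagged as NaN, and verified
  against a brute-force masked loop).
* **Saturated depth**: deepest slab edge such that every shallower
  culture slab has mean ρ ≥ 0.99·ρ_max.  Exact equality with ρ_max is
  unreachable under capped exponential growth in finite time, hence the
  threshold; it is a config knob, and depth is reported at slab
  resolution (10 μm default — fine enough that the published 86-vs-98 μm
  distinction spans more than one slab).
* **Saturation time t_s**: first checkpoint meeting the steady criterion
  (after activity), for the D_s/D_w = 1 run; by convention this single
  t_s normalizes the timing fractions of *all* runs.
* **Top saturation / bottom peak**: first checkpoint where the top slab
  reaches 0.99·ρ_max; argmax of the bottom-slab trace, flagged undefined
  when the maximum sits at the final checkpoint or the series is
  monotone (always the case at k_d = 0).
* **Sweeps** iterate (α, arrangement, D_s/D_w), adding the D_s/D_w = 1
  reference per group for the normalizer, and record per-run failures
  without aborting the table.

## 6. The desk-scale headline study and its discrepancies

`strutdiff.headline` pins the study configuration: α = 50% lattice,
pitch 600 μm, 10 μm voxels, quarter-period reduction, 2 h steps,
k_d = 0.1·r_g,max, ε = 10⁻³/day, 50-day cap, with strut diffusivities
D_s/D_w ∈ {0, 0.93, 1}.  Three structural findings matter when comparing
to the published figures (saturated depths 86/98/99 μm, t_s ≈ 28 d,
fractions 0.54/0.13/0.23):

1. **Geometry sensitivity.** With culture-only consumption, the strut
   volume removes half the oxygen sink, and permeable strut crossings
   form consumption-free vertical conduits whose influence scales with
   strut width.  Sweeping the pitch from 120 to 600 μm moves the
   ultimate non-permeable front from ~100 to ~50 μm and the permeable
   front from ~170 to ~120 μm.  No pitch reproduces the published
   *pair* (86, 98): the model's permeable/non-permeable gap is ≥60% at
   any pitch, against the published ~15%.  The published depths instead
   coincide, to a few percent, with the 1D closed form
   L·(1−√(C*/C₀)) evaluated with *full-volume* consumption and the
   respective diffusivity — suggesting the original model's (unstated)
   lateral geometry interacted with consumption quite differently from
   a block-strut unit cell.  The package reports what the stated
   geometry defaults actually produce.
2. **Slow front creep.** Near the saturation front sits culture with C
   barely above C*, growing at a net rate approaching zero; along
   permeable strut conduits the C(z) gradient is shallow, so a band of
   voxels creeps toward ρ_max for tens of days and the ε = 10⁻³/day
   criterion is genuinely slow to satisfy.  The bulk dynamics (top
   saturation, bottom peak and decline) complete within ~30–40 days;
   the tail is a marginal-stability effect of the Monod + decay
   structure.  Runs that hit the 50-day cap are flagged unconverged and
   use the cap as the timing normalizer.
3. **Timing metrics** inherit both effects: the top-surface saturation
   time (~17 days) is robust, but its *fraction* of t_s depends on the
   normalizer, which the creep inflates.

The acceptance suite asserts the published bands anyway and lets the
depth and timing tests fail where the model, run faithfully at the
documented defaults, lands outside them; the property-based acceptance
checks (closed-form oracles, bounds, monotonicity in D_s, parameter
recovery) all pass and are the tests that validate the implementation
itself.

## 7. Known limitations

* Strut cross-sections are rectangular blocks; the lens-shaped profile
  of fabricated lines, fiber-scale microstructure inside struts (it is
  abstracted into D_s) and scaffold degradation are not modeled.
* Single nutrient (oxygen), no convection/perfusion, no cell migration
  or mechanics.
* The FRAP generator is 2D with an ideal instantaneous bleach; detector
  physics beyond additive Gaussian noise is out of scope.
* The decay term k_d is a surrogate for an unknown loss mechanism;
  bottom-peak timing depends on it roughly linearly through C*.
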