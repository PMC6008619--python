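# Methods

## Physical model

The drive is a sinusoidal-equivalent pulse: a biphasic TMS pulse is
represented by its dominant frequency f = 2.5 kHz and peak current
I = 5 kA (100% stimulator output), so all reported fields are peak
amplitudes of a single-frequency phasor. At these frequencies head tissues
satisfy σ ≫ ωε (for gray matter at 2.5 kHz, ωε/σ ~ 10⁻³ even with generous
permittivity values), so the permittivity is dropped everywhere except in
the quasistatic smallness check ωμσd² (≈ 2.5·10⁻³ for σ = 2 S/m,
d = 0.25 m — comfortably quasistatic). Consequences adopted throughout:

* the source field is the magnetostatic vector potential A₀ of the winding
  currents with μ = μ₀ everywhere (no magnetic materials, induced-current
  feedback on B neglected);
* the electric field is E = −(ω I A₀ + ∇φ), with the scalar potential from
  charge conservation ∇·(σ∇φ) = −ω I ∇·(σ A₀);
* boundaries (tissue–air, domain box) carry zero normal current
  (zero-Neumann); E is defined only where σ > 0;
* the problem is real-valued: the factor jω of the complex formulation
  becomes the amplitude scaling ω under the peak-phasor convention.

## Coil models

Coils are ordered lists of straight segments with signed dimensionless
current weights. Spiral windings become bundles of concentric closed
circular loops (pitch error second order), each a regular polygon of 128
chords by default (loop-center field error < 0.1%; halving to 64 changes
V50-level results imperceptibly and is used in the test suite).

* **Double-cone**: two wings of 10 loops, diameters 15→40 mm, planes at a
  120° dihedral angle meeting at the apex, opposite senses so the current
  under the apex is co-directed. Wings bend toward the head (apex is the
  wire point farthest from the scalp); the placement reference is the
  bottom-of-windings level under the apex, so a 10 mm vertex offset keeps
  the whole coil off the scalp on convex heads.
* **Figure-of-eight**: the 180° (flat) limit of the double cone.
* **Halo**: 5 coplanar circular windings, radii 138→150 mm, one sense,
  worn 97 mm below the vertex. The printed winding dimensions are
  interpreted as radii: a 150 mm *diameter* ring cannot encircle an
  adult-sized head at that plane (the default phantom's lateral radius
  there is ≈ 90 mm), while radii reproduce the published halo-coil
  construction and clear the scalp by ~50 mm.
* **Magstim-style D70**: two flat wings of 9 windings, radii 16→24 mm at a
  1 mm center-to-center pitch — the only layout consistent with the quoted
  inner/outer diameters (32/48 mm) and the 1 mm separation; a mismatch
  raises a geometry-infeasibility error.
* **HDA / HFA**: concatenations (Halo + double-cone / + figure-of-eight)
  driven by the same current. Sign convention: Halo counterclockwise seen
  from above, right wing of the double-cone/Fo8 likewise, left wing
  opposite. The right side of the head then sees co-directed currents from
  both coils and the left side opposing ones, which is the entire source of
  the right/left asymmetry in the results; reversing the double-cone sense
  mirrors it.

Biot–Savart uses exact per-segment closed forms (the stable two-endpoint
expression for B, the log expression for A₀), so no quadrature tolerance
enters; fields superpose across combined coils to machine precision. Points
within 1 mm of a wire are reported as NaN: the zero-thickness wire model
diverges there. Head voxels are never affected (coils sit ≥ 10 mm off the
scalp); the guard exists for visualization grids.

## Discretization and solver

Uniform isotropic voxel grids; voxel centers at origin + (index + ½)h.
The scalar-potential equation is integrated over each σ > 0 voxel with a
7-point stencil:

* face conductance g = (2σᵢσⱼ)/(σᵢ+σⱼ) · h (harmonic mean), which is zero
  across any face touching σ = 0 and thereby *is* the insulating boundary —
  no explicit boundary handling, and current continuity across tissue
  interfaces is preserved;
* source flux per face uses the same harmonic σ with A₀ averaged from the
  two adjacent voxel centers and projected on the face normal; the
  right-hand side telescopes to zero exactly (pure-Neumann compatibility);
* the operator is symmetric positive semidefinite with a constant
  nullspace; the RHS is mean-projected and the gauge fixed by removing the
  σ-weighted mean of φ; solved by conjugate gradients with Jacobi
  preconditioning, relative tolerance 10⁻⁸, max 10 000 iterations (the
  2 mm phantom solves take 400–600 iterations);
* E reconstruction uses central differences for ∇φ, one-sided at
  lossy-domain boundaries so φ values from outside the domain never enter;
* a conservation diagnostic recomputes all face currents from the solved φ
  and reports the largest per-voxel imbalance over the mean face current —
  at the linear-solver residual scale for a converged solve.

Exactness properties used as test oracles: a spatially uniform A₀ over any
voxelized domain is cancelled exactly by a linear φ (slab and ball tests
pass at ~10⁻¹²), and the assembled matrix rows sum to zero.

### Staircasing limitation

A coaxial circular coil over a spherically layered conductor has φ = 0 in
the continuum (azimuthal source, radial conductivity gradients). On a voxel
grid this holds only in the bulk: the discrete domain is a jagged
polyhedron whose insulating surface normals are not radial, so the
azimuthal current genuinely accumulates charge at the steps. Measured on
the 2 mm three-layer sphere, max|∇φ| is ~50% of max|ωA₀I| in a thin surface
layer and does not shrink with refinement, while the median converges O(h)
(0.7% at 2 mm, ~0.35% at 1 mm) and |E| at interior probe points changes
< 1% between 2 mm and 1 mm. This is the textbook staircase artifact of
voxel dosimetry; it is the reason the cortical "maximum" is defined as the
99th percentile, and it is why the symmetry-oracle acceptance test that
demands 1% in max-norm fails while every bulk-field statistic behaves.

## Phantom and conductivities

The synthetic head is a deterministic layered sphere: outer radius 90 mm
with scalp 5 mm, skull 7 mm, CSF 3 mm, gray matter 4 mm shells over a
71 mm white-matter core, sampled at 2 mm (tests; 1 mm available) by
voxel-center membership on a grid that is mirror-symmetric about all three
mid-planes — left/right structure pairs therefore occupy exactly equal
voxel counts and the mid-sagittal plane x = 0 contains no voxel centers.
Deep-structure analogs are ellipsoids in the core at anatomically motivated
positions (bilateral hippocampi, accumbens, amygdalae; midline thalamus and
hypothalamus; an inferior-posterior cerebellum blob), scaled to the core
radius for non-default phantom sizes; overlapping or escaping structures
are construction errors.

What the phantom does *not* emulate: gyral folding, skull layering, neck
and body return paths, tissue anisotropy (notably white matter), and
realistic structure shapes. Passing the phantom study therefore validates
the *mechanisms* (field superposition, hemispheric asymmetry of combined
coils, depth–focality trade-off, metric bookkeeping) — not anatomical field
magnitudes. On the phantom the Halo sits ~50 mm from the scalp everywhere
(a real head is closer and non-spherical), so absolute V50 values differ
substantially from anatomical-model results; the orderings (combined coils
right > left; HDA ≥ HFA at depth; symmetric coils balanced) are the
reproducible content.

Conductivities ship as a versioned CSV (S/m at 2.5 kHz): scalp 0.465,
skull 0.010, CSF 1.654, gray matter 0.275, white matter 0.126, deep gray
structures at the gray-matter value — the standard low-frequency
head-modeling set consistent with the Gabriel-family database as adopted by
mainstream TMS dosimetry pipelines. Only ratios across tissues matter for
V50 orderings; absolute σ rescales φ but not E's shape.

## Metrics

Cortical peak: 99th percentile (linear interpolation between order
statistics, voxels equally weighted) of |E| over the gray-matter label;
when a distinct cerebellum label exists it is excluded from "cortex" since
it is reported separately. V50: 100 × (voxels with |E| ≥ 0.5·peak)/(tissue
voxels), threshold inclusive. Hemispheres split head voxels by the
mid-sagittal plane (head centroid by default); on-plane voxels go right — a
tie-break that never fires on the symmetric phantom grid. Hemispheric V50
uses per-hemisphere denominators so each side can independently reach
100%. A coil inducing no field at all reports V50 = 0 (not the degenerate
100% a zero threshold would imply); an absent tissue reports NaN, never a
silent zero.

## Validation line scan

The Magstim-style D70 export samples the coil-normal component of
H = B/μ₀ (kA/m) along the line through both wing centers at 20 mm height.
The signed profile is odd about the junction (B is a pseudovector under the
coil's mirror symmetry) with |H| peaking above the windings at ±24 mm
(407.6 kA/m at 5 kA) and a zero crossing at the junction. Measured bench
profiles can be supplied as CSV for a deviation report; none ships with
the package.

## Problem sizes

Default study: 92³ grid (2 mm), ~382 000 conducting voxels, five coil
configurations (Halo, double-cone, Fo8, HDA, HFA) — under a minute on one
CPU for the full pipeline including all solves. The 1 mm phantom
(~3 million unknowns) solves in minutes and is available through the same
config; grid-convergence checks in the suite use a scaled three-layer
sphere at 2 mm vs 1 mm to keep the default run light.
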