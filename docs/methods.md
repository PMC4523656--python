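# Methods

`tdcsim` simulates the quasi-static electric field induced in the human body
by transcranial direct current stimulation (tDCS) and quantifies how that
field varies across individuals of different size.  This note documents the
model, the synthetic phantoms, the numerical choices and their limitations.

## Physical model

Under the quasi-static approximation the potential φ in a volume conductor
with conductivity σ(x) obeys

    ∇ · σ ∇φ = 0,

with the electric field **E** = −∇φ and current density **J** = σ**E**.
Within any region of uniform σ, |E| and |J| differ only by the factor σ, so
every per-tissue statistic computed from one applies to the other.

Boundary conditions: the electrode pads are equipotential surfaces (all
active pads tied to one potential, the reference pad to another), and every
body–air interface is insulating (zero normal current).  The injected
current is imposed indirectly: the solver applies a provisional 1 V pad
difference, measures the resulting net current through the closed voxel
surface around the active pad(s), and rescales φ, **E**, **J** by
linearity so the total equals the prescribed current (1 mA by default).
After scaling, the re-measured current matches the target to well below
0.1%, and by discrete conservation the same current crosses *any* surface
separating the electrodes.

## Discretisation

The solver uses a 7-point finite-volume (box integration) scheme on the
uniform voxel grid.  The conductance of the face between voxels i and j is

    g_ij = harm(σ_i, σ_j) · A / h,      harm(a, b) = 2ab / (a + b),

with A the face area and h the spacing.  The harmonic mean preserves flux
continuity across tissue interfaces; a σ = 0 neighbour (air, internal air)
gives g = 0, which *is* the no-flux condition, so the insulated bounding box
and the skin–air condition need no extra boundary rows.  Pad voxels are
Dirichlet nodes; the remaining conductive voxels form a symmetric,
diagonally dominant system solved either by a sparse direct factorisation
(small grids) or Jacobi-preconditioned conjugate gradients to a relative
residual of 1e-8 (changing 1e-6 → 1e-10 moves the solution by < 1e-5
relative, so the default is far inside the plateau).  **E** is evaluated at
cell centres by central differences, one-sided at tissue–air faces; air
voxels carry zero field and never enter statistics.  Everything is
deterministic — the pipeline contains no random numbers.

Exact properties of this discretisation, all verified by the test suite:
doubling the injected current doubles the field; multiplying every σ by k
leaves **J** unchanged and divides **E** by k; scaling every linear
dimension by k (same voxel lattice) multiplies |E| by 1/k² at fixed
current.  The last property is the mechanistic reason a smaller subject
experiences higher fields at equal injected current.

## Verification oracle

An analytic series solution for concentric-sphere conductors with a surface
point current source and sink serves as an independent standard.  Per
Legendre degree n, the radial part A rⁿ + B r^−(n+1) is chained across
shells by a 2×2 transfer recursion using radially scaled basis functions
(no overflow at high order; default truncation 200 with an explicit tail
estimate).  The voxel solver is compared on a 60 mm three-shell sphere with
brain/skull/skin conductivities; electrodes in the voxel model are Dirichlet
patches of fixed 5 mm radius so refinement converges toward a single
continuum problem, and a band of two voxels around the patch rim is excluded
(the point-source potential is singular there).  Relative L2 disagreement
falls monotonically, ≈ 7% → 4% → 2.5% at 6 → 4 → 2 mm.

## Synthetic phantoms

Real MRI-derived anatomies are proprietary, so the study population is a
parametric stand-in — an explicit emulation, not a reconstruction:

* **Head**: concentric spheres (scalp skin 6 mm, skull 7 mm, CSF 3 mm, grey
  matter 10 mm at the 1.77 m reference; white matter fills the core;
  outer radius 92 mm).  The deep regions the dosimetry reports on —
  thalamus, cerebellum, midbrain, pons, medulla oblongata — are ellipsoidal
  sub-regions of the inner sphere at fixed fractional coordinates, sized so
  their voxelised volumes converge (< 3% change when the voxel size halves).
* **Body** (for extracephalic montages): head sphere + neck cylinder + trunk
  ellipsoid + arm and leg cylinders, with a one-voxel skin shell, a
  subcutaneous-fat shell, muscle bulk and bone cores; electrode sites on the
  lateral mid-upper right arm and the anteromedial mid-tibia.
* **Family**: adult female (1.63 m), adult male (1.77 m), adolescent
  (1.47 m) — one reference geometry scaled isotropically by standing height.

Each head layer is floored to one voxel thickness at paint time so the
skin/skull/CSF conduction topology survives coarse grids.  This matters for
interpretation: at 4 mm, the adolescent's ~2.5 mm CSF is inflated relatively
more than the adults', which artificially suppresses its brain field.  The
default study resolution (2 mm heads, 4 mm bodies) resolves the CSF of all
members, and there the expected ordering — the smallest phantom has the
highest grey-matter median |E| under every montage — holds.

What the phantoms deliberately do not model: gyrification and realistic
cortical geometry, the ~75-tissue segmentation of MRI-derived models,
ventricles, anisotropic white matter, and electrode–skin contact impedance.
Passing tests therefore demonstrate correctness of the physics, metrics and
statistics machinery, and the *qualitative* size effects; they do not
reproduce the field magnitudes or focality percentages of any real anatomy.

## Electrode montages

Pads are 5 × 7 cm conductors (σ = 5.9e7 S/m) over 7 × 8 cm saline sponges
(σ = 0.3 S/m) contacting the skin.  Scalp positions follow the 10–20 system
as fixed (inclination, azimuth) angles on the best-fit scalp sphere, with
F3/F4 constructed as spherical midpoints of Fz–F7/Fz–F8.  Montages:
A = F3/F4, B = T3 + right arm, C = C3+C4 (parallel) + right arm,
D = Fz + right tibia; 1 mA total in all cases.

Voxelisation: sponge and pad occupy signed-distance bands above the nominal
anatomical surface (scalp sphere or limb cylinder), restricted to the
footprint rectangle in tangent coordinates, with the long axis along the
anterior–posterior tangent (limb axis for extracephalic sites).  Pad and
sponge thicknesses (1 mm and 5 mm nominal, unstated in clinical practice
descriptions beyond "sponge pad") are rounded up to whole voxels.  Because
tissue voxel centres lie inside the nominal surface, the sponge is always
face-adjacent to skin and the pad can only reach skin through its sponge.
On a sphere head the two 7 × 8 cm sponges of montage A physically collide
near the midline; each footprint is clipped at the inter-electrode bisector
leaving an ≈ 1-voxel air gap (an error is raised if the *pads* themselves
would overlap).  `standard_montage(..., electrode_scale=...)` shrinks the
hardware proportionally for reduced-size phantoms used in tests.

## Metrics

* Per-tissue descriptive statistics of |E|: median, 25th/75th percentiles
  (linear interpolation), minimum, maximum; "peak" is the literal maximum by
  default, with an optional 99.9th-percentile robust peak because single-voxel
  maxima are the quantity most sensitive to grid artifacts.
* Focality: V70 (V50) = percentage of a tissue's volume with amplitude
  strictly greater than 70% (50%) of its within-tissue peak; the thresholds
  correspond to amplitude reductions of 20·log10(1/0.7) ≈ 3 dB and
  20·log10(1/0.5) ≈ 6 dB.  Both are scale-invariant.
* Variability: CV = sample standard deviation / mean (n−1 convention, n = 3
  models) of the peak and median of |E| across the family, reported in dB as
  20·log10(1 + CV).  This convention maps CV = 1 to ≈ 6 dB, consistent with
  the amplitude-dB scale above; the plain 20·log10(CV) convention is
  selectable.

## Statistics

The focality percentages are compared across the family with a
Kruskal–Wallis test (factor: human model; midranks, tie correction,
chi-square p with df = k−1).  V70 and V50 are tested separately; the
sampling unit is the (montage × tissue) cell — 8 values per model with four
montages and grey/white matter.  If the omnibus test is significant at
α = 0.05, Mann–Whitney pairwise comparisons follow with Bonferroni
adjustment for the three model pairs.  For small samples the package
computes an exact permutation p for H by full enumeration of rank
assignments (pooled N ≤ 12), and uses the exact U distribution when both
groups have ≤ 8 tie-free observations.  Under identical continuous nulls
the simulated type-I error of the omnibus test at α = 0.05 over 10 000
seeded replicates (3 groups × 8) is ≈ 0.046 — the mild conservatism of the
chi-square approximation at these sample sizes.

## Problem sizes and runtime

The default study (3 phantoms × 4 montages) uses 2 mm heads (~10⁶ voxels,
~4·10⁵ unknowns) and 4 mm bodies (~3·10⁶ voxels, ~7·10⁵ unknowns); a case
solves in seconds to about a minute on one CPU core.  The test suite uses
smaller phantoms (scaled heights, 4–8 mm voxels, proportionally scaled
electrodes) for unit-level checks and the default resolution for the family
study.  2 mm whole-body grids are supported but take substantially longer;
1 mm (the resolution clinical modelling studies typically quote for heads)
is practical for head-only montages.

## Known limitations

* The phantom family varies only overall size (plus optional per-layer
  overrides); real interindividual variability also involves CSF
  architecture, skull thickness patterns and cortical folding, all of which
  shape the current flow and are not represented.
* Focality values on sphere heads are not comparable in magnitude to values
  computed on realistic anatomies (spheres lack sulci where local hotspots
  form).
* Electrodes are ideal conductors over uniform sponges; contact impedance
  and saline saturation gradients are ignored.
* The analytic oracle covers concentric spheres only; the body-phantom
  solves are verified through conservation, scaling and symmetry properties
  rather than an analytic solution.
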