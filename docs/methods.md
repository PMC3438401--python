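# Methods

`trabevalid` implements and validates specimen-specific micro-finite-element
(μFE) models of cement-augmented trabecular structures. The physical system
it targets is a cylindrical open-cell polyurethane foam specimen — a standard
surrogate for osteoporotic trabecular bone — whose two ends are embedded in
PMMA bone cement, compressed quasi-statically inside a micro-CT scanner, and
imaged unloaded and at several load increments. The package covers the whole
chain: synthetic specimen generation, scan emulation, segmentation, boundary
condition estimation, voxel-based μFE solution, and a pixel-wise
deformed-morphology validation metric. Because no real scan data ship with
the package, the experiment is closed-loop: "experimental" loaded scans are
synthesised from the solved displacement field plus imaging noise, and the
validation machinery is then run blind against them.

## Synthetic specimen generator

The foam phase is a Poisson–Voronoi strut lattice. Per specimen, a nominal
cell size `c` is drawn uniformly from `cell_size_range` (default
1.5–2.5 mm); seed points are scattered as a Poisson process with mean
spacing `1.5 c`, the edges of their Voronoi tessellation become strut axes,
and each strut is dilated to a radius drawn from half the strut-thickness
range (default thickness 0.15–0.30 mm). The spacing factor 1.5 is a
deliberate calibration: a Poisson–Voronoi tessellation carries edge length
density `5.832 λ^{2/3}` per unit volume, substantially more than a real
reticulated foam of equal nominal cell size, and the factor brings the
resulting relative density below 5% across the supported parameter ranges,
matching the >95% porosity of the physical foam.

Two post-conditions are enforced:

* **Porosity ≥ 95%.** If the rasterised solid fraction of the cylinder
  interior exceeds 5%, all strut radii are shrunk by a single factor found
  by bisection (the solid mask is a threshold on a precomputed
  distance-to-axis/radius field, so the bisection is cheap). Shrinking below
  one voxel radius is an error rather than a silent distortion.
* **Connectivity.** The solid phase is reduced to its largest 26-connected
  component and must touch both end planes, otherwise the specimen could not
  transmit load and generation fails.

Cement end-caps convert every non-foam voxel of the cylinder cross-section
within the cap depth into cement while retaining the foam struts inside the
cap — the interdigitated composite that makes the bone–cement interface
non-trivial. Fiducial markers are 3-voxel-radius spheres placed in the pore
space near the cylinder wall; their only role is to define the sagittal
comparison stations, mimicking the "paint" markers an operator would add to
real scans.

### Imaging emulator

A scan is produced as: per-class mean gray value → Gaussian point-spread
blur (σ = 15 μm by default, producing partial-volume blending at material
boundaries) → additive Gaussian noise with a per-class standard deviation.
Defaults (background 20 ± 8, foam 105 ± 12, cement 165 ± 12, marker
235 ± 10, 8-bit-like scale) give the foam and cement overlapping grayscale
distributions — the property that makes their segmentation genuinely
ambiguous on real specimens — while leaving the background well separated.
The emulator does not model X-ray projection physics, beam hardening, or
ring artefacts; consequently the tests demonstrate method consistency under
realistic noise and partial volume, not robustness to reconstruction
artefacts.

## Preprocessing and segmentation

Scans are emulated at 25 μm and block-mean downsampled by 2 to 50 μm for
model generation (block mean preserves the partial-volume behaviour that a
subsequent threshold acts on; the comparison scans stay at 25 μm). The two
segmentation thresholds are chosen by three-class Otsu (between-class
variance maximisation) on the pre-loaded scan and can always be overridden;
intensity equal to a threshold joins the upper class. A connectivity filter
removes solid islands smaller than `min_component_voxels` (default 27 at
50 μm — larger than any noise speck or detached marker residue, far smaller
than any real strut network); removing more than 20% of the solid volume is
treated as evidence of misplaced thresholds and raises. This filter plus
threshold override is the automated stand-in for manual slice-wise
refinement; peak local stresses are the quantity known to be sensitive to
that refinement (on the order of 20%), which is a documented limitation.

## Boundary conditions

End displacements are estimated exactly as an operator would from images:
≥5 corresponding points per end, unloaded vs loaded, and the componentwise
signed mean of their differences (the estimator is literally the sample
mean — permutation-invariant and linear). Platen twist is not estimated. In
the closed loop the landmark step is exercised with synthetic points; a
per-point noise option emulates measurement uncertainty.

## Micro-FE model

One 8-node trilinear hexahedron per solid voxel (edge 50 μm), 2×2×2 Gauss
quadrature (exact for the cube element), two homogeneous linear-elastic
materials: foam E = 280 MPa, cement E = 2280 MPa, ν = 0.3 for both. Voxel
hexahedra replace smoothed tetrahedra deliberately: they admit uniform
per-material element stiffness templates, and the unloaded-state calibration
of the validation metric absorbs the geometric difference the same way it
absorbs smoothing effects.

* **Boundary conditions** are Dirichlet: all three displacement components
  of every end-face solid node are prescribed to the rigid end displacement
  ("clamped"). An `axial_free` mode (axial component only, plus minimal
  lateral pins) exists for verification problems whose closed forms assume
  free lateral expansion.
* **Interfaces.** Tied contact is shared nodes — the natural voxel-mesh
  default. The frictionless model duplicates every node shared by bone and
  cement elements and couples only the face-normal displacement component of
  each interface-face corner pair through a penalty spring (default
  100·E_cement·h per face, split over its four corner pairs); tangential
  sliding is free. This is a linearisation of small-sliding frictionless
  contact; Coulomb friction is out of scope. Note the infinite-penalty limit
  is rigid-normal frictionless contact, *not* tied bonding, so the penalty
  solution converges to that limit while its distance to the tied solution
  plateaus at the physical tied-vs-frictionless gap.
* **Solver.** The assembled sparse system is reduced by eliminating
  prescribed DOFs and solved with Jacobi-preconditioned conjugate gradients
  (deterministic ordering; default relative residual 1e-8, max 20 000
  iterations) or a sparse direct factorisation below 4000 free DOFs.
  Specimen-scale pipeline runs use a residual of 1e-5: the validation
  operates on 25 μm pixels, and at that tolerance displacement errors are
  nanometres. Small-strain theory throughout; solutions at proportional load
  increments are exact scalar multiples, which the pipeline exploits by
  solving once per direction and scaling.
* **Stress recovery.** Centroid stress is the average of the eight
  Gauss-point stresses; "maximum von Mises" excludes the element layers
  adjacent to the Dirichlet faces to avoid constraint singularities.
* **Apparent stiffness.** Defined as axial reaction over relative axial end
  displacement. For purely axial prescribed displacements the solver
  evaluates it through the equivalent work identity `F·Δu = uᵀKu`: the
  energy converges quadratically in the conjugate-gradient error where raw
  reaction sums converge only linearly, so the stiffness estimate is robust
  at pipeline tolerances (on very compliant strut structures the raw
  reaction imbalance can reach percents of the reaction at a 1e-6 residual,
  while the energy estimate moves by <0.1% between 1e-6 and 1e-8).
* **Force balance** (top vs bottom reactions) holds to the solver residual
  and is asserted at 1e-6 relative in the verification suite, which uses
  direct solves.

## Deformed-morphology validation

The FE-predicted deformed geometry is rasterised back into image space: each
solid voxel hexahedron is carried through its 8 nodal displacements, split
into 6 tetrahedra around its main diagonal, and sampled at 2× supersampled
target pixel centres (point-in-tetrahedron by barycentric coordinates); a
target voxel is solid when at least half its 8 samples are, with ties and
overlaps resolved toward the higher class code (cement over bone). The
output grid stays aligned with the input origin, so a zero field at equal
resolution reproduces the input bit-for-bit. Negative-volume (inverted)
tetrahedra are counted and reported as a distortion warning.

Comparison slices are single-pixel sagittal planes at three stations given
by the marker centroids (fractional 25/50/75% defaults when no markers).
Both sides are compared at the scan resolution (25 μm), the FE side being
rasterised to match. Within the registered region, model-solid/scan-background
pixels are false positives, model-background/scan-solid are false negatives,
and the total error is their sum normalised by the *scan's* solid pixel
count. The normalising image is genuinely ambiguous in the field's usage;
normalising by the observed structure expresses errors relative to what was
actually measured and is recorded here as the package's choice. Marker
pixels are excluded from all counts. Applied to the unloaded pair, the same
metric yields the calibration baseline attributable to segmentation,
meshing and rasterisation alone.

## Closed-loop experiment and problem sizes

The desk-scale configuration (`pipeline.scaled_demo_config`) uses a 4 mm ×
8 mm cylinder with 1.5 mm caps at 25 μm scan / 50 μm element resolution
(~3.3×10⁵ elements, ~1.1×10⁶ DOF) and cells scaled with the specimen
(1.0–1.7 mm) so several cells span the reduced diameter; porosity
enforcement then thins some struts toward ~0.1–0.2 mm, which the elements
still resolve. On this configuration the unloaded calibration error is
~2%, and closed-loop errors at the 3% and 5% nominal-strain increments stay
at the same level — as they should, since the loaded scans are synthesised
from the model's own field and the residual error is baseline plus imaging
noise. The sensitivity of the metric to *genuine* mismatch is demonstrated
separately by injecting a plastic-collapse displacement component that grows
with the increment, which drives the error up strictly and mirrors the
elastic-limit breakdown expected of linear models at large strain. Interface
sensitivity studies use a smaller specimen (2.5 mm × 5 mm) so a 4-decade
penalty sweep stays affordable.

## Known limitations

* Linear elasticity only: no plasticity, damage or element deletion, so the
  ~15% increment of the physical protocol is outside the model's validity
  (demonstrated, not hidden, by the mismatch-injection test).
* Coulomb-friction contact and geometric nonlinearity are out of scope.
* The imaging model is additive-Gaussian with a Gaussian PSF; scanner
  artefacts are not emulated, so segmentation accuracy on real scans may be
  worse than the closed-loop figures.
* Peak von Mises stress is sensitive to segmentation detail at the
  interface (order 20%); stiffness and morphology are not (sub-1%).
* Manual slice-wise segmentation refinement is not implemented; the
  connectivity filter and threshold overrides are its automated stand-in.
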