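# trabevalid

Specimen-specific micro-finite-element (μFE) models of cement-augmented
trabecular structures, and a pixel-wise deformed-morphology method for
validating them against micro-CT images of the loaded specimen.

## The problem

After vertebroplasty, PMMA bone cement interdigitates with trabecular bone,
and how that composite region behaves mechanically is hard to capture with
continuum models. μFE models resolve individual trabeculae (one element per
image voxel), but validating them is the bottleneck: classical strain-field
registration does not apply cleanly, so the approach here compares the
*deformed morphology* directly — rasterise the FE-predicted deformed
geometry back into image space and count, pixel by pixel on registered
slices, where the model and the scan disagree.

The experimental system is an open-cell polyurethane foam cylinder
(porosity > 95%, cells 1.5–2.5 mm, struts 0.15–0.30 mm — a standard
surrogate for osteoporotic trabecular bone) with both ends embedded in PMMA
cement, compressed in steps of ~3, 5 and 15% nominal strain inside a μCT
scanner at 25 μm voxels. Since no scan data are deposited, the package
includes a first-class synthetic-specimen generator and imaging emulator,
and validates the whole chain closed-loop.

## The metric

On each of three marker-located sagittal slices, within the registered
region:

* **false positive (FP)** — pixel solid (bone or cement) in the FE image,
  background in the scan;
* **false negative (FN)** — background in the FE image, solid in the scan;
* **total error** = (FP + FN) / (scan solid pixels), in percent.

Applied to the unloaded pair it calibrates the baseline error contributed by
segmentation, meshing and rasterisation; applied at each load increment it
scores the deformation prediction.

## The model

Voxel hexahedral μFE at 50 μm element size (scans block-mean downsampled
from 25 μm), two homogeneous linear-elastic materials (foam E = 280 MPa,
cement E = 2280 MPa, ν = 0.3), end displacements measured landmark-wise
from the images and applied as Dirichlet data, bone–cement interfaces
either tied (shared nodes) or linearised-frictionless (duplicated interface
nodes, normal-only penalty coupling). Jacobi-preconditioned conjugate
gradients with deterministic ordering. See `docs/methods.md` for the full
account, numerical choices and limitations.

## Worked example

`examples/04_closed_loop_validation.py` runs the desk-scale closed loop
(4 mm × 8 mm specimen, ~3.3×10⁵ elements, a few minutes on one CPU):

```
mesh: 331798 elements
thresholds: t_bone=61.1 t_cement=133.5
slice stations (mm): [1.22, 2.01, 2.82]

increment  fp_mean    fp_sd  fn_mean    fn_sd  total_mean  total_sd  n
  initial 1.051268 0.502378 0.884826 0.126104    1.936094  0.383831  3
    step1 1.053153 0.394994 0.777469 0.051851    1.830622  0.429662  3
    step2 1.055405 0.361740 0.678483 0.108436    1.733888  0.411921  3
```

The `initial` row is the unloaded calibration: ~1.9% total error is what
segmentation + 50 μm meshing + rasterisation alone cost, before any
mechanics. The loaded rows (3% and 5% nominal strain, scans synthesised
from the solved field plus fresh imaging noise) stay at the same level —
the deformation prediction adds essentially nothing to the error budget in
the elastic regime, which is the property the validation method is designed
to demonstrate. A dedicated test injects a growing plastic-collapse
component into the "experimental" scans and shows the metric responds with
strictly increasing error.

Other examples: specimen generation (`01`), scan emulation + segmentation
with Dice scores (`02`), a single μFE solve with stiffness and peak von
Mises stress (`03`), and the tied-vs-frictionless interface sweep (`05`).

There is also a thin CLI (`trabevalid foamgen|scan|segment|bc|solve|
validate|pipeline|compare-interfaces`); every subcommand wraps one library
call.

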