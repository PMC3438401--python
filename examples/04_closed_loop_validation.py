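"""Run the full closed-loop pipeline and print the validation table.

Generates the desk-scale specimen, emulates and segments its scan, solves
the tied-interface model at 3% and 5% nominal strain, synthesises loaded
"experimental" scans from the solved field plus imaging noise, and scores
the FE-predicted deformed morphology against them.  The 'initial' row is
the unloaded calibration (error from segmentation/meshing alone); loaded
rows that stay near it show the deformation prediction is as good as the
model generation allows.  Takes a few minutes on one CPU.
"""

from trabevalid.pipeline import run_pipeline, scaled_demo_config

cfg = scaled_demo_config(seed=1, increments=(0.03, 0.05))
result = run_pipeline(cfg, out_dir="scratch/closed_loop")

print(f"mesh: {result.mesh.n_elements} elements")
print(f"thresholds: t_bone={result.thresholds.t_bone:.1f} "
      f"t_cement={result.thresholds.t_cement:.1f}")
print(f"slice stations (mm): "
      f"{[round(x, 2) for x in result.plan.stations_x_mm]}")
print()
print(result.summary.to_string(index=False))
print("\ncolumns are mean (SD) percentages over the three slice stations;")
print("total = false positive + false negative, normalised by scan solid "
      "pixels")
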