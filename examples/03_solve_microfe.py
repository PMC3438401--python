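"""Mesh a small composite specimen and solve a 3% compression step.

Prints the apparent stiffness (axial reaction over relative end
displacement), the peak von Mises stress away from the loaded faces, and
verifies force balance between the two ends.
"""

import numpy as np

from trabevalid import microfe, synthfoam
from trabevalid.registration import build_boundary_conditions

params = synthfoam.FoamParams(cylinder_diameter_mm=2.5, cylinder_height_mm=5.0,
                              cell_size_range_mm=(0.8, 1.2),
                              voxel_size_um=50.0, seed=7)
foam = synthfoam.generate_foam_lattice(params)
specimen = synthfoam.add_cement_caps(foam, 0.8, 0.8)

mesh = microfe.build_mesh(specimen)
height = mesh.shape[0] * mesh.h_mm
strain = 0.03
bc = build_boundary_conditions((0, 0, -strain * height / 2),
                               (0, 0, +strain * height / 2),
                               "step1", specimen_height_mm=height)
sol = microfe.solve(mesh, bc, opts=microfe.SolverOptions(tolerance=1e-6))

print(f"mesh: {mesh.n_elements} hexahedra, {mesh.n_nodes} nodes, "
      f"{len(mesh.interface_faces)} bone-cement interface faces")
print(f"nominal strain:     {bc.nominal_strain:.1%}")
print(f"apparent stiffness: {sol.apparent_stiffness_n_per_mm:.2f} N/mm")
print(f"peak von Mises:     {sol.max_von_mises():.2f} MPa "
      "(end layers excluded)")
imbalance = np.abs(sol.reaction_top_n + sol.reaction_bottom_n).max()
print(f"force imbalance:    {imbalance:.2e} N")
print("(raw reaction sums inherit the iterative residual; the stiffness "
      "above uses the work identity, which converges much faster)")
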