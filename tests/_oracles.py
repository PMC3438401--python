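"""Independent measurement oracles shared across test modules."""

import numpy as np
from scipy import ndimage

from trabevalid.volume import BONE


def local_thickness_at_strut_midpoints(label, geom, params):
    """Distance-transform local-thickness oracle, sampled at the analytic
    strut midpoints (away from junctions): thickness ~ 2 * EDT."""
    vs = params.voxel_size_um * 1e-3
    edt = ndimage.distance_transform_edt(label.labels == BONE, sampling=vs)
    verts, edges = geom["vertices"], geom["edges"]
    nz, ny, nx = label.shape
    vals = []
    for (ia, ib), r in zip(edges, geom["radii_mm"]):
        mid = 0.5 * (verts[ia] + verts[ib])
        i, j, k = (int(np.floor(c / vs)) for c in mid)
        if not (0 <= i < nx and 0 <= j < ny and 0 <= k < nz):
            continue
        if label.labels[k, j, i] != BONE:
            continue
        # only count struts long enough that the midpoint clears junctions
        length = np.linalg.norm(verts[ib] - verts[ia])
        if length < 6 * r:
            continue
        vals.append(2.0 * edt[k, j, i])
    return np.array(vals)
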