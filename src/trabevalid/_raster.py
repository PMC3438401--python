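"""Numba kernel: rasterise deformed voxel hexahedra into a supersampled grid.

Each solid voxel of the source label volume is carried through its 8 nodal
displacements, decomposed into 6 tetrahedra around the main diagonal, and
every 2x-supersampled pixel centre of the target grid inside a tetrahedron
takes the element's class (priority by class code, cement over bone).
"""

from __future__ import annotations

import numba
import numpy as np

# hex corner offsets in (z, y, x), matching microfe.NODE_OFFSETS (x, y, z)
CORNER_ZYX = np.array([
    [0, 0, 0], [0, 0, 1], [0, 1, 1], [0, 1, 0],
    [1, 0, 0], [1, 0, 1], [1, 1, 1], [1, 1, 0],
], dtype=np.int64)

# 6-tetrahedron decomposition around the 0-6 diagonal
TETS = np.array([
    [0, 1, 2, 6], [0, 2, 3, 6], [0, 3, 7, 6],
    [0, 7, 4, 6], [0, 4, 5, 6], [0, 5, 1, 6],
], dtype=np.int64)


def _reference_signs() -> np.ndarray:
    """Sign of each tet's determinant on the undeformed unit cube."""
    signs = np.empty(len(TETS))
    corners = CORNER_ZYX.astype(np.float64)
    for t, tet in enumerate(TETS):
        a, b, c, d = corners[tet]
        signs[t] = np.sign(np.linalg.det(np.stack([b - a, c - a, d - a])))
    return signs


REF_SIGNS = _reference_signs()


@numba.njit(cache=True, nogil=True)
def rasterize_elements(node_pos, elems, cls, corner_zyx, tets, ref_signs, out):
    """Scatter element classes onto supersample centres; returns the number
    of inverted (negative-volume) tetrahedra encountered.

    node_pos: (nzn, nyn, nxn, 3) float32, displaced node positions in units
    of supersample cells, component order (z, y, x).
    elems: (E, 3) int32 voxel (k, j, i); cls: (E,) uint8 class codes;
    out: (2nz, 2ny, 2nx) uint8 supersample class grid (modified in place).
    """
    nzs, nys, nxs = out.shape
    eps = 1e-9
    inverted = 0
    cz = np.empty(8)
    cy = np.empty(8)
    cx = np.empty(8)
    for e in range(elems.shape[0]):
        k0, j0, i0 = elems[e, 0], elems[e, 1], elems[e, 2]
        for a in range(8):
            kk = k0 + corner_zyx[a, 0]
            jj = j0 + corner_zyx[a, 1]
            ii = i0 + corner_zyx[a, 2]
            cz[a] = node_pos[kk, jj, ii, 0]
            cy[a] = node_pos[kk, jj, ii, 1]
            cx[a] = node_pos[kk, jj, ii, 2]
        code = cls[e]
        for t in range(6):
            ia, ib, ic, id_ = tets[t, 0], tets[t, 1], tets[t, 2], tets[t, 3]
            az, ay, ax = cz[ia], cy[ia], cx[ia]
            e1z, e1y, e1x = cz[ib] - az, cy[ib] - ay, cx[ib] - ax
            e2z, e2y, e2x = cz[ic] - az, cy[ic] - ay, cx[ic] - ax
            e3z, e3y, e3x = cz[id_] - az, cy[id_] - ay, cx[id_] - ax
            det = (e1z * (e2y * e3x - e2x * e3y)
                   - e1y * (e2z * e3x - e2x * e3z)
                   + e1x * (e2z * e3y - e2y * e3z))
            if det * ref_signs[t] < 0:
                inverted += 1
            if abs(det) < 1e-30:
                continue
            # rows of the inverse edge matrix (Cramer)
            m00 = (e2y * e3x - e2x * e3y) / det
            m01 = -(e1y * e3x - e1x * e3y) / det
            m02 = (e1y * e2x - e1x * e2y) / det
            m10 = -(e2z * e3x - e2x * e3z) / det
            m11 = (e1z * e3x - e1x * e3z) / det
            m12 = -(e1z * e2x - e1x * e2z) / det
            m20 = (e2z * e3y - e2y * e3z) / det
            m21 = -(e1z * e3y - e1y * e3z) / det
            m22 = (e1z * e2y - e1y * e2z) / det

            zmin = min(min(cz[ia], cz[ib]), min(cz[ic], cz[id_]))
            zmax = max(max(cz[ia], cz[ib]), max(cz[ic], cz[id_]))
            ymin = min(min(cy[ia], cy[ib]), min(cy[ic], cy[id_]))
            ymax = max(max(cy[ia], cy[ib]), max(cy[ic], cy[id_]))
            xmin = min(min(cx[ia], cx[ib]), min(cx[ic], cx[id_]))
            xmax = max(max(cx[ia], cx[ib]), max(cx[ic], cx[id_]))
            kz0 = max(0, int(np.ceil(zmin - 0.5 - eps)))
            kz1 = min(nzs - 1, int(np.floor(zmax - 0.5 + eps)))
            jy0 = max(0, int(np.ceil(ymin - 0.5 - eps)))
            jy1 = min(nys - 1, int(np.floor(ymax - 0.5 + eps)))
            ix0 = max(0, int(np.ceil(xmin - 0.5 - eps)))
            ix1 = min(nxs - 1, int(np.floor(xmax - 0.5 + eps)))
            for kz in range(kz0, kz1 + 1):
                rz = kz + 0.5 - az
                for jy in range(jy0, jy1 + 1):
                    ry = jy + 0.5 - ay
                    for ix in range(ix0, ix1 + 1):
                        rx = ix + 0.5 - ax
                        # barycentric coordinates along the three edges
                        l1 = m00 * rz + m10 * ry + m20 * rx
                        if l1 < -eps:
                            continue
                        l2 = m01 * rz + m11 * ry + m21 * rx
                        if l2 < -eps:
                            continue
                        l3 = m02 * rz + m12 * ry + m22 * rx
                        if l3 < -eps or l1 + l2 + l3 > 1.0 + eps:
                            continue
                        if code > out[kz, jy, ix]:
                            out[kz, jy, ix] = code
    return inverted
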