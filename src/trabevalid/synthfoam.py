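"""Synthetic cement-augmented open-cell foam specimens and a uCT emulator.

The physical specimens this package targets are cylinders of open-cell rigid
polyurethane foam (a standard surrogate for osteoporotic trabecular bone:
porosity above 95%, cells 1.5-2.5 mm, struts 0.15-0.3 mm) whose ends are
embedded in PMMA bone cement to a depth of a few millimetres, imaged by
micro-CT at 25 um isotropic voxels.  No real scans ship with the package, so
this module builds label-volume ground truth for such specimens and emulates
their imaging, giving every downstream stage (segmentation, meshing, FE,
morphological validation) a closed loop to be tested against.

Foam topology is a Poisson-Voronoi strut lattice: seed points are scattered
with mean spacing proportional to the drawn cell size, the edges of the
Voronoi tessellation become struts, each dilated to its own radius drawn from
the strut-thickness range, and the network is clipped to the cylinder.  If
the rasterised solid fraction exceeds 5% of the cylinder interior, strut
radii are shrunk uniformly by bisection until the porosity bound holds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import Voronoi

from .volume import (BACKGROUND, BONE, CEMENT, MARKER, GrayscaleVolume,
                     LabelVolume)

# Poisson-Voronoi lattices carry considerably more edge length per unit
# volume than real reticulated foams of equal nominal cell size; seeds are
# therefore spaced SPACING_FACTOR * cell_size so the relative density stays
# below 5% across the supported cell-size / strut-thickness ranges.
SPACING_FACTOR = 1.5

POROSITY_FLOOR = 95.0  # percent, manufacturer-quoted bound enforced on output


class FoamParameterError(ValueError):
    """A foam parameter bound was violated."""


class FoamGeometryError(ValueError):
    """Requested specimen geometry is inconsistent (e.g. overlapping caps)."""


class MarkerPlacementError(ValueError):
    """A fiducial marker could not be placed."""


@dataclass
class FoamParams:
    """Geometry and sampling parameters of a synthetic foam specimen."""

    cylinder_diameter_mm: float = 6.0
    cylinder_height_mm: float = 12.0
    cell_size_range_mm: tuple[float, float] = (1.5, 2.5)
    strut_thickness_range_mm: tuple[float, float] = (0.15, 0.30)
    cement_cap_depth_range_mm: tuple[float, float] = (2.0, 4.0)
    voxel_size_um: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        lengths = (self.cylinder_diameter_mm, self.cylinder_height_mm,
                   self.voxel_size_um)
        if any(not np.isfinite(v) or v <= 0 for v in lengths):
            raise FoamParameterError("all lengths must be positive")
        for name in ("cell_size_range_mm", "strut_thickness_range_mm",
                     "cement_cap_depth_range_mm"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi) and name != "cement_cap_depth_range_mm":
                raise FoamParameterError(f"{name} must satisfy 0 < low <= high")
            if lo > hi or lo < 0:
                raise FoamParameterError(f"{name} must be ordered low <= high")
        if self.cylinder_diameter_mm * 1e3 / self.voxel_size_um < 50:
            raise FoamParameterError(
                "need at least 50 voxels across the cylinder diameter; "
                f"got {self.cylinder_diameter_mm * 1e3 / self.voxel_size_um:.1f}")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        vs = self.voxel_size_um * 1e-3
        n_xy = int(round(self.cylinder_diameter_mm / vs))
        n_z = int(round(self.cylinder_height_mm / vs))
        return (n_z, n_xy, n_xy)


@dataclass
class ImagingParams:
    """Grayscale model of the scanner: per-class mean/sd plus a Gaussian PSF.

    Defaults give the foam and cement overlapping grayscale distributions
    (separation comparable to a few noise standard deviations plus
    partial-volume blending), as seen on real PMMA-augmented specimens.
    """

    class_mean_gray: dict = field(default_factory=lambda: {
        BACKGROUND: 20.0, BONE: 105.0, CEMENT: 165.0, MARKER: 235.0})
    class_sd_gray: dict = field(default_factory=lambda: {
        BACKGROUND: 8.0, BONE: 12.0, CEMENT: 12.0, MARKER: 10.0})
    psf_sigma_um: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        m = self.class_mean_gray
        if not (m[BACKGROUND] < m[BONE] < m[CEMENT]):
            raise ValueError("class means must satisfy background < bone < cement")
        if any(sd < 0 for sd in self.class_sd_gray.values()):
            raise ValueError("class grayscale sd must be >= 0")
        if self.psf_sigma_um < 0:
            raise ValueError("psf_sigma_um must be >= 0")


def cylinder_mask(shape: tuple[int, int, int], voxel_size_um: float,
                  diameter_mm: float | None = None) -> np.ndarray:
    """Boolean mask of the cylindrical specimen interior.

    The cylinder axis runs along z through the centre of the x-y cross
    section; the diameter defaults to the full x extent of the grid.
    """
    nz, ny, nx = shape
    vs = voxel_size_um * 1e-3
    if diameter_mm is None:
        diameter_mm = nx * vs
    cx = nx * vs / 2.0
    cy = ny * vs / 2.0
    x = (np.arange(nx) + 0.5) * vs - cx
    y = (np.arange(ny) + 0.5) * vs - cy
    r2 = x[None, :] ** 2 + y[:, None] ** 2
    disk = r2 <= (diameter_mm / 2.0) ** 2
    return np.broadcast_to(disk, shape).copy()


def measure_porosity(label: LabelVolume,
                     diameter_mm: float | None = None) -> float:
    """Background fraction (percent) of the cylinder interior."""
    mask = cylinder_mask(label.shape, label.voxel_size_um, diameter_mm)
    inside = label.labels[mask]
    return 100.0 * float(np.count_nonzero(inside == BACKGROUND)) / inside.size


def foam_strut_geometry(params: FoamParams) -> dict:
    """Sample the analytic strut network (Voronoi edges + radii).

    Deterministic in ``params.seed``; :func:`generate_foam_lattice` rasterises
    exactly this geometry, so tests may use it as an independent record of
    where strut axes lie and how thick each strut was drawn.
    """
    rng = np.random.default_rng(params.seed)
    cell = rng.uniform(*params.cell_size_range_mm)
    spacing = SPACING_FACTOR * cell
    lam = 1.0 / spacing ** 3

    d, h = params.cylinder_diameter_mm, params.cylinder_height_mm
    pad = spacing
    lo = np.array([-pad, -pad, -pad])
    hi = np.array([d + pad, d + pad, h + pad])
    vol = np.prod(hi - lo)
    n_pts = max(int(rng.poisson(lam * vol)), 12)
    pts = rng.uniform(lo, hi, size=(n_pts, 3))

    vor = Voronoi(pts)
    edge_set = set()
    for ridge in vor.ridge_vertices:
        if -1 in ridge:
            continue
        m = len(ridge)
        for a in range(m):
            i, j = ridge[a], ridge[(a + 1) % m]
            edge_set.add((min(i, j), max(i, j)))
    edges = np.array(sorted(edge_set), dtype=np.int64)
    verts = vor.vertices
    t_lo, t_hi = params.strut_thickness_range_mm
    radii = rng.uniform(t_lo, t_hi, size=len(edges)) / 2.0
    return {"vertices": verts, "edges": edges, "radii_mm": radii,
            "cell_size_mm": cell, "n_seeds": n_pts}


def _clip_segment(p0, p1, lo, hi):
    """Clip segment p0->p1 to the axis-aligned box [lo, hi]; None if outside."""
    d = p1 - p0
    t0, t1 = 0.0, 1.0
    for ax in range(3):
        if abs(d[ax]) < 1e-300:
            if p0[ax] < lo[ax] or p0[ax] > hi[ax]:
                return None
            continue
        ta = (lo[ax] - p0[ax]) / d[ax]
        tb = (hi[ax] - p0[ax]) / d[ax]
        ta, tb = min(ta, tb), max(ta, tb)
        t0, t1 = max(t0, ta), min(t1, tb)
        if t0 > t1:
            return None
    return p0 + t0 * d, p0 + t1 * d


def _strut_ratio_field(params: FoamParams, geom: dict) -> np.ndarray:
    """Per-voxel min over struts of (distance to strut axis) / strut radius.

    Thresholding this field at a scale s yields the solid mask with all strut
    radii multiplied by s, which makes the porosity bisection a sequence of
    cheap threshold operations on one precomputed array.
    """
    shape = params.grid_shape
    nz, ny, nx = shape
    vs = params.voxel_size_um * 1e-3
    ratio = np.full(shape, np.inf, dtype=np.float32)

    box_lo = np.array([0.0, 0.0, 0.0])
    box_hi = np.array([nx * vs, ny * vs, nz * vs])
    verts, edges, radii = geom["vertices"], geom["edges"], geom["radii_mm"]
    margin = float(radii.max(initial=0.0)) + 2 * vs

    xc = (np.arange(nx) + 0.5) * vs
    yc = (np.arange(ny) + 0.5) * vs
    zc = (np.arange(nz) + 0.5) * vs

    for (ia, ib), r in zip(edges, radii):
        clipped = _clip_segment(verts[ia], verts[ib],
                                box_lo - margin, box_hi + margin)
        if clipped is None:
            continue
        p0, p1 = clipped
        lo_mm = np.minimum(p0, p1) - (r + vs)
        hi_mm = np.maximum(p0, p1) + (r + vs)
        i0 = max(int(np.floor(lo_mm[0] / vs - 0.5)), 0)
        i1 = min(int(np.ceil(hi_mm[0] / vs - 0.5)) + 1, nx)
        j0 = max(int(np.floor(lo_mm[1] / vs - 0.5)), 0)
        j1 = min(int(np.ceil(hi_mm[1] / vs - 0.5)) + 1, ny)
        k0 = max(int(np.floor(lo_mm[2] / vs - 0.5)), 0)
        k1 = min(int(np.ceil(hi_mm[2] / vs - 0.5)) + 1, nz)
        if i0 >= i1 or j0 >= j1 or k0 >= k1:
            continue
        dx = p1 - p0
        ll = float(dx @ dx)
        X = xc[i0:i1][None, None, :] - p0[0]
        Y = yc[j0:j1][None, :, None] - p0[1]
        Z = zc[k0:k1][:, None, None] - p0[2]
        if ll > 0:
            t = (X * dx[0] + Y * dx[1] + Z * dx[2]) / ll
            np.clip(t, 0.0, 1.0, out=t)
        else:
            t = 0.0
        d2 = (X - t * dx[0]) ** 2 + (Y - t * dx[1]) ** 2 + (Z - t * dx[2]) ** 2
        sub = ratio[k0:k1, j0:j1, i0:i1]
        np.minimum(sub, (np.sqrt(d2) / r).astype(np.float32), out=sub)
    return ratio


def _spanning_solid(solid: np.ndarray) -> np.ndarray:
    """Largest 26-connected solid component that touches both end planes."""
    structure = np.ones((3, 3, 3), dtype=bool)
    comp, n = ndimage.label(solid, structure=structure)
    if n == 0:
        raise FoamParameterError("foam lattice produced no solid voxels")
    bottom = np.unique(comp[0])
    top = np.unique(comp[-1])
    spanning = np.setdiff1d(np.intersect1d(bottom, top), [0])
    if spanning.size == 0:
        raise FoamParameterError(
            "no solid component spans both end planes; increase specimen "
            "height relative to cell size or re-seed")
    sizes = ndimage.sum_labels(solid, comp, spanning)
    keep = spanning[int(np.argmax(sizes))]
    return comp == keep


def generate_foam_lattice(params: FoamParams, return_geometry: bool = False):
    """Generate the cylindrical open-cell foam specimen as a label volume.

    The returned volume labels the strut network ``BONE`` inside the
    cylinder; the solid phase is a single 26-connected component touching
    both end planes and occupies less than 5% of the cylinder interior
    (porosity >= 95%), enforced by uniform bisection shrink of strut radii.
    """
    geom = foam_strut_geometry(params)
    ratio = _strut_ratio_field(params, geom)
    mask = cylinder_mask(params.grid_shape, params.voxel_size_um,
                         params.cylinder_diameter_mm)
    n_inside = int(np.count_nonzero(mask))
    vs = params.voxel_size_um * 1e-3

    def porosity_at(scale: float) -> float:
        solid = (ratio <= scale) & mask
        return 100.0 * (1.0 - np.count_nonzero(solid) / n_inside)

    scale = 1.0
    if porosity_at(scale) < POROSITY_FLOOR:
        # porosity is monotone decreasing in scale; find the largest scale
        # (up to a small guard band) that restores the bound
        lo_s, hi_s = 0.0, 1.0
        for _ in range(40):
            mid = 0.5 * (lo_s + hi_s)
            if porosity_at(mid) >= POROSITY_FLOOR + 0.05:
                lo_s = mid
            else:
                hi_s = mid
        scale = lo_s
        min_radius = float(geom["radii_mm"].min()) * scale
        if min_radius < vs:
            raise FoamParameterError(
                f"porosity floor of {POROSITY_FLOOR}% unreachable: shrinking "
                f"struts to radius {min_radius:.4f} mm would fall below one "
                f"voxel ({vs:.4f} mm)")

    solid = _spanning_solid((ratio <= scale) & mask)
    labels = np.zeros(params.grid_shape, dtype=np.uint8)
    labels[solid] = BONE
    out = LabelVolume(labels, params.voxel_size_um)
    if return_geometry:
        geom = dict(geom)
        geom["radius_scale"] = scale
        return out, geom
    return out


def add_cement_caps(label: LabelVolume, depth_top_mm: float,
                    depth_bottom_mm: float, seed: int = 0) -> LabelVolume:
    """Fill both specimen ends with cement to the given depths.

    Every non-bone voxel of the cylinder cross-section within the cap depth
    of an end plane becomes cement; bone voxels are retained, producing the
    interdigitated bone-cement composite.  ``seed`` is accepted for interface
    uniformity (cap surfaces are currently deterministic planes).
    """
    if depth_top_mm < 0 or depth_bottom_mm < 0:
        raise FoamGeometryError("cap depths must be >= 0")
    nz = label.shape[0]
    height = nz * label.voxel_size_mm
    if depth_top_mm + depth_bottom_mm >= height and (depth_top_mm or depth_bottom_mm):
        raise FoamGeometryError(
            f"cap depths {depth_top_mm}+{depth_bottom_mm} mm overlap on a "
            f"{height:.2f} mm specimen")
    out = label.copy()
    mask = cylinder_mask(label.shape, label.voxel_size_um)
    zc = (np.arange(nz) + 0.5) * label.voxel_size_mm
    in_cap = (zc < depth_bottom_mm) | (zc > height - depth_top_mm)
    cap_region = mask & in_cap[:, None, None]
    fill = cap_region & (out.labels != BONE)
    out.labels[fill] = CEMENT
    return out


def embed_markers(label: LabelVolume, positions_mm,
                  radius_voxels: int = 3) -> LabelVolume:
    """Write small spherical fiducial markers (code 3) at the given points."""
    out = label.copy()
    if len(positions_mm) == 0:
        return out
    nz, ny, nx = label.shape
    vs = label.voxel_size_mm
    rv = int(radius_voxels)
    off = np.arange(-rv, rv + 1)
    dz, dy, dx = np.meshgrid(off, off, off, indexing="ij")
    ball = dz ** 2 + dy ** 2 + dx ** 2 <= rv ** 2
    for p, pos in enumerate(positions_mm):
        x, y, z = pos
        # containing voxel; epsilon breaks exact-boundary ties upward so the
        # placement is stable against float division noise
        eps = 1e-9 * vs
        i = int(np.floor((x + eps) / vs))
        j = int(np.floor((y + eps) / vs))
        k = int(np.floor((z + eps) / vs))
        if not (rv <= i < nx - rv and rv <= j < ny - rv and rv <= k < nz - rv):
            raise MarkerPlacementError(
                f"marker {p} at {tuple(pos)} mm does not fit inside the volume")
        sub = out.labels[k - rv:k + rv + 1, j - rv:j + rv + 1, i - rv:i + rv + 1]
        if np.any(sub[ball] == MARKER):
            raise MarkerPlacementError(
                f"marker {p} at {tuple(pos)} mm overlaps an existing marker")
        sub[ball] = MARKER
    return out


def emulate_uct(label: LabelVolume, imaging: ImagingParams) -> GrayscaleVolume:
    """Image a label volume: class means, Gaussian PSF blur, then class noise."""
    mean_lut = np.zeros(MARKER + 1, dtype=np.float32)
    sd_lut = np.zeros(MARKER + 1, dtype=np.float32)
    for code in range(MARKER + 1):
        mean_lut[code] = imaging.class_mean_gray.get(code, 0.0)
        sd_lut[code] = imaging.class_sd_gray.get(code, 0.0)
    img = mean_lut[label.labels]
    sigma_vox = imaging.psf_sigma_um / label.voxel_size_um
    if sigma_vox > 0:
        img = ndimage.gaussian_filter(img, sigma_vox)
    rng = np.random.default_rng(imaging.seed)
    noise = rng.standard_normal(label.shape).astype(np.float32)
    img = img + noise * sd_lut[label.labels]
    return GrayscaleVolume(img, label.voxel_size_um, label.origin_mm)


def synthesize_loaded_scan(label: LabelVolume, displacement_field: np.ndarray,
                           imaging: ImagingParams) -> GrayscaleVolume:
    """Emulate a scan of the specimen deformed through a nodal field.

    ``displacement_field`` has shape ``(nz+1, ny+1, nx+1, 3)`` — an (x, y, z)
    mm displacement at every node (voxel corner) of the label grid.  The
    labels are warped through the field at the native resolution and then
    imaged; with a zero field and the same imaging seed the result is
    bit-identical to :func:`emulate_uct` of the unloaded labels.
    """
    from . import morphval  # local import to avoid a cycle

    nz, ny, nx = label.shape
    expect = (nz + 1, ny + 1, nx + 1, 3)
    if tuple(displacement_field.shape) != expect:
        raise ValueError(
            f"displacement field shape {displacement_field.shape} does not "
            f"match the label node grid {expect}")
    warped = morphval.warp_labels(label, displacement_field,
                                  target_voxel_size_um=label.voxel_size_um)
    return emulate_uct(warped, imaging)
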