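"""Deformed-morphology validation: rasterise the FE-predicted geometry back
into image space and score it against loaded-state scans pixel by pixel.

The validation metric works on vertical (sagittal) slices at three stations
distributed across the specimen, located by small fiducial markers (or by
fractional defaults).  Within the registered region of each slice, a pixel
that the model predicts solid (bone or cement) while the scan shows
background is a *false positive*; background in the model but solid in the
scan is a *false negative*; the total error is their sum as a fraction of the
scan's solid pixel count.  Applied to the unloaded state the same metric
calibrates the baseline error contributed by segmentation and meshing alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from ._raster import CORNER_ZYX, REF_SIGNS, TETS, rasterize_elements
from .volume import BACKGROUND, BONE, CEMENT, MARKER, LabelVolume


class SlicePlanError(ValueError):
    """Cannot determine the three comparison stations."""


@dataclass
class SlicePlan:
    """Three sagittal (fixed-x) slice stations for morphology comparison."""

    stations_x_mm: tuple[float, float, float]
    axis: str = "sagittal"

    def __post_init__(self) -> None:
        if len(self.stations_x_mm) != 3:
            raise SlicePlanError("exactly 3 slice stations are required")
        self.stations_x_mm = tuple(float(v) for v in self.stations_x_mm)


@dataclass
class MorphologyComparison:
    """Pixel counts and percentages of one slice comparison."""

    match_solid: int
    false_positive: int
    false_negative: int
    denominator: int
    increment: str = "initial"
    station_x_mm: float = float("nan")

    @property
    def fp_pct(self) -> float:
        return 100.0 * self.false_positive / self.denominator

    @property
    def fn_pct(self) -> float:
        return 100.0 * self.false_negative / self.denominator

    @property
    def total_error_pct(self) -> float:
        return self.fp_pct + self.fn_pct


# ---------------------------------------------------------------------------
# deformed-geometry rasterisation

def warp_labels(label: LabelVolume, displacements: np.ndarray,
                target_voxel_size_um: float | None = None) -> LabelVolume:
    """Carry every solid voxel through its 8 nodal displacements and
    rasterise into a (possibly finer) target grid.

    ``displacements``: (nz+1, ny+1, nx+1, 3) array of (x, y, z) mm nodal
    displacements on the label grid's node lattice.  Each deformed voxel
    hexahedron is split into 6 tetrahedra and sampled at 2x supersampled
    target pixel centres; overlaps resolve by class priority (marker >
    cement > bone).  The output grid covers the deformed bounding box and
    stays aligned with the input origin, so a zero field at equal resolution
    reproduces the input exactly.
    """
    nz, ny, nx = label.shape
    if displacements.shape != (nz + 1, ny + 1, nx + 1, 3):
        raise ValueError(
            f"displacement field shape {displacements.shape} does not match "
            f"node grid {(nz + 1, ny + 1, nx + 1, 3)}")
    vs_src = label.voxel_size_mm
    if target_voxel_size_um is None:
        target_voxel_size_um = label.voxel_size_um
    vs_tgt = target_voxel_size_um * 1e-3
    if vs_tgt > vs_src * (1 + 1e-9):
        raise ValueError("target resolution must be <= source resolution")

    ox, oy, oz = label.origin_mm
    # displaced node positions, component order (z, y, x), in mm
    kk, jj, ii = np.meshgrid(np.arange(nz + 1), np.arange(ny + 1),
                             np.arange(nx + 1), indexing="ij")
    pos = np.empty((nz + 1, ny + 1, nx + 1, 3), dtype=np.float64)
    pos[..., 0] = oz + kk * vs_src + displacements[..., 2]
    pos[..., 1] = oy + jj * vs_src + displacements[..., 1]
    pos[..., 2] = ox + ii * vs_src + displacements[..., 0]

    lo = pos.reshape(-1, 3).min(axis=0)   # (z, y, x) mm
    hi = pos.reshape(-1, 3).max(axis=0)
    origin_zyx = np.array([oz, oy, ox])
    start = np.floor((lo - origin_zyx) / vs_tgt + 1e-9).astype(np.int64)
    out_origin = origin_zyx + start * vs_tgt
    n_out = np.ceil((hi - out_origin) / vs_tgt - 1e-9).astype(np.int64)
    n_out = np.maximum(n_out, 1)

    # node positions in supersample-cell units relative to the output grid
    half = vs_tgt / 2.0
    pos32 = ((pos - out_origin) / half).astype(np.float32)

    elems = np.argwhere(label.labels != BACKGROUND).astype(np.int32)
    cls = label.labels[elems[:, 0], elems[:, 1], elems[:, 2]].astype(np.uint8)
    samples = np.zeros((2 * n_out[0], 2 * n_out[1], 2 * n_out[2]),
                       dtype=np.uint8)
    inverted = 0
    chunk = 500_000
    for s in range(0, len(elems), chunk):
        inverted += rasterize_elements(pos32, elems[s:s + chunk],
                                       cls[s:s + chunk], CORNER_ZYX, TETS,
                                       REF_SIGNS, samples)
    if inverted:
        warnings.warn(f"{inverted} inverted tetrahedra during rasterisation "
                      "(excessive element distortion)", stacklevel=2)

    # fold 2x2x2 supersamples into voxel labels: solid when at least half the
    # samples are solid; class by majority, ties to the higher code
    blocks = samples.reshape(n_out[0], 2, n_out[1], 2, n_out[2], 2)
    counts = np.stack([(blocks == c).sum(axis=(1, 3, 5))
                       for c in (BONE, CEMENT, MARKER)])
    n_solid = counts.sum(axis=0)
    # reversed argmax so that ties resolve to the higher class code
    winner = 3 - np.argmax(counts[::-1], axis=0).astype(np.uint8)
    labels = np.where(n_solid >= 4, winner, BACKGROUND).astype(np.uint8)
    return LabelVolume(labels, target_voxel_size_um,
                       (out_origin[2], out_origin[1], out_origin[0]))


def uniform_strain_field(node_grid_shape, voxel_size_um: float,
                         strain_z: float, lateral_ratio: float = 0.0,
                         translation_mm=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Scripted nodal field: uniform axial compression about the specimen
    centre (positive ``strain_z`` shortens), optional lateral expansion and
    rigid translation.  Shape: node grid + (3,) with (x, y, z) components."""
    nzn, nyn, nxn = node_grid_shape
    vs = voxel_size_um * 1e-3
    z = np.arange(nzn) * vs
    y = np.arange(nyn) * vs
    x = np.arange(nxn) * vs
    zc, yc, xc = z.mean(), y.mean(), x.mean()
    field = np.empty(tuple(node_grid_shape) + (3,), dtype=np.float64)
    field[..., 0] = (lateral_ratio * strain_z * (x - xc))[None, None, :] \
        + translation_mm[0]
    field[..., 1] = (lateral_ratio * strain_z * (y - yc))[None, :, None] \
        + translation_mm[1]
    field[..., 2] = (-strain_z * (z - zc))[:, None, None] + translation_mm[2]
    return field


def resample_field(field: np.ndarray, src_voxel_size_um: float,
                   dst_node_shape, dst_voxel_size_um: float) -> np.ndarray:
    """Trilinearly interpolate a nodal field onto another node grid sharing
    the same origin (e.g. 50 um FE nodes -> 25 um image nodes)."""
    ratio = dst_voxel_size_um / src_voxel_size_um
    nzd, nyd, nxd = dst_node_shape
    zi = np.arange(nzd) * ratio
    yi = np.arange(nyd) * ratio
    xi = np.arange(nxd) * ratio
    zz, yy, xx = np.meshgrid(zi, yi, xi, indexing="ij")
    out = np.empty((nzd, nyd, nxd, 3), dtype=np.float64)
    for c in range(3):
        out[..., c] = ndimage.map_coordinates(
            field[..., c], [zz, yy, xx], order=1, mode="nearest")
    return out


# ---------------------------------------------------------------------------
# slice plan and metric

def slice_plan(markers: LabelVolume | None = None,
               stations_mm=None) -> SlicePlan:
    """Three sagittal stations: explicit, marker-derived, or fractional.

    With a label volume containing exactly three markers the stations are
    the marker centroids' x coordinates; a volume with no markers falls back
    to 25/50/75% of the specimen width; any other marker count is an error.
    """
    if stations_mm is not None:
        return SlicePlan(tuple(stations_mm))
    if markers is None:
        raise SlicePlanError("need either explicit stations or a label volume")
    mk = markers.labels == MARKER
    comp, n = ndimage.label(mk, structure=np.ones((3, 3, 3), bool))
    nx = markers.shape[2]
    if n == 0:
        w = nx * markers.voxel_size_mm
        return SlicePlan(tuple(markers.origin_mm[0] + w * f
                               for f in (0.25, 0.50, 0.75)))
    if n != 3:
        raise SlicePlanError(f"expected exactly 3 markers, found {n}")
    centroids = ndimage.center_of_mass(mk, comp, [1, 2, 3])
    xs = sorted(markers.origin_mm[0] + (c[2] + 0.5) * markers.voxel_size_mm
                for c in centroids)
    return SlicePlan(tuple(xs))


def extract_slice(label: LabelVolume, station_x_mm: float) -> np.ndarray:
    """The 2D (z, y) label slice at the voxel plane nearest a station."""
    ix = int(round((station_x_mm - label.origin_mm[0]) / label.voxel_size_mm - 0.5))
    ix = min(max(ix, 0), label.shape[2] - 1)
    return label.labels[:, :, ix]


def compare_slices(fe_slice: np.ndarray, uct_slice: np.ndarray,
                   region: np.ndarray | None = None,
                   increment: str = "initial",
                   station_x_mm: float = float("nan")) -> MorphologyComparison:
    """Score one FE-predicted slice against the corresponding scan slice.

    Marker pixels (in either image) are excluded from all counts.  The
    denominator is the scan's solid (bone+cement) pixel count within the
    region, so errors are expressed relative to the observed structure.
    """
    fe_slice = np.asarray(fe_slice)
    uct_slice = np.asarray(uct_slice)
    if fe_slice.shape != uct_slice.shape:
        raise ValueError(f"slice grids differ: {fe_slice.shape} vs "
                         f"{uct_slice.shape}")
    if region is None:
        region = np.ones(fe_slice.shape, dtype=bool)
    elif region.shape != fe_slice.shape:
        raise ValueError("region mask shape does not match the slices")
    region = region & (fe_slice != MARKER) & (uct_slice != MARKER)

    fe_solid = ((fe_slice == BONE) | (fe_slice == CEMENT)) & region
    uct_solid = ((uct_slice == BONE) | (uct_slice == CEMENT)) & region
    match = int(np.count_nonzero(fe_solid & uct_solid))
    fp = int(np.count_nonzero(fe_solid & ~uct_solid))
    fn = int(np.count_nonzero(~fe_solid & uct_solid))
    denom = int(np.count_nonzero(uct_solid))
    if denom == 0:
        raise ValueError("scan slice has no solid pixels in the region; "
                         "cannot normalise the error")
    return MorphologyComparison(match, fp, fn, denom, increment, station_x_mm)


def aggregate(records, group_by: str = "increment") -> pd.DataFrame:
    """Mean and SD of FP/FN/total-error percentages per load increment."""
    records = list(records)
    if not records:
        raise ValueError("no comparison records to aggregate")
    df = pd.DataFrame([{
        "increment": r.increment,
        "station_x_mm": r.station_x_mm,
        "fp_pct": r.fp_pct,
        "fn_pct": r.fn_pct,
        "total_pct": r.total_error_pct,
    } for r in records])
    agg = df.groupby(group_by, sort=False).agg(
        fp_mean=("fp_pct", "mean"), fp_sd=("fp_pct", "std"),
        fn_mean=("fn_pct", "mean"), fn_sd=("fn_pct", "std"),
        total_mean=("total_pct", "mean"), total_sd=("total_pct", "std"),
        n=("total_pct", "size"),
    ).reset_index()
    return agg.fillna({"fp_sd": 0.0, "fn_sd": 0.0, "total_sd": 0.0})


def calibrate_unloaded(fe_slices, uct_slices, regions=None,
                       stations_x_mm=None) -> list[MorphologyComparison]:
    """Baseline (unloaded) comparison: the error attributable to model
    generation alone, reported alongside loaded-state errors."""
    fe_slices = list(fe_slices)
    uct_slices = list(uct_slices)
    if len(fe_slices) != len(uct_slices):
        raise ValueError("slice lists differ in length")
    regions = regions or [None] * len(fe_slices)
    stations = stations_x_mm or [float("nan")] * len(fe_slices)
    return [compare_slices(f, u, region=r, increment="initial", station_x_mm=s)
            for f, u, r, s in zip(fe_slices, uct_slices, regions, stations)]


def overlay_rgb(fe_slice: np.ndarray, uct_slice: np.ndarray) -> np.ndarray:
    """RGB visualisation: green = match, red = false positive, blue = false
    negative, black elsewhere (marker pixels left black)."""
    fe_solid = (fe_slice == BONE) | (fe_slice == CEMENT)
    uct_solid = (uct_slice == BONE) | (uct_slice == CEMENT)
    marker = (fe_slice == MARKER) | (uct_slice == MARKER)
    img = np.zeros(fe_slice.shape + (3,), dtype=np.uint8)
    img[fe_solid & uct_solid & ~marker] = (0, 200, 0)
    img[fe_solid & ~uct_solid & ~marker] = (220, 0, 0)
    img[~fe_solid & uct_solid & ~marker] = (0, 0, 220)
    return img
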