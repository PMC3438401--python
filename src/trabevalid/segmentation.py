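"""Two-threshold segmentation of grayscale scans into background/bone/cement.

The physical specimens contain two solid phases whose grayscale
distributions overlap (foam struts and the much stiffer PMMA cement), plus
air background.  Segmentation is a straight two-threshold classification —
an automated surrogate for the visual threshold selection an operator would
perform on the pre-loaded scan — followed by a connectivity filter that
removes small disconnected solid islands, standing in for manual slice-wise
clean-up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_multiotsu

from .volume import BACKGROUND, BONE, CEMENT, MARKER, GrayscaleVolume, LabelVolume


class ThresholdError(ValueError):
    """Automatic threshold selection failed (degenerate histogram)."""


class ConnectivityError(ValueError):
    """Connectivity filtering would discard an implausible solid fraction."""


@dataclass(frozen=True)
class SegmentationThresholds:
    """The two class boundaries: below t_bone is background, above t_cement
    is cement, in between is bone.  Intensity equal to a threshold goes to
    the upper class."""

    t_bone: float
    t_cement: float

    def __post_init__(self) -> None:
        if not self.t_bone < self.t_cement:
            raise ValueError(
                f"require t_bone < t_cement, got {self.t_bone} >= {self.t_cement}")


def auto_thresholds(volume: GrayscaleVolume, nbins: int = 256) -> SegmentationThresholds:
    """Choose the two thresholds by three-class Otsu (between-class variance
    maximisation over the intensity histogram).  Always overridable."""
    data = np.asarray(volume.data)
    if float(data.max()) == float(data.min()):
        raise ThresholdError("constant image: no histogram modes to separate")
    try:
        t_bone, t_cement = threshold_multiotsu(data, classes=3, nbins=nbins)
    except ValueError as exc:  # fewer distinct values than classes
        raise ThresholdError(f"histogram too degenerate for 3 classes: {exc}")
    return SegmentationThresholds(float(t_bone), float(t_cement))


def segment(volume: GrayscaleVolume, thresholds: SegmentationThresholds,
            marker_mask: np.ndarray | None = None) -> LabelVolume:
    """Classify every voxel by the two thresholds.

    ``marker_mask`` (optional boolean array) re-codes fiducial-marker voxels
    to the marker label after classification so they can be excluded from
    material assignment and from validation counts.
    """
    data = np.asarray(volume.data)
    labels = np.full(data.shape, BACKGROUND, dtype=np.uint8)
    labels[data >= thresholds.t_bone] = BONE
    labels[data >= thresholds.t_cement] = CEMENT
    if marker_mask is not None:
        if marker_mask.shape != data.shape:
            raise ValueError("marker mask shape does not match the volume")
        labels[marker_mask] = MARKER
    return LabelVolume(labels, volume.voxel_size_um, volume.origin_mm)


def connectivity_filter(label: LabelVolume, min_component_voxels: int,
                        max_removed_fraction: float = 0.20):
    """Drop solid (bone|cement, 26-connectivity) components smaller than
    ``min_component_voxels``; returns ``(filtered, report)``.

    Removing more than ``max_removed_fraction`` of the solid volume raises —
    that regime signals badly chosen thresholds rather than specks.
    """
    solid = label.solid_mask()
    structure = np.ones((3, 3, 3), dtype=bool)
    comp, n = ndimage.label(solid, structure=structure)
    removed_sizes: list[int] = []
    out = label.copy()
    if n:
        sizes = np.bincount(comp.ravel())[1:]  # component ids 1..n
        small = np.flatnonzero(sizes < min_component_voxels) + 1
        removed_sizes = sorted((int(sizes[i - 1]) for i in small), reverse=True)
        total_solid = int(solid.sum())
        n_removed = int(sum(removed_sizes))
        if total_solid and n_removed > max_removed_fraction * total_solid:
            raise ConnectivityError(
                f"connectivity filter would remove {n_removed} of "
                f"{total_solid} solid voxels "
                f"({100 * n_removed / total_solid:.1f}%); thresholds are "
                "likely misplaced")
        if small.size:
            out.labels[np.isin(comp, small)] = BACKGROUND
    report = {"n_components": int(n),
              "n_removed": len(removed_sizes),
              "removed_sizes": removed_sizes,
              "removed_voxels": int(sum(removed_sizes))}
    return out, report


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two boolean masks (1.0 when both are empty)."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.count_nonzero(a & b) / float(denom)
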