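"""Core image containers shared by every stage of the pipeline.

Arrays are indexed ``[z, y, x]`` with z the loading axis.  World coordinates
are millimetres in ``(x, y, z)`` order; the centre of voxel ``(k, j, i)`` sits
at ``origin + (index + 0.5) * voxel_size`` along each axis, and grid *nodes*
(voxel corners) sit at ``origin + index * voxel_size``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Label codes used throughout the package.
BACKGROUND = 0
BONE = 1
CEMENT = 2
MARKER = 3

LABEL_CODES = (BACKGROUND, BONE, CEMENT, MARKER)
SOLID_CODES = (BONE, CEMENT)


def _check_voxel_size(voxel_size_um: float) -> None:
    if not np.isfinite(voxel_size_um) or voxel_size_um <= 0:
        raise ValueError(f"voxel_size_um must be positive, got {voxel_size_um!r}")


@dataclass
class GrayscaleVolume:
    """A 3D scalar image with isotropic voxels (the uCT surrogate)."""

    data: np.ndarray  # (nz, ny, nx) float or integer intensities
    voxel_size_um: float
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)  # (x, y, z)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.size == 0:
            raise ValueError("intensity grid must be a non-empty 3D array")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensities must be finite")
        _check_voxel_size(self.voxel_size_um)
        self.origin_mm = tuple(float(v) for v in self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_size_mm(self) -> float:
        return self.voxel_size_um * 1e-3

    def copy(self) -> "GrayscaleVolume":
        return replace(self, data=self.data.copy())


@dataclass
class LabelVolume:
    """Per-voxel class map: background / bone / cement / marker."""

    labels: np.ndarray  # (nz, ny, nx) small integers
    voxel_size_um: float
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3 or self.labels.size == 0:
            raise ValueError("label grid must be a non-empty 3D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer typed")
        if self.labels.min() < BACKGROUND or self.labels.max() > MARKER:
            raise ValueError(f"label codes must lie in {LABEL_CODES}")
        _check_voxel_size(self.voxel_size_um)
        self.origin_mm = tuple(float(v) for v in self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_size_mm(self) -> float:
        return self.voxel_size_um * 1e-3

    def solid_mask(self) -> np.ndarray:
        """Boolean mask of bone-or-cement voxels (markers excluded)."""
        return (self.labels == BONE) | (self.labels == CEMENT)

    def copy(self) -> "LabelVolume":
        return replace(self, labels=self.labels.copy())


def voxel_centers_mm(shape: tuple[int, int, int], voxel_size_um: float,
                     origin_mm=(0.0, 0.0, 0.0)):
    """1D coordinate arrays (x_mm, y_mm, z_mm) of voxel centres."""
    vs = voxel_size_um * 1e-3
    nz, ny, nx = shape
    x = origin_mm[0] + (np.arange(nx) + 0.5) * vs
    y = origin_mm[1] + (np.arange(ny) + 0.5) * vs
    z = origin_mm[2] + (np.arange(nz) + 0.5) * vs
    return x, y, z


def world_to_index(point_mm, voxel_size_um: float, origin_mm=(0.0, 0.0, 0.0)):
    """Map a world point (x, y, z) mm to the (k, j, i) voxel containing it."""
    vs = voxel_size_um * 1e-3
    x, y, z = point_mm
    i = int(np.floor((x - origin_mm[0]) / vs))
    j = int(np.floor((y - origin_mm[1]) / vs))
    k = int(np.floor((z - origin_mm[2]) / vs))
    return k, j, i
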