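"""Boundary displacements from landmark points on unloaded vs loaded images.

In the physical experiment the specimen ends are compressed inside the
scanner; the displacement actually delivered to each end is measured by
recording the coordinates of a handful of identifiable points on the top and
bottom surfaces in the unloaded scan and again at each load increment, and
averaging the differences.  At least five points per end are required, and
the estimator is exactly the componentwise sample mean of (loaded - ref).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

MIN_POINTS = 5


class LandmarkError(ValueError):
    """Landmark sets unsuitable for displacement estimation."""


@dataclass
class LandmarkSet:
    """Corresponding points (mm, relative to a fixed image frame) on one
    specimen end in one load state; correspondence is by index."""

    end: str                      # "top" | "bottom"
    points_mm: np.ndarray         # (n, 3) (x, y, z)
    state: str = "ref"            # load increment id

    def __post_init__(self) -> None:
        if self.end not in ("top", "bottom"):
            raise LandmarkError(f"end must be 'top' or 'bottom', got {self.end!r}")
        self.points_mm = np.atleast_2d(np.asarray(self.points_mm, dtype=float))
        if self.points_mm.ndim != 2 or self.points_mm.shape[1] != 3:
            raise LandmarkError("points must be an (n, 3) array of mm triplets")
        if not np.all(np.isfinite(self.points_mm)):
            raise LandmarkError("landmark coordinates must be finite")

    def __len__(self) -> int:
        return len(self.points_mm)


@dataclass
class BoundaryConditions:
    """Per-increment rigid end displacements applied to the FE model."""

    increment: str
    u_top_mm: np.ndarray     # (3,) (x, y, z)
    u_bottom_mm: np.ndarray  # (3,)
    nominal_strain: float = 0.0

    def __post_init__(self) -> None:
        self.u_top_mm = np.asarray(self.u_top_mm, dtype=float).reshape(3)
        self.u_bottom_mm = np.asarray(self.u_bottom_mm, dtype=float).reshape(3)
        if not (np.all(np.isfinite(self.u_top_mm))
                and np.all(np.isfinite(self.u_bottom_mm))):
            raise ValueError("boundary displacements must be finite")
        zt, zb = self.u_top_mm[2], self.u_bottom_mm[2]
        # compression toward the centre: axial components oppose, or one is 0
        if zt * zb > 0:
            raise ValueError(
                f"axial end displacements must oppose (or one be zero); got "
                f"u_top_z={zt}, u_bottom_z={zb}")

    def to_json(self) -> str:
        return json.dumps({
            "increment": self.increment,
            "u_top_mm": self.u_top_mm.tolist(),
            "u_bottom_mm": self.u_bottom_mm.tolist(),
            "nominal_strain": self.nominal_strain,
        }, indent=1)


def compute_end_displacements(ref: LandmarkSet, loaded: LandmarkSet) -> np.ndarray:
    """Componentwise mean of (loaded - ref) over corresponding points (mm)."""
    if ref.end != loaded.end:
        raise LandmarkError(f"landmark ends differ: {ref.end!r} vs {loaded.end!r}")
    if len(ref) != len(loaded):
        raise LandmarkError(
            f"point correspondence broken: {len(ref)} reference vs "
            f"{len(loaded)} loaded points")
    if len(ref) < MIN_POINTS:
        raise LandmarkError(
            f"need at least {MIN_POINTS} points per end, got {len(ref)}")
    return (loaded.points_mm - ref.points_mm).mean(axis=0)


def build_boundary_conditions(u_top_mm, u_bottom_mm, increment: str,
                              specimen_height_mm: float | None = None
                              ) -> BoundaryConditions:
    """Package per-end displacement vectors; records the nominal strain
    (|u_top,z| + |u_bottom,z|) / height when the height is given."""
    bc = BoundaryConditions(increment, u_top_mm, u_bottom_mm)
    if specimen_height_mm:
        bc.nominal_strain = float(
            (abs(bc.u_top_mm[2]) + abs(bc.u_bottom_mm[2])) / specimen_height_mm)
    if np.allclose(bc.u_top_mm, 0) and np.allclose(bc.u_bottom_mm, 0) \
            and increment not in ("ref", "initial", "0"):
        import warnings
        warnings.warn(f"increment {increment!r} has zero displacement at both "
                      "ends", stacklevel=2)
    return bc


def write_landmarks_csv(path, sets: list[LandmarkSet]) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["end", "state", "x_mm", "y_mm", "z_mm"])
        for s in sets:
            for p in s.points_mm:
                w.writerow([s.end, s.state, *(f"{v:.6f}" for v in p)])


def read_landmarks_csv(path) -> list[LandmarkSet]:
    groups: dict[tuple[str, str], list] = {}
    with Path(path).open() as fh:
        for row in csv.DictReader(fh):
            key = (row["end"], row["state"])
            groups.setdefault(key, []).append(
                [float(row["x_mm"]), float(row["y_mm"]), float(row["z_mm"])])
    return [LandmarkSet(end, np.array(pts), state)
            for (end, state), pts in groups.items()]
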