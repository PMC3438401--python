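"""Reading/writing image stacks and the grayscale preprocessing steps.

Supported formats: multipage TIFF stacks (via tifffile), NRRD and MetaImage
(MHD/RAW, via SimpleITK).  Voxel size and origin travel in a JSON sidecar
(``<file>.json`` with keys ``voxel_size_um``, ``origin_mm``, ``axis_order``)
so that TIFF stacks, which carry no calibrated spacing, round-trip exactly;
for NRRD/MetaImage the spacing is additionally stored in the native header.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import tifffile
import SimpleITK as sitk

from .volume import GrayscaleVolume, LabelVolume

log = logging.getLogger(__name__)

FORMATS = ("tiff", "nrrd", "mha")


class FormatError(ValueError):
    """Malformed or inconsistent image file."""


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _write_sidecar(path: Path, voxel_size_um: float, origin_mm) -> None:
    meta = {"voxel_size_um": float(voxel_size_um),
            "origin_mm": [float(v) for v in origin_mm],
            "axis_order": "zyx"}
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt in ("tif", "tiff"):
            return "tiff"
        if fmt not in FORMATS:
            raise FormatError(f"unknown format {fmt!r}; supported: {FORMATS}")
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        return "tiff"
    if suffix == ".nrrd":
        return "nrrd"
    if suffix in (".mha", ".mhd"):
        return "mha"
    raise FormatError(f"cannot infer format from suffix {suffix!r}")


def write_stack(volume, path, fmt: str | None = None) -> Path:
    """Write a grayscale or label volume; returns the written path.

    Intensities round-trip bit-exactly for integer dtypes and float32.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    data = volume.data if isinstance(volume, GrayscaleVolume) else volume.labels
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "tiff":
        tifffile.imwrite(path, data)
    else:
        img = sitk.GetImageFromArray(data)
        vs_mm = volume.voxel_size_um * 1e-3
        img.SetSpacing((vs_mm, vs_mm, vs_mm))
        img.SetOrigin(tuple(float(v) for v in volume.origin_mm))
        sitk.WriteImage(img, str(path))
    _write_sidecar(path, volume.voxel_size_um, volume.origin_mm)
    return path


def read_stack(path, fmt: str | None = None, voxel_size_um: float | None = None,
               as_labels: bool = False):
    """Read an image stack into a :class:`GrayscaleVolume` (or LabelVolume).

    Voxel size is taken from the JSON sidecar when present, else from the
    native header (NRRD/MetaImage), else from ``voxel_size_um``; a TIFF stack
    without sidecar and without an explicit voxel size is an error after a
    warning, since downstream geometry would be meaningless.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    origin = (0.0, 0.0, 0.0)
    native_vs = None
    if fmt == "tiff":
        with tifffile.TiffFile(path) as tf:
            shapes = {page.shape for page in tf.pages}
            if len(shapes) > 1:
                raise FormatError(
                    f"inconsistent slice dimensions in TIFF stack: {sorted(shapes)}")
            data = tf.asarray()
        if data.ndim == 2:
            data = data[None]
    else:
        img = sitk.ReadImage(str(path))
        data = sitk.GetArrayFromImage(img)
        sp = img.GetSpacing()
        if max(sp) - min(sp) > 1e-9 * max(sp):
            raise FormatError(f"anisotropic voxels unsupported: spacing {sp}")
        native_vs = sp[0] * 1e3
        origin = tuple(img.GetOrigin())
        if data.ndim == 2:
            data = data[None]

    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        vs = float(meta["voxel_size_um"])
        origin = tuple(meta.get("origin_mm", origin))
    elif native_vs is not None:
        vs = native_vs
    elif voxel_size_um is not None:
        vs = float(voxel_size_um)
    else:
        warnings.warn(f"{path}: no voxel-size metadata; pass voxel_size_um "
                      "explicitly", stacklevel=2)
        raise FormatError(f"{path}: missing voxel-size metadata")
    if voxel_size_um is not None:
        vs = float(voxel_size_um)

    if as_labels:
        return LabelVolume(data, vs, origin)
    return GrayscaleVolume(data, vs, origin)


def downsample_mean(volume: GrayscaleVolume, factor: int) -> GrayscaleVolume:
    """Block-mean downsampling by an integer factor.

    Each output voxel is the arithmetic mean of its ``factor**3`` input
    block; the voxel size is multiplied by ``factor`` and the origin is
    preserved.  Dimensions not divisible by the factor are padded with the
    volume minimum (logged) before averaging.
    """
    factor = int(factor)
    if factor <= 0:
        raise ValueError(f"downsampling factor must be >= 1, got {factor}")
    if factor == 1:
        return volume.copy()
    data = np.asarray(volume.data, dtype=np.float64)
    pads = [(-s) % factor for s in data.shape]
    if any(pads):
        log.info("downsample_mean: padding %s voxels with background", pads)
        fill = float(data.min())
        data = np.pad(data, [(0, p) for p in pads], constant_values=fill)
    nz, ny, nx = (s // factor for s in data.shape)
    blocks = data.reshape(nz, factor, ny, factor, nx, factor)
    out = blocks.mean(axis=(1, 3, 5))
    return GrayscaleVolume(out, volume.voxel_size_um * factor, volume.origin_mm)
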