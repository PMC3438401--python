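"""Shared fixtures: small specimens and scans that many tests reuse."""

from __future__ import annotations

import numpy as np
import pytest

from trabevalid import microfe, segmentation, synthfoam
from trabevalid.volume import BONE, CEMENT, LabelVolume


@pytest.fixture(scope="session")
def small_foam_params() -> synthfoam.FoamParams:
    """A cheap specimen: 2.5 mm x 5 mm at 50 um with scaled-down cells."""
    return synthfoam.FoamParams(
        cylinder_diameter_mm=2.5, cylinder_height_mm=5.0,
        cell_size_range_mm=(0.8, 1.2), strut_thickness_range_mm=(0.15, 0.30),
        voxel_size_um=50.0, seed=7)


@pytest.fixture(scope="session")
def small_foam(small_foam_params):
    label, geom = synthfoam.generate_foam_lattice(small_foam_params,
                                                  return_geometry=True)
    return label, geom


@pytest.fixture(scope="session")
def capped_specimen(small_foam):
    label, _ = small_foam
    return synthfoam.add_cement_caps(label, 0.8, 0.8)


@pytest.fixture(scope="session")
def default_scan(capped_specimen):
    imaging = synthfoam.ImagingParams(seed=3)
    return synthfoam.emulate_uct(capped_specimen, imaging), capped_specimen


@pytest.fixture()
def two_material_block() -> LabelVolume:
    """3x3x4 composite block with an interdigitated bone finger."""
    lab = np.zeros((4, 3, 3), dtype=np.uint8)
    lab[:2] = CEMENT
    lab[2:] = BONE
    lab[1, 1, 1] = BONE
    return LabelVolume(lab, 1000.0)


@pytest.fixture(scope="session")
def nu0_materials():
    """Poisson ratio 0 so 1D series/parallel closed forms hold exactly."""
    return {BONE: microfe.Material("bone", 280.0, 0.0),
            CEMENT: microfe.Material("cement", 2280.0, 0.0)}
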