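"""End-to-end closed-loop pipeline: specimen -> scan -> model -> validation.

Because no real scans are deposited, the pipeline is closed-loop: it
generates a ground-truth specimen, emulates its unloaded scan, builds the
micro-FE model from that scan exactly as one would from real data, then
*synthesises* the loaded-state "experimental" scans by warping the ground
truth through the solved displacement field and re-imaging it with fresh
noise.  The morphological validation then proceeds blind to the ground
truth: it only ever compares model-predicted slices with (synthetic)
experimental slices, so the reported errors measure what the method itself
contributes (segmentation, meshing, rasterisation, noise) — the same role
the unloaded calibration plays with physical specimens.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, Field

from . import imagio, microfe, morphval, registration, segmentation, synthfoam
from .volume import BACKGROUND, BONE, CEMENT, MARKER, LabelVolume


class FoamConfig(BaseModel):
    cylinder_diameter_mm: float = 6.0
    cylinder_height_mm: float = 12.0
    cell_size_range_mm: tuple[float, float] = (1.5, 2.5)
    strut_thickness_range_mm: tuple[float, float] = (0.15, 0.30)
    cap_depth_mm: tuple[float, float] = (3.0, 3.0)  # (top, bottom)
    voxel_size_um: float = 25.0


class ImagingConfig(BaseModel):
    class_mean_gray: dict[int, float] = Field(
        default_factory=lambda: {BACKGROUND: 20.0, BONE: 105.0,
                                 CEMENT: 165.0, MARKER: 235.0})
    class_sd_gray: dict[int, float] = Field(
        default_factory=lambda: {BACKGROUND: 8.0, BONE: 12.0,
                                 CEMENT: 12.0, MARKER: 10.0})
    psf_sigma_um: float = 15.0
    marker_threshold: float = 200.0


class MaterialConfig(BaseModel):
    E_mpa: float
    nu: float = 0.3


class PipelineConfig(BaseModel):
    """Full configuration; defaults follow the physical test protocol the
    package emulates (nominal strains 3/5/15%, foam E=280 MPa, cement
    E=2280 MPa, nu=0.3, scans at 25 um downsampled to 50 um models)."""

    foam: FoamConfig = Field(default_factory=FoamConfig)
    imaging: ImagingConfig = Field(default_factory=ImagingConfig)
    thresholds: str | tuple[float, float] = "auto"
    downsample_factor: int = 2
    increments: list[float] = Field(default_factory=lambda: [0.03, 0.05, 0.15])
    materials: dict[str, MaterialConfig] = Field(default_factory=lambda: {
        "bone": MaterialConfig(E_mpa=280.0),
        "cement": MaterialConfig(E_mpa=2280.0)})
    interface_kind: str = "tied"
    penalty_stiffness: float | None = None
    solver_tolerance: float = 1e-8
    solver_max_iterations: int = 20000
    min_component_voxels: int = 27
    marker_station_fractions: tuple[float, float, float] = (0.30, 0.50, 0.70)
    landmark_noise_um: float = 0.0
    n_landmarks_per_end: int = 6
    reuse_linear_scaling: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self) -> str:
        return yaml.safe_dump(json.loads(self.model_dump_json()))


def scaled_demo_config(seed: int = 0, increments=(0.03, 0.05)) -> PipelineConfig:
    """Desk-scale specimen (~4 mm diameter x 8 mm, 1.5 mm caps) that keeps
    the 50 um element size while remaining solvable on one CPU in minutes.
    The foam microstructure is scaled with the specimen (cells 1.0-1.7 mm)
    so several cells still fit across the reduced diameter; strut thickness
    keeps its physical range, which the 50 um elements resolve."""
    return PipelineConfig(
        foam=FoamConfig(cylinder_diameter_mm=4.0, cylinder_height_mm=8.0,
                        cell_size_range_mm=(1.0, 1.7),
                        cap_depth_mm=(1.5, 1.5)),
        increments=list(increments),
        # validation operates on 25 um pixels; residual 1e-5 leaves
        # displacement errors orders of magnitude below one pixel
        solver_tolerance=1e-5,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# helpers

def detect_markers(scan, threshold: float) -> np.ndarray:
    """Fiducial-marker mask: bright voxels, opened to drop noise speckle."""
    from scipy import ndimage
    mask = scan.data >= threshold
    return ndimage.binary_opening(mask)


def default_marker_positions(cfg: PipelineConfig) -> list[tuple[float, float, float]]:
    """Three markers in the pore space near the +y side, one per station."""
    d = cfg.foam.cylinder_diameter_mm
    h = cfg.foam.cylinder_height_mm
    vs = cfg.foam.voxel_size_um * 1e-3
    margin = 5 * vs
    pos = []
    for f in cfg.marker_station_fractions:
        x = f * d
        # largest |y| still inside the volume with a safety margin
        y = d - margin
        pos.append((x, y, h / 2.0))
    return pos


def align_crop(a: LabelVolume, b: LabelVolume) -> tuple[LabelVolume, LabelVolume]:
    """Crop two same-resolution volumes to their common world-space region."""
    if abs(a.voxel_size_um - b.voxel_size_um) > 1e-9:
        raise ValueError("volumes differ in resolution")
    vs = a.voxel_size_mm
    # integer voxel offset of b's origin relative to a's, per (z, y, x)
    off = np.round((np.array(b.origin_mm) - np.array(a.origin_mm)) / vs
                   ).astype(int)[::-1]
    lo_a = np.maximum(off, 0)
    lo_b = np.maximum(-off, 0)
    n = np.minimum(np.array(a.shape) - lo_a, np.array(b.shape) - lo_b)
    if np.any(n <= 0):
        raise ValueError("volumes do not overlap")
    sl_a = tuple(slice(l, l + m) for l, m in zip(lo_a, n))
    sl_b = tuple(slice(l, l + m) for l, m in zip(lo_b, n))
    origin = tuple(a.origin_mm[c] + sl_a[2 - c].start * vs for c in range(3))
    return (LabelVolume(a.labels[sl_a], a.voxel_size_um, origin),
            LabelVolume(b.labels[sl_b], b.voxel_size_um, origin))


def mesh_label_volume(mesh: microfe.VoxelMesh) -> LabelVolume:
    """The exact label geometry the mesh represents (post filtering/drops)."""
    lab = np.zeros(mesh.shape, dtype=np.uint8)
    lab[mesh.elem_kji[:, 0], mesh.elem_kji[:, 1], mesh.elem_kji[:, 2]] = mesh.elem_mat
    return LabelVolume(lab, mesh.voxel_size_um, mesh.origin_mm)


def _scale_solution(sol: microfe.FESolution, factor: float,
                    bcs: registration.BoundaryConditions) -> microfe.FESolution:
    """Exact scaling of a linear solution to a proportional load increment."""
    return microfe.FESolution(
        sol.mesh, sol.u_mm * factor, sol.stress_mpa * factor,
        sol.von_mises_mpa * abs(factor), sol.reaction_top_n * factor,
        sol.reaction_bottom_n * factor, sol.apparent_stiffness_n_per_mm,
        sol.iterations, sol.residual, bcs)


def synthetic_end_landmarks(cfg: PipelineConfig, u_top, u_bottom, increment,
                            rng) -> dict[str, registration.LandmarkSet]:
    """Landmark sets emulating the manual point measurements on both ends."""
    d = cfg.foam.cylinder_diameter_mm
    h = cfg.foam.cylinder_height_mm
    n = cfg.n_landmarks_per_end
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    ring = np.stack([d / 2 + 0.3 * d * np.cos(ang),
                     d / 2 + 0.3 * d * np.sin(ang)], axis=1)
    sets = {}
    for end, z, u in (("top", h, u_top), ("bottom", 0.0, u_bottom)):
        ref = np.column_stack([ring, np.full(n, z)])
        noise = rng.normal(0.0, cfg.landmark_noise_um * 1e-3, size=(n, 3))
        loaded = ref + np.asarray(u)[None, :] + noise
        sets[end] = (registration.LandmarkSet(end, ref, "ref"),
                     registration.LandmarkSet(end, loaded, increment))
    return sets


def _sha(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# the pipeline

@dataclass
class PipelineResult:
    config: PipelineConfig
    thresholds: segmentation.SegmentationThresholds
    plan: morphval.SlicePlan
    mesh: microfe.VoxelMesh
    solutions: dict[str, microfe.FESolution]
    records: list[morphval.MorphologyComparison]
    summary: "object"              # pandas DataFrame
    manifest: dict


def run_pipeline(cfg: PipelineConfig, out_dir=None,
                 keep_solutions: bool = True) -> PipelineResult:
    """Run foamgen -> scan -> segment -> bc -> solve -> validate."""
    import pandas as pd

    seed = int(cfg.seed)
    manifest: dict = {"seeds": {"master": seed}, "stages": {}, "hashes": {}}

    # -- ground-truth specimen --------------------------------------------
    fp = synthfoam.FoamParams(
        cylinder_diameter_mm=cfg.foam.cylinder_diameter_mm,
        cylinder_height_mm=cfg.foam.cylinder_height_mm,
        cell_size_range_mm=tuple(cfg.foam.cell_size_range_mm),
        strut_thickness_range_mm=tuple(cfg.foam.strut_thickness_range_mm),
        voxel_size_um=cfg.foam.voxel_size_um,
        seed=seed)
    foam = synthfoam.generate_foam_lattice(fp)
    capped = synthfoam.add_cement_caps(foam, *cfg.foam.cap_depth_mm, seed=seed)
    truth = synthfoam.embed_markers(capped, default_marker_positions(cfg))
    manifest["stages"]["foamgen"] = {
        "porosity_pct": synthfoam.measure_porosity(foam, fp.cylinder_diameter_mm),
        "solid_voxels": int(np.count_nonzero(capped.solid_mask()))}
    manifest["hashes"]["truth_labels"] = _sha(truth.labels)

    # -- unloaded scan and segmentation -----------------------------------
    imaging0 = synthfoam.ImagingParams(
        class_mean_gray=dict(cfg.imaging.class_mean_gray),
        class_sd_gray=dict(cfg.imaging.class_sd_gray),
        psf_sigma_um=cfg.imaging.psf_sigma_um, seed=seed + 1000)
    scan0 = synthfoam.emulate_uct(truth, imaging0)
    manifest["hashes"]["scan0"] = _sha(scan0.data)

    if cfg.thresholds == "auto":
        thr = segmentation.auto_thresholds(scan0)
    else:
        thr = segmentation.SegmentationThresholds(*cfg.thresholds)
    manifest["stages"]["segment"] = {"t_bone": thr.t_bone,
                                     "t_cement": thr.t_cement}

    seg25 = segmentation.segment(
        scan0, thr, detect_markers(scan0, cfg.imaging.marker_threshold))
    scan50 = imagio.downsample_mean(scan0, cfg.downsample_factor)
    seg50 = segmentation.segment(
        scan50, thr, detect_markers(scan50, cfg.imaging.marker_threshold))
    seg50f, filt_report = segmentation.connectivity_filter(
        seg50, cfg.min_component_voxels)
    manifest["stages"]["connectivity_filter"] = filt_report

    materials = {BONE: microfe.Material("bone", cfg.materials["bone"].E_mpa,
                                        cfg.materials["bone"].nu),
                 CEMENT: microfe.Material("cement", cfg.materials["cement"].E_mpa,
                                          cfg.materials["cement"].nu)}
    mesh = microfe.build_mesh(seg50f, materials)
    manifest["stages"]["mesh"] = {"n_elements": mesh.n_elements,
                                  "n_nodes": mesh.n_nodes,
                                  "n_interface_faces": len(mesh.interface_faces)}
    fe_label = mesh_label_volume(mesh)

    # -- slice plan and unloaded calibration -------------------------------
    plan = morphval.slice_plan(seg25)
    zero_field = np.zeros(tuple(s + 1 for s in fe_label.shape) + (3,))
    fe_base = morphval.warp_labels(fe_label, zero_field,
                                   target_voxel_size_um=scan0.voxel_size_um)
    a, b = align_crop(fe_base, seg25)
    records = [morphval.compare_slices(
        morphval.extract_slice(a, x), morphval.extract_slice(b, x),
        increment="initial", station_x_mm=x) for x in plan.stations_x_mm]

    # -- boundary conditions + solves per increment ------------------------
    interface = microfe.InterfaceModel(cfg.interface_kind,
                                       cfg.penalty_stiffness)
    opts = microfe.SolverOptions(tolerance=cfg.solver_tolerance,
                                 max_iterations=cfg.solver_max_iterations)
    height = mesh.shape[0] * mesh.h_mm
    rng = np.random.default_rng(seed + 2000)
    solutions: dict[str, microfe.FESolution] = {}
    bcs_all: dict[str, registration.BoundaryConditions] = {}
    base_name = None
    for idx, strain in enumerate(cfg.increments, start=1):
        name = f"step{idx}"
        u_top = np.array([0.0, 0.0, -strain * height / 2.0])
        u_bot = np.array([0.0, 0.0, +strain * height / 2.0])
        lm = synthetic_end_landmarks(cfg, u_top, u_bot, name, rng)
        u_top_est = registration.compute_end_displacements(*lm["top"])
        u_bot_est = registration.compute_end_displacements(*lm["bottom"])
        bcs = registration.build_boundary_conditions(
            u_top_est, u_bot_est, name, specimen_height_mm=height)
        bcs_all[name] = bcs
        if cfg.reuse_linear_scaling and base_name is not None:
            ref = solutions[base_name]
            factor = (bcs.u_top_mm[2] - bcs.u_bottom_mm[2]) / \
                (ref.bcs.u_top_mm[2] - ref.bcs.u_bottom_mm[2])
            solutions[name] = _scale_solution(ref, factor, bcs)
        else:
            solutions[name] = microfe.solve(mesh, bcs, interface, opts)
            base_name = name
        manifest["stages"][name] = {
            "nominal_strain": bcs.nominal_strain,
            "apparent_stiffness_n_per_mm":
                solutions[name].apparent_stiffness_n_per_mm,
            "max_von_mises_mpa": solutions[name].max_von_mises(),
            "iterations": solutions[name].iterations}

    # -- loaded-state synthesis and morphology comparison ------------------
    nodes25 = tuple(s + 1 for s in truth.shape)
    for idx, (name, sol) in enumerate(solutions.items(), start=1):
        field50 = microfe.nodal_field_on_grid(mesh, sol)
        fe_def = morphval.warp_labels(fe_label, field50,
                                      target_voxel_size_um=truth.voxel_size_um)
        field25 = morphval.resample_field(field50, mesh.voxel_size_um,
                                          nodes25, truth.voxel_size_um)
        imaging_i = synthfoam.ImagingParams(
            class_mean_gray=dict(cfg.imaging.class_mean_gray),
            class_sd_gray=dict(cfg.imaging.class_sd_gray),
            psf_sigma_um=cfg.imaging.psf_sigma_um, seed=seed + 1000 + idx)
        scan_i = synthfoam.synthesize_loaded_scan(truth, field25, imaging_i)
        seg_i = segmentation.segment(
            scan_i, thr, detect_markers(scan_i, cfg.imaging.marker_threshold))
        a, b = align_crop(fe_def, seg_i)
        for x in plan.stations_x_mm:
            records.append(morphval.compare_slices(
                morphval.extract_slice(a, x), morphval.extract_slice(b, x),
                increment=name, station_x_mm=x))
        manifest["hashes"][f"scan_{name}"] = _sha(scan_i.data)
        manifest["hashes"][f"fe_def_{name}"] = _sha(fe_def.labels)

    summary = morphval.aggregate(records)
    manifest["summary"] = summary.to_dict(orient="records")

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.yaml").write_text(cfg.to_yaml())
        summary.to_csv(out / "summary.csv", index=False)
        for name, bcs in bcs_all.items():
            (out / f"bc_{name}.json").write_text(bcs.to_json())
        import imageio.v3 as iio
        av, bv = align_crop(fe_base, seg25)
        for x in plan.stations_x_mm:
            rgb = morphval.overlay_rgb(morphval.extract_slice(av, x),
                                       morphval.extract_slice(bv, x))
            iio.imwrite(out / f"overlay_initial_x{x:.2f}mm.png", rgb[::-1])
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))

    return PipelineResult(cfg, thr, plan, mesh,
                          solutions if keep_solutions else {},
                          records, summary, manifest)


def compare_interfaces(cfg: PipelineConfig, penalty_stiffness: float | None = None):
    """Tied vs linearised-frictionless comparison on the same specimen:
    stiffness, peak von Mises and deformed-morphology differences (percent,
    relative to the tied model), per load increment."""
    import pandas as pd

    tied_cfg = cfg.model_copy(update={"interface_kind": "tied"})
    fless_cfg = cfg.model_copy(update={
        "interface_kind": "frictionless_penalty",
        "penalty_stiffness": penalty_stiffness})
    tied = run_pipeline(tied_cfg)
    fless = run_pipeline(fless_cfg)

    rows = []
    for name in tied.solutions:
        st, sf = tied.solutions[name], fless.solutions[name]
        k_t, k_f = st.apparent_stiffness_n_per_mm, sf.apparent_stiffness_n_per_mm
        vm_t, vm_f = st.max_von_mises(), sf.max_von_mises()
        field_t = microfe.nodal_field_on_grid(tied.mesh, st)
        field_f = microfe.nodal_field_on_grid(fless.mesh, sf)
        lab_t = mesh_label_volume(tied.mesh)
        lab_f = mesh_label_volume(fless.mesh)
        scan_res = cfg.foam.voxel_size_um
        wt = morphval.warp_labels(lab_t, field_t, scan_res)
        wf = morphval.warp_labels(lab_f, field_f, scan_res)
        a, b = align_crop(wt, wf)
        morph = np.mean([morphval.compare_slices(
            morphval.extract_slice(b, x), morphval.extract_slice(a, x),
            increment=name, station_x_mm=x).total_error_pct
            for x in tied.plan.stations_x_mm])
        rows.append({"increment": name,
                     "stiffness_tied_n_per_mm": k_t,
                     "stiffness_frictionless_n_per_mm": k_f,
                     "stiffness_diff_pct": 100.0 * (k_t - k_f) / k_t,
                     "max_von_mises_diff_pct": 100.0 * (vm_t - vm_f) / vm_t,
                     "morphology_diff_pct": morph})
    return pd.DataFrame(rows), tied, fless
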