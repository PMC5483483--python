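"""Dataset formats, configuration and the five-step pipeline driver.

Volumes are stored either as NIfTI (a 5-D file ``(nx, ny, nz, t, component)``
with a JSON sidecar carrying VENC and frame times) or as a documented HDF5
layout::

    /velocity   (n_frames, 3, nx, ny, nz)  float, m/s
    /magnitude  (n_frames, nx, ny, nz)     float
    attrs: spacing (mm), origin (mm), venc (m/s), frame_times (ms)

Velocities are stored in m/s, reported in cm/s where clinical tables do;
wall shear stress in Pa; flow in ml/s internally and l/min in reports.
Voxel indexing is 0-based with the voxel-centre world convention
``world = origin + (index + 0.5)·spacing``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bulkflow, geometry, preprocess, sections, template, wss
from .phantom import FourDFlowDataset, PhantomSpec, make_phantom

logger = logging.getLogger(__name__)

__all__ = [
    "StudyConfig",
    "RunManifest",
    "read_dataset",
    "write_dataset",
    "run_pipeline",
    "cohort_report",
]

#: fraction of the phantom centerline at which pseudo-landmarks sit when a
#: study supplies none (PA and BrA have no analogue on a tube)
DEFAULT_LANDMARK_FRACTIONS = {"LVOT": 0.0, "PA": 0.4, "BrA": 0.8, "DeA": 1.0}


@dataclass
class StudyConfig:
    """Everything needed to run one subject through the pipeline."""

    dataset_path: str | None = None
    phantom: dict | None = None          # PhantomSpec kwargs, alternative input
    landmarks: dict | None = None        # name -> [x, y, z] mm
    landmark_fractions: dict = field(
        default_factory=lambda: dict(DEFAULT_LANDMARK_FRACTIONS))
    venc: float | None = None            # m/s, overrides file metadata
    viscosity: float = 3.7e-3            # Pa·s
    anterior_axis: tuple = (0.0, 1.0, 0.0)
    static_percentile: float = 5.0       # eddy correction static-voxel cut
    smoothing_iterations: int = 20       # surface Laplacian smoothing
    smoothing_relaxation: float = 0.1
    upsample_factor: int = 4             # in-plane spline upsampling
    n_boundary: int = 72                 # boundary points per section
    template_bins: tuple = (template.N_S_BINS, template.N_R_BINS)
    gv_inward_offset_voxels: float = 1.0
    apply_preprocess: bool = True
    mask_threshold: float = 0.5          # magnitude cue for programmatic masks
    cohort: str = "HV"                   # cohort membership: HV or patient
    seed: int = 0
    subject_id: str = "subject"
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class RunManifest:
    """Provenance record serialized beside every set of outputs."""

    subject_id: str
    stages: list = field(default_factory=list)
    parameters: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    input_hash: str | None = None

    def add(self, stage: str, **info) -> None:
        self.stages.append({"stage": stage, **info})

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


def _array_hash(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


# ---------------------------------------------------------------- dataset IO

def write_dataset(dataset: FourDFlowDataset, path) -> None:
    """Write a dataset as NIfTI (+ JSON sidecar) or HDF5, by extension."""
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        import h5py
        with h5py.File(path, "w") as fh:
            fh.create_dataset("velocity", data=dataset.velocity)
            fh.create_dataset("magnitude", data=dataset.magnitude)
            fh.attrs["spacing"] = dataset.spacing
            fh.attrs["origin"] = dataset.origin
            fh.attrs["venc"] = dataset.venc
            fh.attrs["frame_times"] = dataset.frame_times
        return
    import nibabel as nib
    # (nx, ny, nz, t, comp) layout; affine encodes spacing and voxel-centre
    # origin so world = affine @ index
    arr = np.moveaxis(dataset.velocity, (0, 1), (3, 4))
    affine = np.diag(np.r_[dataset.spacing, 1.0])
    affine[:3, 3] = dataset.origin + 0.5 * dataset.spacing
    nib.save(nib.Nifti1Image(arr.astype(np.float32), affine), str(path))
    mag = np.moveaxis(dataset.magnitude, 0, 3)
    base = str(path)
    for ext in (".nii.gz", ".nii"):
        if base.endswith(ext):
            base = base[: -len(ext)]
            suffix = ext
            break
    else:
        suffix = ".nii.gz"
    nib.save(nib.Nifti1Image(mag.astype(np.float32), affine),
             base + "_mag" + suffix)
    sidecar = {
        "venc": dataset.venc,
        "frame_times_ms": dataset.frame_times.tolist(),
        "spacing_mm": dataset.spacing.tolist(),
        "origin_mm": dataset.origin.tolist(),
    }
    with open(base + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def read_dataset(path, venc: float | None = None) -> FourDFlowDataset:
    """Read a dataset written by :func:`write_dataset`.

    VENC must come from the HDF5 attributes, the JSON sidecar, or the
    ``venc`` argument; a missing VENC is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix in {".h5", ".hdf5"}:
        import h5py
        with h5py.File(path, "r") as fh:
            missing = [k for k in ("velocity", "magnitude") if k not in fh]
            if missing:
                raise ValueError(f"dataset {path} missing component(s): "
                                 f"{', '.join(missing)}")
            velocity = fh["velocity"][()]
            magnitude = fh["magnitude"][()]
            spacing = np.asarray(fh.attrs["spacing"], float)
            origin = np.asarray(fh.attrs["origin"], float)
            frame_times = np.asarray(fh.attrs["frame_times"], float)
            file_venc = float(fh.attrs["venc"]) if "venc" in fh.attrs else None
    else:
        import nibabel as nib
        img = nib.load(str(path))
        arr = np.asarray(img.dataobj)
        if arr.ndim != 5 or arr.shape[4] != 3:
            raise ValueError(
                f"expected a 5-D NIfTI (nx, ny, nz, t, 3), got {arr.shape}")
        velocity = np.moveaxis(arr, (3, 4), (0, 1)).astype(float)
        base = str(path)
        for ext in (".nii.gz", ".nii"):
            if base.endswith(ext):
                base = base[: -len(ext)]
                break
        sidecar_path = Path(base + ".json")
        if not sidecar_path.exists():
            raise ValueError(f"missing JSON sidecar {sidecar_path} (carries "
                             "VENC and frame times)")
        with open(sidecar_path) as fh:
            sidecar = json.load(fh)
        file_venc = sidecar.get("venc")
        frame_times = np.asarray(sidecar["frame_times_ms"], float)
        spacing = np.asarray(sidecar.get(
            "spacing_mm", np.diag(img.affine)[:3]), float)
        origin = np.asarray(sidecar.get(
            "origin_mm", img.affine[:3, 3] - 0.5 * spacing), float)
        mag_path = Path(base + "_mag" + str(path)[len(base):])
        if mag_path.exists():
            magnitude = np.moveaxis(
                np.asarray(nib.load(str(mag_path)).dataobj), 3, 0)
        else:
            magnitude = np.ones((velocity.shape[0],) + velocity.shape[2:])
    venc = venc if venc is not None else file_venc
    if venc is None:
        raise ValueError(f"dataset {path}: VENC not found in metadata and "
                         "not supplied")
    if magnitude.shape != (velocity.shape[0],) + velocity.shape[2:]:
        raise ValueError("magnitude/velocity grid shapes disagree")
    return FourDFlowDataset(velocity=velocity, magnitude=magnitude,
                            spacing=spacing, frame_times=frame_times,
                            venc=float(venc), origin=origin)


# ------------------------------------------------------------------- driver

def _lumen_mask_from_magnitude(dataset: FourDFlowDataset,
                               threshold: float) -> np.ndarray:
    mag = dataset.magnitude.mean(axis=0)
    return mag > threshold


def run_pipeline(config: StudyConfig, write_outputs: bool = True) -> dict:
    """Execute preprocess → geometry → sections → bulkflow → wss → template.

    Returns a results dictionary; when ``config.output_dir`` is set (and
    ``write_outputs``), metric tables, template maps, the wall mesh and the
    run manifest are persisted there.  Deterministic given the config seed.
    """
    manifest = RunManifest(subject_id=config.subject_id,
                           parameters=config.to_dict())
    results: dict = {"config": config, "manifest": manifest}
    anterior = np.asarray(config.anterior_axis, float)

    # ---- input
    truth = None
    if (config.phantom is None) == (config.dataset_path is None):
        raise ValueError("config must supply exactly one of phantom or "
                         "dataset_path")
    if config.phantom is not None:
        spec = PhantomSpec(**{**config.phantom, "seed": config.seed})
        dataset, truth = make_phantom(spec)
        results["truth"] = truth
    else:
        dataset = read_dataset(config.dataset_path, venc=config.venc)
    manifest.input_hash = _array_hash(dataset.velocity)
    manifest.add("input", grid=list(dataset.grid_shape),
                 n_frames=dataset.n_frames, venc=dataset.venc)

    # landmarks must be resolvable before any compute starts
    if config.landmarks is None and truth is None:
        raise ValueError("landmarks are required for non-phantom datasets")

    # ---- step 1: preprocessing
    if config.apply_preprocess:
        field_ = preprocess.preprocess(
            dataset=dataset, static_percentile=config.static_percentile)
    else:
        field_ = preprocess.VelocityField.from_dataset(dataset)
    manifest.add("preprocess", flags=dict(field_.flags))

    # ---- step 2: geometry
    if truth is not None:
        mask = truth.lumen_mask
        provenance = "phantom analytic lumen"
    else:
        mask = _lumen_mask_from_magnitude(dataset, config.mask_threshold)
        provenance = "magnitude threshold"
    roi = geometry.ROIMask(mask=mask, spacing=dataset.spacing,
                           origin=dataset.origin, provenance=provenance)
    surface = geometry.extract_surface(
        roi, n_iter=config.smoothing_iterations,
        relaxation=config.smoothing_relaxation)
    if config.landmarks is not None:
        lm_points = {k: np.asarray(v, float)
                     for k, v in config.landmarks.items()}
    else:
        # pseudo-landmarks at fixed fractions of the analytic centerline
        cl = truth.centerline
        arc = np.r_[0, np.cumsum(np.linalg.norm(np.diff(cl, axis=0), axis=1))]
        lm_points = {
            name: np.stack([np.interp(frac * arc[-1], arc, cl[:, d])
                            for d in range(3)])
            for name, frac in config.landmark_fractions.items()}
    skeleton_pts = geometry.skeletonize_and_order(
        roi, lm_points["LVOT"], lm_points["DeA"])
    centerline = geometry.fit_centerline(
        skeleton_pts, voxel_size=float(np.mean(dataset.spacing)))
    centerline.set_landmarks(lm_points)
    manifest.add("geometry", n_skeleton=len(skeleton_pts),
                 centerline_length_mm=centerline.total_length,
                 landmarks=centerline.landmarks)
    results.update(roi=roi, surface=surface, centerline=centerline)

    # ---- step 3: cross-sections
    secs = sections.build_sections(
        field_, roi, surface, centerline,
        anterior=anterior, n_boundary=config.n_boundary,
        upsample_factor=config.upsample_factor)
    manifest.add("sections", n_sections=len(secs))
    results["sections"] = secs

    # ---- step 4: bulk flow
    lvot_sec = secs[0]
    wave = bulkflow.flow_waveform(lvot_sec, field_.frame_times)
    stats = [bulkflow.section_stats(s, wave.t_ps) for s in secs]
    lm = centerline.landmarks
    tract_table = bulkflow.tract_summary(stats, lm)
    q_all = np.stack([bulkflow.flow_rate(s) for s in secs])
    manifest.add("bulkflow", t_ps=wave.t_ps, t_es=wave.t_es,
                 q_max_lpm=wave.q_max_lpm, sv_ml=wave.sv_ml)
    results.update(waveform=wave, section_stats=stats,
                   tract_table=tract_table, flow_rates=q_all)

    # ---- step 5: wall shear stress
    t_frames = range(wave.t_es + 1)
    tau_frames = [wss.strain_tensor_gv(field_.velocity[k], field_.spacing,
                                       config.viscosity) for k in t_frames]
    gv_series, lp_series = [], []
    for k in t_frames:
        gv_k = np.concatenate([
            wss.wss_gv(tau_frames[k], s.boundary_world, s.x_r,
                       field_.spacing, field_.origin,
                       config.gv_inward_offset_voxels) for s in secs])
        gv_series.append(gv_k)
        lp_k = np.concatenate([wss.wss_lp(s, k, config.viscosity)
                               for s in secs])
        lp_series.append(lp_k)
    gv_series = np.stack(gv_series)          # (T_sys, B_total, 3)
    lp_series = np.stack(lp_series)
    normals = np.concatenate([s.x_r for s in secs])
    x3_all = np.concatenate([np.broadcast_to(s.x3, s.x_r.shape)
                             for s in secs])
    xt_all = np.concatenate([s.x_t for s in secs])
    metrics_gv = wss.time_metrics(gv_series, field_.frame_times, wave.t_es,
                                  normals, x3_all, xt_all)
    peak_gv = wss.peak_systole_wss(gv_series, wave.t_ps)
    peak_lp = wss.peak_systole_wss(lp_series, wave.t_ps)
    manifest.add("wss", n_wall_points=gv_series.shape[1],
                 frames=len(tau_frames))
    results.update(gv_series=gv_series, lp_series=lp_series,
                   metrics_gv=metrics_gv, peak_gv=peak_gv, peak_lp=peak_lp)

    # ---- template maps on the LVOT-BrA tract
    s_lvot, s_bra = lm["LVOT"], lm["BrA"]
    s_pa = (lm["PA"] - s_lvot) / (s_bra - s_lvot)
    s_coord, r_coord, point_idx = template.template_coordinates(
        secs, s_lvot, s_bra)
    n_s, n_r = config.template_bins
    weights = template.section_cell_weights(secs, s_lvot, s_bra, n_s, n_r)
    # flat indices into the concatenated wall-point arrays
    offsets = np.r_[0, np.cumsum([len(s.boundary_local) for s in secs])]
    flat = offsets[point_idx[:, 0]] + point_idx[:, 1]
    maps = {}
    for name, values in [("wss_gv", peak_gv), ("osi", metrics_gv.osi),
                         ("rrt", metrics_gv.rrt),
                         ("transwss", metrics_gv.transwss)]:
        maps[name] = template.rasterize(s_coord, r_coord, values[flat],
                                        s_pa, n_s, n_r, cell_weights=weights)
    sectors = template.sector_partition(s_pa, n_s, n_r)
    manifest.add("template", s_pa=s_pa,
                 n_sectors=len(np.unique(sectors)))
    results.update(maps=maps, sectors=sectors, s_pa=s_pa)

    if write_outputs and config.output_dir:
        _write_outputs(results, Path(config.output_dir))
    return results


def _write_outputs(results: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    config: StudyConfig = results["config"]
    tract: pd.DataFrame = results["tract_table"]
    tract.to_csv(out_dir / "tract_table.csv")
    wave = results["waveform"]
    pd.DataFrame({"time_ms": wave.frame_times, "q_ml_s": wave.q}).to_csv(
        out_dir / "flow_waveform.csv", index=False)
    metrics = results["metrics_gv"]
    pd.DataFrame({
        "awss_pa": metrics.awss, "awssv_pa": metrics.awssv,
        "osi": metrics.osi, "rrt_pa_inv": metrics.rrt,
        "transwss_pa": metrics.transwss,
        "osi_axial": metrics.osi_axial, "osi_circ": metrics.osi_circ,
        "peak_wss_gv_pa": results["peak_gv"],
        "peak_wss_lp_pa": results["peak_lp"],
    }).to_csv(out_dir / "wall_metrics.csv", index_label="wall_point")
    for name, tmap in results["maps"].items():
        np.savetxt(out_dir / f"template_{name}.csv", tmap.values,
                   delimiter=",")
        _save_heatmap(tmap, out_dir / f"template_{name}.png", name)
    results["surface"].mesh.export(out_dir / "wall_surface.ply")
    config.to_yaml(out_dir / "config.yaml")
    results["manifest"].save(out_dir / "manifest.json")


def _save_heatmap(tmap, path, title: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(tmap.values.T, origin="lower", aspect="auto",
                   extent=(0, 1, 0, 1), cmap="inferno")
    ax.axvline(tmap.s_pa, color="w", ls="--", lw=0.8)
    ax.set_xlabel("s (LVOT → BrA)")
    ax.set_ylabel("r (anterior, CCW)")
    ax.set_title(title)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


# ------------------------------------------------------------------ cohorts

def cohort_report(
    hv_results: list[dict],
    patient_results: list[dict],
    out_dir=None,
    map_names: tuple = ("wss_gv", "osi", "rrt", "transwss"),
) -> dict:
    """Cohort percentile maps, per-patient relative classes and exceedance.

    ``hv_results``/``patient_results`` are outputs of :func:`run_pipeline`.
    Also emits the per-tract Mann–Whitney comparison table.
    """
    if len(hv_results) < 3:
        raise ValueError("HV cohort must contain >= 3 runs")
    report: dict = {"percentiles": {}, "patients": {}}
    for name in map_names:
        maps = [r["maps"][name] for r in hv_results]
        report["percentiles"][name] = template.group_percentiles(maps)
    for patient in patient_results:
        pid = patient["config"].subject_id
        entry = {}
        for name in map_names:
            p10, p50, p90 = report["percentiles"][name]
            rel = template.relative_classify(patient["maps"][name],
                                             p10, p50, p90)
            exc = template.exceedance(patient["maps"][name], p90)
            entry[name] = {"classes": rel, "exceedance_pct": exc}
        report["patients"][pid] = entry

    # Mann-Whitney comparison of every tract variable
    variables = ["D_max_mm", "V_max_cms", "V_mean_cms", "jet_angle_deg",
                 "flow_displacement"]
    rows = []
    for tract in ("LVOT-PA", "PA-BrA"):
        for var in variables:
            hv_vals = [r["tract_table"].loc[tract, var] for r in hv_results]
            pa_vals = [r["tract_table"].loc[tract, var]
                       for r in patient_results]
            if pa_vals:
                p, sig = bulkflow.compare_groups(hv_vals, pa_vals)
            else:
                p, sig = np.nan, False
            rows.append({"tract": tract, "variable": var, "p_value": p,
                         "significant": sig})
    report["mann_whitney"] = pd.DataFrame(rows)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        report["mann_whitney"].to_csv(out_dir / "mann_whitney.csv",
                                      index=False)
        frac_rows = []
        for pid, entry in report["patients"].items():
            for name, data in entry.items():
                row = {"subject": pid, "variable": name,
                       "exceedance_pct": data["exceedance_pct"]}
                row.update(data["classes"].fractions)
                frac_rows.append(row)
        pd.DataFrame(frac_rows).to_csv(out_dir / "relative_classes.csv",
                                       index=False)
    return report
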