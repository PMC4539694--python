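"""End-to-end workflows on phantom data.

``run_workflow`` reproduces one full detection pipeline: phantom cohort
-> (optional) spatial normalization -> intensity scaling and smoothing
-> reference database -> per-patient statistical map -> clusters,
classification and peak localization.  ``run_comparison`` runs several
configurations on the same subjects and tabulates per-subject peaks and
cluster sizes, pairwise overlap/Dice concordance and Wilcoxon tests
between cluster sizes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from . import clusters as cl
from . import phantom, preprocess, refdb, registration, ssp, statmap
from .grid import BrainVolume, VolumeGrid, save_json, save_nifti

STATISTICS = ("z", "t", "tz", "ssp-z")
NORMALIZATIONS = ("none", "affine", "bspline", "dct")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Settings for one detection workflow on phantom data."""

    space: str = "MNI_LIKE"
    grid: Optional[VolumeGrid] = None          # override the default grid
    normalization: str = "none"                # none|affine|bspline|dct
    scaling: str = "median"                    # median | glb
    fwhm_mm: float = 10.0
    statistic: str = "z"                       # z | t | tz | ssp-z
    cap: Optional[float] = statmap.DEFAULT_Z_CAP
    z_threshold: float = cl.DEFAULT_Z_THRESHOLD
    size_threshold: int = cl.DEFAULT_SIZE_THRESHOLD
    connectivity: int = cl.DEFAULT_CONNECTIVITY
    seed: int = 0
    n_controls: int = 37
    control_noise_sd: float = 10.0
    control_warp_mm: float = 0.25
    texture_amplitude: float = 8.0
    patient_lesions: tuple = ()                # one tuple of LesionSpec per patient
    out_dir: Optional[str] = None

    def __post_init__(self):
        if self.statistic not in STATISTICS:
            raise ConfigError(f"unknown statistic {self.statistic!r}")
        if self.normalization not in NORMALIZATIONS:
            raise ConfigError(f"unknown normalization {self.normalization!r}")
        if self.scaling not in ("median", "glb"):
            raise ConfigError(f"unknown scaling {self.scaling!r}")
        if self.cap is not None and self.statistic == "t":
            raise ConfigError("a z-score cap is only valid for z-valued statistics")
        lesions = []
        for patient in self.patient_lesions:
            lesions.append(tuple(patient))
        object.__setattr__(self, "patient_lesions", tuple(lesions))

    def default_grid(self):
        if self.grid is not None:
            return self.grid
        return (VolumeGrid.mni_like() if self.space == "MNI_LIKE"
                else VolumeGrid.tal_like())

    def to_manifest(self):
        d = {
            "space": self.space,
            "normalization": self.normalization,
            "scaling": self.scaling,
            "fwhm_mm": self.fwhm_mm,
            "statistic": self.statistic,
            "cap": self.cap,
            "z_threshold": self.z_threshold,
            "size_threshold": self.size_threshold,
            "connectivity": self.connectivity,
            "seed": self.seed,
            "n_controls": self.n_controls,
            "control_noise_sd": self.control_noise_sd,
            "control_warp_mm": self.control_warp_mm,
            "texture_amplitude": self.texture_amplitude,
            "n_patients": len(self.patient_lesions),
            "patient_lesions": [[{"center_mm": l.center_mm,
                                  "radius_mm": l.radius_mm,
                                  "reduction": l.reduction,
                                  "edge_sigma_mm": l.edge_sigma_mm}
                                 for l in pat] for pat in self.patient_lesions],
        }
        if self.grid is not None:
            d["grid"] = {"shape": self.grid.shape,
                         "voxel_size_mm": self.grid.voxel_size_mm,
                         "origin_voxel": self.grid.origin_voxel}
        blob = json.dumps(d, sort_keys=True)
        d["config_hash"] = hashlib.sha256(blob.encode()).hexdigest()[:16]
        return d

    @classmethod
    def from_yaml(cls, path):
        import yaml
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "grid" in raw:
            g = raw.pop("grid")
            raw["grid"] = VolumeGrid(tuple(g["shape"]),
                                     tuple(g["voxel_size_mm"]),
                                     raw.get("space", "NATIVE"),
                                     tuple(g.get("origin_voxel"))
                                     if g.get("origin_voxel") else None)
        if "patient_lesions" in raw:
            pls = []
            for pat in raw["patient_lesions"]:
                pls.append(tuple(phantom.LesionSpec(
                    tuple(l["center_mm"]), l["radius_mm"], l["reduction"],
                    l.get("edge_sigma_mm", 2.0)) for l in pat))
            raw["patient_lesions"] = tuple(pls)
        return cls(**raw)


@dataclass
class PatientResult:
    index: int
    stat: statmap.StatMap
    report: cl.ClusterReport
    classification: str
    peak_value: Optional[float]
    peak_mm: Optional[tuple]
    peak_region: Optional[str]
    ground_truth: phantom.GroundTruthRecord


@dataclass
class WorkflowResult:
    config: RunConfig
    database: refdb.ReferenceDatabase
    patients: list
    manifest: dict

    def to_frame(self):
        import pandas as pd
        rows = []
        for p in self.patients:
            rows.append({
                "patient": p.index,
                "max_stat": p.peak_value,
                "total_cluster_size": p.report.total_size if p.report else 0,
                "max_cluster_size": p.report.max_cluster_size if p.report else 0,
                "classification": p.classification,
                "peak_x_mm": p.peak_mm[0] if p.peak_mm else np.nan,
                "peak_y_mm": p.peak_mm[1] if p.peak_mm else np.nan,
                "peak_z_mm": p.peak_mm[2] if p.peak_mm else np.nan,
                "peak_region": p.peak_region,
            })
        return pd.DataFrame(rows)


def _normalize_volume(native, template, method):
    if method == "none":
        return native
    affine = registration.register_affine(native, template)
    warp = None
    if method == "bspline":
        warp = registration.refine_bspline(native, template, affine)
    elif method == "dct":
        warp = registration.refine_dct(native, template, affine)
    tf = registration.SpatialTransform(affine, template.grid, warp)
    return registration.apply_transform(native, tf, "trilinear")


def _preprocess(vol, mask, config):
    if config.scaling == "median":
        scaled = preprocess.scale_to_mask_median(vol, mask)
    else:
        scaled = preprocess.scale_to_region_mean(vol, mask)
    return preprocess.smooth_gaussian(scaled, config.fwhm_mm)


def run_workflow(config, log=None):
    """Run one full phantom detection workflow; deterministic in the seed."""
    def say(msg):
        if log:
            log(msg)

    grid = config.default_grid()
    template = phantom.make_template(
        grid, texture_amplitude=config.texture_amplitude)
    mask = phantom.make_gm_wm_mask(template)
    atlas = phantom.make_atlas(grid)
    say(f"template on {grid.shape} grid; mask {mask.n_true} voxels")

    jitter = (phantom.AffineJitter() if config.normalization != "none"
              else phantom.AffineJitter.none())
    ctrl_spec = phantom.CohortSpec(
        n_subjects=config.n_controls, seed=config.seed,
        affine_jitter=jitter, warp_amplitude_mm=config.control_warp_mm,
        noise_sd=config.control_noise_sd)
    controls = phantom.make_cohort(template, ctrl_spec)

    processed = []
    for vol, _gt in controls:
        vol = _normalize_volume(vol, template, config.normalization)
        processed.append(_preprocess(vol, mask, config))
    say(f"preprocessed {len(processed)} controls")

    meta = {"fwhm_mm": config.fwhm_mm, "scaling": config.scaling,
            "space": grid.space}
    db = refdb.build_reference(processed, mask, meta=meta)

    model = None
    ssp_ref = None
    if config.statistic == "ssp-z":
        model = ssp.build_surface_model(mask)
        ctrl_proj = [ssp.project_ssp(v, model, scaling=config.scaling)
                     for v in processed]
        ssp_ref = ssp.build_ssp_reference(ctrl_proj)
        say(f"surface model with {model.n_vertices} vertices")

    patients = []
    for i, lesions in enumerate(config.patient_lesions):
        pat_spec = phantom.CohortSpec(
            n_subjects=1, seed=config.seed + 10_000 + i,
            affine_jitter=jitter, warp_amplitude_mm=config.control_warp_mm,
            noise_sd=config.control_noise_sd, lesions=lesions)
        native, gt = phantom.sample_subject(template, pat_spec, 0)
        vol = _normalize_volume(native, template, config.normalization)
        vol = _preprocess(vol, mask, config)

        if config.statistic == "ssp-z":
            proj = ssp.project_ssp(vol, model, scaling=config.scaling)
            zproj = ssp.ssp_zscores(proj, ssp_ref)
            peak_idx = int(np.argmax(zproj.values))
            patients.append(PatientResult(
                i, None, None,
                "positive" if zproj.values[peak_idx] > config.z_threshold
                else "negative",
                float(zproj.values[peak_idx]),
                tuple(model.vertices_mm[peak_idx]),
                None, gt))
            continue

        if config.statistic == "z":
            smap = statmap.zscore_map(vol, db, cap=config.cap,
                                      patient_meta=meta)
        else:
            tmap = statmap.single_subject_tmap(vol, processed, mask,
                                               cohort_meta=db.meta,
                                               patient_meta=meta)
            smap = tmap if config.statistic == "t" else statmap.tmap_to_zmap(tmap)
            if config.statistic == "tz" and config.cap is not None:
                smap = statmap.StatMap(
                    np.clip(smap.values, -config.cap, config.cap),
                    "z", smap.grid, smap.mask)
        report = cl.extract_clusters(smap, config.z_threshold,
                                     config.connectivity)
        classification = cl.classify_scan(report, config.z_threshold,
                                          config.size_threshold)
        if report.clusters:
            peak_value, peak_mm = cl.peak_info(report)
            region = cl.label_peak(peak_mm, atlas)
        else:
            peak_value, peak_mm, region = None, None, None
        say(f"patient {i}: {classification}, "
            f"{report.total_size} suprathreshold voxels")
        patients.append(PatientResult(i, smap, report, classification,
                                      peak_value, peak_mm, region, gt))

    manifest = config.to_manifest()
    result = WorkflowResult(config, db, patients, manifest)
    if config.out_dir:
        _write_outputs(result)
    return result


def _write_outputs(result):
    out = Path(result.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    refdb.save_reference(result.database, out / "refdb")
    for p in result.patients:
        if p.stat is not None:
            save_nifti(p.stat.volume(), out / f"patient{p.index:02d}_stat.nii.gz")
            save_json({"kind": p.stat.kind, "df": p.stat.df,
                       "sign_convention": p.stat.sign_convention},
                      out / f"patient{p.index:02d}_stat.json")
    result.to_frame().to_csv(out / "report.csv", index=False)
    save_json(result.manifest, out / "manifest.json")


def _suprathreshold_mask(patient, config):
    return patient.stat.values > config.z_threshold


def run_comparison(configs, log=None):
    """Run several workflows on the same subjects and compare the results."""
    if len(configs) < 2:
        raise ConfigError("need at least two configurations to compare")
    n_pat = len(configs[0].patient_lesions)
    for c in configs[1:]:
        if len(c.patient_lesions) != n_pat:
            raise ConfigError("configurations analyse different subjects")
    results = [run_workflow(c, log=log) for c in configs]

    import pandas as pd
    rows = []
    for ci, res in enumerate(results):
        frame = res.to_frame()
        frame.insert(0, "method", ci)
        rows.append(frame)
    table = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()

    pairwise = []
    for i in range(len(results)):
        for j in range(i + 1, len(results)):
            ri, rj = results[i], results[j]
            dices, commons = [], []
            same_region = 0
            for pi, pj in zip(ri.patients, rj.patients):
                if pi.stat is None or pj.stat is None:
                    continue
                ov = cl.overlap_stats(_suprathreshold_mask(pi, configs[i]),
                                      _suprathreshold_mask(pj, configs[j]))
                dices.append(ov["dice"])
                commons.append(ov["common_size"])
                if pi.peak_region is not None and pi.peak_region == pj.peak_region:
                    same_region += 1
            entry = {"methods": (i, j),
                     "mean_dice": float(np.mean(dices)) if dices else np.nan,
                     "common_sizes": commons,
                     "peak_region_concordance": same_region}
            sizes_i = [p.report.total_size for p in ri.patients if p.report]
            sizes_j = [p.report.total_size for p in rj.patients if p.report]
            if len(sizes_i) >= 5 and sizes_i != sizes_j:
                try:
                    w, p = cl.compare_cluster_sizes(sizes_i, sizes_j)
                    entry["wilcoxon"] = {"statistic": w, "p": p}
                except ValueError:
                    entry["wilcoxon"] = None
            pairwise.append(entry)
    return {"results": results, "table": table, "pairwise": pairwise}
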