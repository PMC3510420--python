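"""End-to-end orchestration: simulate -> mask -> quantify -> classify ->
analyze -> survival, as one reproducible, seeded run.

A single run seed fans out to per-stage child seeds by stable derivation
(`numpy.random.SeedSequence(seed, spawn_key=...)`), so any stage can be rerun
in isolation and the whole run is idempotent: identical config + seed produce
byte-identical reports.
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

from . import __version__
from .cohortstats import cohort_report
from .maskbuild import RoiSet, build_roi_set
from .normcut import ThresholdModel, classify, derive_threshold
from .quantify import DEFAULT_WINDOW, build_template, integrate_frames, \
    quantify_subject, ratio_image
from .survival import conversion_summary, km_estimate, logrank
from .synthcohort import GeneratorConfig, SubjectTruth, cohort_to_frame, \
    config_from_dict, config_to_dict, render_gm_probability_maps, \
    render_phantom, sample_cohort
from .templates import Atlas, build_atlas

log = logging.getLogger("pibquant.pipeline")

EXCLUSION_REASONS = ("normalization_failure", "fov", "clinical_rediagnosis")


@dataclass
class ImagingConfig:
    shape: tuple[int, int, int] = (64, 64, 48)
    voxel_mm: float = 3.0
    n_gm_maps: int = 10
    gm_perturbation: float = 0.05
    erode_iterations: int = 2
    erode_connectivity: str = "face"
    window: tuple[float, float] = DEFAULT_WINDOW
    cutoff_multiplier: float = 1.96
    threshold_method: str = "trim"


@dataclass
class PipelineConfig:
    seed: int = 0
    cohort: GeneratorConfig = field(default_factory=GeneratorConfig)
    imaging: ImagingConfig = field(default_factory=ImagingConfig)

    @staticmethod
    def from_dict(d: dict) -> "PipelineConfig":
        d = dict(d or {})
        cohort = config_from_dict(d.get("cohort", {}))
        img = d.get("imaging", {})
        if "shape" in img:
            img["shape"] = tuple(img["shape"])
        if "window" in img:
            img["window"] = tuple(img["window"])
        return PipelineConfig(seed=int(d.get("seed", 0)), cohort=cohort,
                              imaging=ImagingConfig(**img))

    def to_dict(self) -> dict:
        return {"seed": self.seed, "cohort": config_to_dict(self.cohort),
                "imaging": dataclasses.asdict(self.imaging)}


def load_pipeline_config(path) -> PipelineConfig:
    import yaml
    with open(path) as fh:
        return PipelineConfig.from_dict(yaml.safe_load(fh) or {})


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stage_seeds: dict[str, int]
    exclusions: dict[str, int]
    n_input: int
    n_included: int
    outputs: dict[str, str] = field(default_factory=dict)
    versions: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        assert self.n_input == self.n_included + sum(self.exclusions.values())
        return d


def _jsonify(obj):
    """Make a report JSON-clean: numpy scalars to python, NaN to null."""
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if not np.isfinite(f) else f
    return obj


def _stage_seed(seed: int, stage: int) -> int:
    return int(np.random.SeedSequence(seed, spawn_key=(stage,))
               .generate_state(1, np.uint32)[0] % (2**31))


def quantify_cohort(subjects: list[SubjectTruth], config: PipelineConfig,
                    atlas: Atlas, rois: RoiSet, seed: int,
                    keep_ratio_volumes: bool = False):
    """Render and quantify every subject; returns (measured DataFrame,
    exclusion tallies, ratio volumes or None)."""
    rng_root = np.random.SeedSequence(seed, spawn_key=(2,))
    child = rng_root.spawn(len(subjects))
    rows = []
    ratios = [] if keep_ratio_volumes else None
    tallies = dict.fromkeys(EXCLUSION_REASONS, 0)
    for subject, ss in zip(subjects, child):
        centre = config.cohort.centre(subject.centre)
        frames = render_phantom(subject, centre, atlas,
                                rng=np.random.default_rng(ss))
        rr = quantify_subject(subject.subject_id, subject.centre, frames,
                              rois, config.imaging.window)
        if rr.qc_excluded:
            tallies["fov"] += 1
        elif keep_ratio_volumes:
            integral = integrate_frames(frames, config.imaging.window)
            ratios.append(ratio_image(integral, rr.cereb_median))
        row = {"subject_id": rr.subject_id, "centre": rr.centre,
               "cereb_median": rr.cereb_median, "composite": rr.composite,
               "qc_excluded": rr.qc_excluded, "qc_reason": rr.qc_reason}
        for name, value in rr.regional.items():
            row[f"roi_{name}"] = value
        rows.append(row)
    return pd.DataFrame(rows), tallies, ratios


def run_all(config: PipelineConfig, out_dir: str | Path | None = None,
            write_images: bool = False) -> tuple[RunManifest, dict]:
    """Execute the whole pipeline; returns (manifest, report)."""
    seeds = {"simulate": _stage_seed(config.seed, 0),
             "gm_maps": _stage_seed(config.seed, 1),
             "render": config.seed}
    stage = "simulate"
    try:
        cohort_cfg = dataclasses.replace(config.cohort, seed=seeds["simulate"])
        subjects = sample_cohort(cohort_cfg)
        truth = cohort_to_frame(subjects)

        stage = "mask"
        atlas = build_atlas(config.imaging.shape, config.imaging.voxel_mm)
        gm_maps = render_gm_probability_maps(
            config.imaging.n_gm_maps, atlas, seed=seeds["gm_maps"],
            amplitude=config.imaging.gm_perturbation)
        rois = build_roi_set(gm_maps, atlas, config.imaging.erode_iterations,
                             config.imaging.erode_connectivity)

        stage = "quantify"
        measured, tallies, ratios = quantify_cohort(
            subjects, config, atlas, rois, config.seed,
            keep_ratio_volumes=write_images)

        stage = "classify"
        table = truth.merge(measured, on=["subject_id", "centre"])
        included = table[~table["qc_excluded"]].copy()
        controls = included[included["diagnosis"] == "control"]
        threshold = derive_threshold(
            dict(zip(controls["subject_id"], controls["composite"])),
            multiplier=config.imaging.cutoff_multiplier,
            method=config.imaging.threshold_method)
        included["classification"] = [
            classify(c, threshold.cutoff) for c in included["composite"]]

        stage = "analyze"
        stats = cohort_report(included)

        stage = "survival"
        surv = conversion_summary(included, threshold.cutoff)
        strat = _stratified_positive_logrank(included, threshold.cutoff)
    except Exception as err:
        raise RuntimeError(
            f"pipeline stage {stage!r} failed: {err}") from err

    n_input = len(table)
    manifest = RunManifest(
        config_hash=config_hash(config), seed=config.seed,
        stage_seeds=seeds, exclusions=tallies,
        n_input=n_input, n_included=len(included),
        versions={"pibquant": __version__, "numpy": np.__version__})
    report = _jsonify({
        "seed": config.seed,
        "config_hash": manifest.config_hash,
        "n_input": n_input,
        "n_included": len(included),
        "exclusions": tallies,
        "threshold": threshold.to_dict(),
        "stats": stats,
        "survival": surv.to_dict(),
        "stratified_positive_logrank": strat,
    })
    if out_dir is not None:
        _write_outputs(out_dir, config, manifest, report, truth, measured,
                       included, threshold, atlas, rois, ratios, write_images)
    return manifest, report


def _stratified_positive_logrank(included: pd.DataFrame,
                                 cutoff: float) -> dict | None:
    """Log-rank between high and low PIB-positive MCI strata (split at the
    median positive composite)."""
    from .normcut import split_high_low
    mci = included[(included["diagnosis"] == "mci")
                   & included["followup_months"].notna()
                   & (included["composite"] > cutoff)]
    if len(mci) < 4:
        return None
    low, high = split_high_low(
        list(zip(mci["subject_id"], mci["composite"])))
    if len(low) == 0 or len(high) == 0:
        return None
    ids_low = {i for i, _ in low}
    sel_low = mci["subject_id"].isin(ids_low)

    def grp(sub):
        conv = sub["converted"].astype("boolean").fillna(False).to_numpy(dtype=bool)
        months = sub["followup_months"].to_numpy(dtype=float)
        cm = sub["conversion_month"].to_numpy(dtype=float)
        t = np.where(conv & np.isfinite(cm), cm, months)
        return t, conv

    chi2, p = logrank(grp(mci[sel_low]), grp(mci[~sel_low]))
    return {"chi2": chi2, "p": p, "n_low": int(sel_low.sum()),
            "n_high": int((~sel_low).sum())}


def _write_outputs(out_dir, config, manifest, report, truth, measured,
                   included, threshold, atlas, rois, ratios, write_images):
    import nibabel as nib
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth.to_csv(out / "cohort_truth.csv", index=False, float_format="%.6f")
    measured.to_csv(out / "regional_retention.csv", index=False,
                    float_format="%.6f")
    included.to_csv(out / "cohort_classified.csv", index=False,
                    float_format="%.6f")
    (out / "threshold.json").write_text(
        json.dumps(threshold.to_dict(), indent=1, sort_keys=True))
    (out / "report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True))
    (out / "manifest.json").write_text(
        json.dumps(manifest.to_dict(), indent=1, sort_keys=True))
    manifest.outputs = {p.name: str(p) for p in out.glob("*")}
    if write_images and ratios:
        nib.save(atlas.to_nifti(), out / "atlas.nii.gz")
        template = build_template(ratios)
        nib.save(nib.Nifti1Image(template.astype(np.float32), atlas.affine),
                 out / "pib_template.nii.gz")
        mask_img = nib.Nifti1Image(
            rois.gm_mask.astype(np.uint8), atlas.affine)
        nib.save(mask_img, out / "gm_mask_eroded.nii.gz")
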