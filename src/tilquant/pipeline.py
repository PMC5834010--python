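"""End-to-end orchestration: simulate -> segment -> classify -> density ->
associate -> accounting.

Stages run sequentially on one machine, each writing its intermediate
files into the output directory, with a JSON manifest recording the config
hash, seed and library versions.  Deterministic stages are bit-identical
under re-run with the same config.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import pickle
import sys
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import __version__
from .accounting import cohort_accounting
from .association import fit_logistic, format_fit_table, table1_models
from .classify import (TrainedClassifier, classify_cells, extract_features,
                       features_to_matrix, predictions_to_frame, train_classifier)
from .config import CohortConfig, SyntheticConfig, config_hash, write_flat_config
from .density import CellMap, density_from_cellmap, summaries_to_frame
from .errors import ConfigurationError, TilquantError
from .segmentation import SegmentationParams, match_to_ground_truth, segment_image
from .synthetic import simulate_cohort, simulate_point_pattern, render_slide

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters; the config file is the single source."""

    slides: SyntheticConfig = field(default_factory=SyntheticConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    n_eval_slides: int = 2
    train_slide: bool = True
    microns_per_pixel: Optional[float] = None  # default: slides.render_pixel_size_um
    min_area_um2: float = 8.0
    max_area_um2: float = 250.0
    smoothing_sigma_um: float = 1.0
    min_peak_distance_um: float = 4.0
    svm_C: float = 1.0
    density_n_neighbours: int = 50
    seed: int = 0

    def segmentation_params(self) -> SegmentationParams:
        mpp = self.microns_per_pixel or self.slides.render_pixel_size_um
        return SegmentationParams(
            microns_per_pixel=mpp,
            smoothing_sigma_um=self.smoothing_sigma_um,
            min_area_um2=self.min_area_um2,
            max_area_um2=self.max_area_um2,
            min_peak_distance_um=self.min_peak_distance_um,
        )


def load_config(path) -> PipelineConfig:
    """Read a TOML config file with [slides], [cohort] and [pipeline] tables."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    cfg = PipelineConfig()
    if "slides" in raw:
        table = dict(raw["slides"])
        if "nucleus_radius_um_by_class" in table:
            table["nucleus_radius_um_by_class"] = {
                k: tuple(v) for k, v in table["nucleus_radius_um_by_class"].items()
            }
        cfg.slides = dataclasses.replace(cfg.slides, **table)
    if "cohort" in raw:
        cfg.cohort = dataclasses.replace(cfg.cohort, **raw["cohort"])
    for key, value in raw.get("pipeline", {}).items():
        if not hasattr(cfg, key):
            raise ConfigurationError(f"unknown pipeline option {key!r}")
        setattr(cfg, key, value)
    cfg.slides.validate()
    cfg.cohort.validate()
    return cfg


def apply_seed(cfg: PipelineConfig, seed: Optional[int]) -> PipelineConfig:
    """Override every generator seed from a single pipeline seed."""
    if seed is None:
        return cfg
    cfg.seed = seed
    cfg.slides = dataclasses.replace(cfg.slides, seed=seed)
    cfg.cohort = dataclasses.replace(cfg.cohort, seed=seed + 1)
    return cfg


def _slide_ids(cfg: PipelineConfig) -> list[str]:
    ids = []
    if cfg.train_slide:
        ids.append("train")
    ids.extend(f"eval_{i:02d}" for i in range(cfg.n_eval_slides))
    return ids


def stage_simulate(cfg: PipelineConfig, outdir: Path) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    files = []
    for i, sid in enumerate(_slide_ids(cfg)):
        scfg = dataclasses.replace(cfg.slides, seed=cfg.slides.seed + i)
        slide = simulate_point_pattern(scfg)
        image = render_slide(slide, scfg)
        cells_path = outdir / f"slide_{sid}_cells.csv"
        img_path = outdir / f"slide_{sid}.png"
        slide.write_cells_csv(cells_path)
        iio.imwrite(img_path, image)
        write_flat_config(scfg, outdir / f"slide_{sid}_config.txt")
        files += [cells_path.name, img_path.name]
        logger.info("simulated slide %s: %d cells", sid, slide.n_cells)
    cohort = simulate_cohort(cfg.cohort)
    cohort.to_csv(outdir / "cohort.csv", index=False)
    write_flat_config(cfg.cohort, outdir / "cohort_config.txt")
    files.append("cohort.csv")
    return {"files": files, "n_patients": len(cohort)}


def stage_segment(cfg: PipelineConfig, outdir: Path) -> dict:
    params = cfg.segmentation_params()
    info = {}
    for sid in _slide_ids(cfg):
        img = iio.imread(outdir / f"slide_{sid}.png")
        objects, h = segment_image(img, params, image_id=sid)
        np.save(outdir / f"slide_{sid}_haematoxylin.npy", h)
        rows = []
        for j, obj in enumerate(objects):
            rows.append((j, obj.centroid_um[0], obj.centroid_um[1], obj.area_um2))
        pd.DataFrame(rows, columns=["nucleus_id", "x_um", "y_um", "area_um2"]).to_csv(
            outdir / f"slide_{sid}_nuclei.csv", index=False
        )
        with open(outdir / f"slide_{sid}_nuclei.pkl", "wb") as fh:
            pickle.dump(objects, fh)
        info[sid] = len(objects)
        logger.info("segmented slide %s: %d nuclei", sid, len(objects))
    return {"n_nuclei": info}


def _load_stage_objects(outdir: Path, sid: str):
    with open(outdir / f"slide_{sid}_nuclei.pkl", "rb") as fh:
        objects = pickle.load(fh)
    h = np.load(outdir / f"slide_{sid}_haematoxylin.npy")
    return objects, h


def stage_classify(cfg: PipelineConfig, outdir: Path) -> dict:
    mpp = cfg.microns_per_pixel or cfg.slides.render_pixel_size_um
    if not cfg.train_slide:
        raise TilquantError("classification requires a training slide (train_slide = true)")
    objects, h = _load_stage_objects(outdir, "train")
    truth = pd.read_csv(outdir / "slide_train_cells.csv")
    assigned, recall, precision = match_to_ground_truth(
        objects, truth[["x_um", "y_um"]].to_numpy(), truth["radius_um"].to_numpy()
    )
    keep = assigned >= 0
    feats = [extract_features(o, h, mpp) for o, k in zip(objects, keep) if k]
    labels = truth["class"].to_numpy()[assigned[keep]]
    clf = train_classifier(feats, labels, C=cfg.svm_C, seed=cfg.seed)
    clf.save(outdir / "classifier.pkl")
    logger.info("trained classifier on %d nuclei (recall %.3f, precision %.3f)",
                len(feats), recall, precision)

    info = {"n_train": len(feats), "train_recall": recall, "train_precision": precision}
    for sid in _slide_ids(cfg):
        if sid == "train":
            continue
        objects, h = _load_stage_objects(outdir, sid)
        feats = [extract_features(o, h, mpp) for o in objects]
        preds = classify_cells(clf, features_to_matrix(feats)) if feats else []
        predictions_to_frame(objects, preds).to_csv(
            outdir / f"slide_{sid}_predictions.csv", index=False
        )
        info[sid] = len(preds)
    return info


def stage_density(cfg: PipelineConfig, outdir: Path) -> dict:
    summaries = []
    for sid in _slide_ids(cfg):
        if sid == "train":
            continue
        preds = pd.read_csv(outdir / f"slide_{sid}_predictions.csv")
        cellmap = CellMap.from_frame(sid, preds, cfg.slides.field_width_um,
                                     cfg.slides.field_height_um,
                                     class_column="predicted_class")
        summaries.append(density_from_cellmap(cellmap, cfg.density_n_neighbours))
    frame = summaries_to_frame(summaries)
    frame.to_csv(outdir / "slide_density_summary.csv", index=False)
    return {"n_slides": len(summaries)}


def stage_associate(cfg: PipelineConfig, outdir: Path) -> dict:
    cohort = pd.read_csv(outdir / "cohort.csv")
    baseline = cohort[cohort["has_baseline_slide"]].copy()
    fits = table1_models(baseline)
    for name, fit in fits.items():
        fit.to_frame().to_csv(outdir / f"logistic_{name}.csv", index=False)
        if fit.converged:
            format_fit_table(fit).to_csv(outdir / f"logistic_{name}_report.csv", index=False)
    info = {name: float(np.exp(fit.params[1])) if fit.converged else None
            for name, fit in fits.items()}

    matched = baseline[baseline["has_post_slide"]].copy()
    if len(matched) == 0 or matched["delta_density"].isna().all():
        logger.info("change-analysis stage skipped: no matched post-treatment data")
        info["change_analysis"] = "skipped: no matched post-treatment data"
    else:
        change_fit = fit_logistic(
            matched, "pcr",
            ("delta_density", "pre_density") + tuple(
                t for t in ("grade", "er_status", "age", "node_status", "arm",
                            "tumour_size_cat")
            ),
        )
        change_fit.to_frame().to_csv(outdir / "logistic_change.csv", index=False)
        info["change_analysis"] = "done"
    return info


def stage_accounting(cfg: PipelineConfig, outdir: Path) -> dict:
    cohort = pd.read_csv(outdir / "cohort.csv")
    flow = cohort_accounting(cohort)
    flow.to_frame().to_csv(outdir / "cohort_flow.csv", index=False)
    payload = {**dataclasses.asdict(flow), **flow.percentages()}
    payload.pop("exclusion_reasons", None)
    with open(outdir / "cohort_flow.json", "w") as fh:
        json.dump(payload, fh, indent=2)
    return payload


STAGES = {
    "simulate": stage_simulate,
    "segment": stage_segment,
    "classify": stage_classify,
    "density": stage_density,
    "associate": stage_associate,
    "accounting": stage_accounting,
}
STAGE_ORDER = ["simulate", "segment", "classify", "density", "associate", "accounting"]


def run_pipeline(config_path, outdir, seed: Optional[int] = None,
                 stages: Optional[list[str]] = None) -> Path:
    """Run the requested stages in order and write the provenance manifest."""
    cfg = apply_seed(load_config(config_path), seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tilquant_version": __version__,
        "python": sys.version.split()[0],
        "config_hash_slides": config_hash(cfg.slides),
        "config_hash_cohort": config_hash(cfg.cohort),
        "seed": cfg.seed,
        "stages": {},
    }
    for pkg in ("numpy", "scipy", "pandas", "sklearn", "skimage", "statsmodels",
                "lifelines"):
        try:
            manifest[f"version_{pkg}"] = __import__(pkg).__version__
        except Exception:  # pragma: no cover
            pass
    for name in stages or STAGE_ORDER:
        if name not in STAGES:
            raise TilquantError(f"unknown stage {name!r}")
        logger.info("=== stage %s ===", name)
        manifest["stages"][name] = STAGES[name](cfg, outdir)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return outdir
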